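"""Set-strategy opponents and the WSLS / Tit-for-Tat consistency classifier.

Set strategies serve as controls against the adaptive agents: fixed
actions, unbiased random play, Win-Stay-Lose-Shift (repeat the last
action after a win, switch after a loss) and Tit-for-Tat (copy the
opponent's last action), plus an "aggressive" opponent that plays the
game's confrontational action with probability ``p_aggress``.

``classify_strategy`` scores a realized history against the WSLS and
T4T templates: for every round from the second on, each template
predicts a move from the history so far, and the score is the fraction
of actual moves matching the prediction.  The scores depend only on
win/loss labels and copied actions, never on payoff scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FIXED_KINDS = {
    "always_hare": "hare",
    "always_stag": "stag",
    "always_escalate": "escalate",
    "always_display": "display",
    "always_swerve": "swerve",
    "always_straight": "straight",
}

KINDS = tuple(FIXED_KINDS) + ("random", "wsls", "t4t", "aggressive")

# aggressive / cooperative poles of each two-action alphabet
AGGRESSIVE_ACTION = {
    ("escalate", "display"): "escalate",
    ("straight", "swerve"): "straight",
    ("swerve", "straight"): "straight",
    ("display", "escalate"): "escalate",
    ("stag", "hare"): "hare",
    ("hare", "stag"): "hare",
}


@dataclass(frozen=True)
class Round:
    """One logged round from a single player's point of view."""

    own: str
    opponent: str
    payoff: float


History = list  # list[Round]; append-only by convention


@dataclass(frozen=True)
class StrategySpec:
    """Named set strategy.

    ``win_threshold`` defines WSLS's "win": a payoff strictly above it
    (default 0, the game's minimum non-negative outcome).  ``first_move``
    overrides the opening action; by default fixed strategies play their
    fixed action and WSLS/T4T open with the cooperative action.
    """

    kind: str
    p_aggress: float = 1.0
    first_move: str | None = None
    win_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if not 0.0 <= self.p_aggress <= 1.0:
            raise ValueError("p_aggress must lie in [0, 1]")


def _other(action: str, alphabet: tuple[str, str]) -> str:
    return alphabet[1] if action == alphabet[0] else alphabet[0]


def _cooperative(alphabet: tuple[str, str]) -> str:
    aggressive = AGGRESSIVE_ACTION[tuple(alphabet)]
    return _other(aggressive, alphabet)


def wsls_prediction(
    last: Round, alphabet: tuple[str, str], win_threshold: float = 0.0
) -> str:
    """Win-Stay-Lose-Shift: repeat after a win, switch after a loss."""
    if last.payoff > win_threshold:
        return last.own
    return _other(last.own, alphabet)


def t4t_prediction(last: Round, alphabet: tuple[str, str]) -> str:
    """Tit-for-Tat: copy the opponent's previous action."""
    return last.opponent


def next_move(
    spec: StrategySpec,
    history: History,
    alphabet: tuple[str, str],
    rng: np.random.Generator,
) -> str:
    """The strategy's next action given the realized history."""
    for r in history:
        if r.own not in alphabet or r.opponent not in alphabet:
            raise ValueError(
                f"history action outside alphabet {alphabet}: {r}"
            )
    if spec.kind in FIXED_KINDS:
        action = FIXED_KINDS[spec.kind]
        if action not in alphabet:
            raise ValueError(
                f"strategy {spec.kind!r} incompatible with alphabet {alphabet}"
            )
        return action
    if spec.kind == "random":
        return alphabet[int(rng.integers(2))]
    if spec.kind == "aggressive":
        aggressive = AGGRESSIVE_ACTION[tuple(alphabet)]
        if rng.random() < spec.p_aggress:
            return aggressive
        return _other(aggressive, alphabet)
    # WSLS / T4T need a previous round; otherwise open cooperatively
    if not history:
        return spec.first_move or _cooperative(alphabet)
    last = history[-1]
    if spec.kind == "wsls":
        return wsls_prediction(last, alphabet, spec.win_threshold)
    return t4t_prediction(last, alphabet)


class SetStrategyHunter:
    """Set-strategy Stag Hunt player: target rule + greedy pathing.

    Supported kinds: always_stag, always_hare, random (fresh target each
    turn), wsls (keep last game's target after a win, switch after a
    loss; opens with stag, the cooperative hunt).
    """

    def __init__(self, spec: StrategySpec, player: int = 2):
        if spec.kind not in (
            "always_stag", "always_hare", "random", "wsls",
        ):
            raise ValueError(
                f"strategy {spec.kind!r} not playable in the Stag Hunt"
            )
        self.spec = spec
        self.player = player
        self._wsls_target = spec.first_move or "stag"

    def end_game(self, own_payoff: float) -> None:
        """Feed the game result back (drives the WSLS switch)."""
        if self.spec.kind == "wsls" and own_payoff <= self.spec.win_threshold:
            self._wsls_target = "hare" if self._wsls_target == "stag" else "stag"

    def target_kind(self, rng: np.random.Generator) -> str:
        if self.spec.kind == "always_stag":
            return "stag"
        if self.spec.kind == "always_hare":
            return "hare"
        if self.spec.kind == "random":
            return ("stag", "hare")[int(rng.integers(2))]
        return self._wsls_target

    def move(self, state, rng: np.random.Generator) -> tuple[str, str]:
        """Returns (move, pursued target kind) for this turn."""
        from .actor_critic import greedy_move, manhattan

        me = state.p1 if self.player == 1 else state.p2
        kind = self.target_kind(rng)
        if kind == "stag":
            target = state.stag
        else:
            target = min(state.hares, key=lambda h: manhattan(me, h))
        return greedy_move(me, target, rng), kind


def classify_strategy(
    history: History,
    alphabet: tuple[str, str],
    win_threshold: float = 0.0,
) -> dict[str, float]:
    """Fraction of moves (round 2 on) matching each template's prediction."""
    if len(history) < 2:
        raise ValueError("classification needs at least 2 rounds")
    wsls_hits = 0
    t4t_hits = 0
    n = len(history) - 1
    for prev, cur in zip(history[:-1], history[1:]):
        if cur.own == wsls_prediction(prev, alphabet, win_threshold):
            wsls_hits += 1
        if cur.own == t4t_prediction(prev, alphabet):
            t4t_hits += 1
    return {"wsls": wsls_hits / n, "t4t": t4t_hits / n}
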