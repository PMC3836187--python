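"""Game environments: Hawk-Dove, Chicken, and a spatial Stag Hunt.

All three games are pure, seedable state machines.  The two matrix games
(Hawk-Dove, Chicken) reduce each round to a simultaneous binary choice;
the Stag Hunt is played on a small grid with token movement, enforced
adjacency for captures, and a turn timeout.

Payoff conventions
------------------
Hawk-Dove: two players contest a resource (the "territory of interest").
``escalate`` is the aggressive action, ``display`` the cooperative one.
Both display -> split the resource; one escalates -> winner takes all;
both escalate -> they fight: each gets half the resource minus an injury
cost, drawn serious with probability ``p_serious`` (the environment's
harshness) and mild otherwise.

Chicken: ``swerve`` concedes the lane (payoff 0 when alone, the minimum
payoff when both swerve); ``straight`` wins the maximum payoff against a
swerver; both straight -> head-on collision, the worst outcome.

Stag Hunt: the stag pays more than a hare but requires both players to be
in capture contact with it on the same turn; a hare is caught by a single
player alone.  A game that reaches the timeout pays nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

HAWK_DOVE_ACTIONS = ("escalate", "display")
CHICKEN_ACTIONS = ("swerve", "straight")
STAG_HUNT_MOVES = ("up", "down", "left", "right", "stay")

_MOVE_DELTAS = {
    "up": (-1, 0),
    "down": (1, 0),
    "left": (0, -1),
    "right": (0, 1),
    "stay": (0, 0),
}


@dataclass(frozen=True)
class HawkDoveConfig:
    """Parameters of the Hawk-Dove resource contest.

    ``p_serious`` tunes environmental harshness: the probability that the
    injury from a fight is serious rather than mild.
    """

    resource_value: float = 1.0
    mild_injury_cost: float = 0.75
    serious_injury_cost: float = 1.5
    p_serious: float = 0.25
    grid_size: int = 5

    def __post_init__(self) -> None:
        if self.resource_value <= 0:
            raise ValueError("resource_value must be > 0")
        if not 0 <= self.mild_injury_cost <= self.serious_injury_cost:
            raise ValueError(
                "need serious_injury_cost >= mild_injury_cost >= 0"
            )
        if not 0.0 <= self.p_serious <= 1.0:
            raise ValueError("p_serious must lie in [0, 1]")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")


@dataclass(frozen=True)
class ChickenConfig:
    """Parameters of the Chicken lane game.

    The lone-swerver payoff is fixed at 0 by the game's definition;
    ``collision_payoff < 0 <= min_payoff < max_payoff`` must hold.
    """

    max_payoff: float = 6.0
    min_payoff: float = 2.0
    collision_payoff: float = -10.0
    swerve_alone_payoff: float = 0.0

    def __post_init__(self) -> None:
        if self.swerve_alone_payoff != 0.0:
            raise ValueError("swerve_alone_payoff is fixed at 0")
        if not (self.collision_payoff < 0 <= self.min_payoff < self.max_payoff):
            raise ValueError(
                "need collision_payoff < 0 <= min_payoff < max_payoff"
            )


@dataclass(frozen=True)
class StagHuntConfig:
    """Parameters of the spatial Stag Hunt."""

    board_size: int = 5
    stag_payoff: float = 5.0
    hare_payoff: float = 1.0
    n_hares: int = 2
    timeout: int = 50

    def __post_init__(self) -> None:
        if not self.stag_payoff > self.hare_payoff > 0:
            raise ValueError("need stag_payoff > hare_payoff > 0")
        if self.timeout <= 0:
            raise ValueError("timeout must be > 0")
        if self.n_hares < 1:
            raise ValueError("need at least one hare")
        if self.board_size**2 < 3 + self.n_hares:
            raise ValueError("board too small for token count")


@dataclass(frozen=True)
class GameOutcome:
    """Joint actions and per-player payoffs for one resolved round.

    ``injury_severity`` is meaningful for Hawk-Dove only ("none", "mild"
    or "serious"); the other games always record "none".
    """

    action_p1: str
    action_p2: str
    payoff_p1: float
    payoff_p2: float
    injury_severity: str = "none"

    def swapped(self) -> "GameOutcome":
        """The same outcome from the other player's seat."""
        return GameOutcome(
            self.action_p2, self.action_p1, self.payoff_p2, self.payoff_p1,
            self.injury_severity,
        )


@dataclass(frozen=True)
class StagHuntState:
    """Board snapshot: token coordinates (0-based row, column) and turn."""

    p1: tuple[int, int]
    p2: tuple[int, int]
    stag: tuple[int, int]
    hares: tuple[tuple[int, int], ...]
    turn: int = 0
    terminal: bool = False
    capture_type: str | None = None  # "stag" | "hare" | "timeout" | None


def _check_action(action: str, alphabet: tuple[str, ...]) -> None:
    if action not in alphabet:
        raise ValueError(
            f"invalid action {action!r}; expected one of {alphabet}"
        )


def resolve_hawk_dove(
    a1: str, a2: str, cfg: HawkDoveConfig, rng: np.random.Generator
) -> GameOutcome:
    """Resolve one Hawk-Dove round.

    Both escalate -> the players fight; a single severity (serious with
    probability ``p_serious``, mild otherwise) applies to both, and each
    receives half the resource minus that injury cost.
    """
    _check_action(a1, HAWK_DOVE_ACTIONS)
    _check_action(a2, HAWK_DOVE_ACTIONS)
    v = cfg.resource_value
    if a1 == "display" and a2 == "display":
        return GameOutcome(a1, a2, v / 2, v / 2)
    if a1 == "escalate" and a2 == "display":
        return GameOutcome(a1, a2, v, 0.0)
    if a1 == "display" and a2 == "escalate":
        return GameOutcome(a1, a2, 0.0, v)
    # both escalate: fight, shared severity draw
    serious = rng.random() < cfg.p_serious
    severity = "serious" if serious else "mild"
    cost = cfg.serious_injury_cost if serious else cfg.mild_injury_cost
    pay = v / 2 - cost
    return GameOutcome(a1, a2, pay, pay, severity)


def resolve_chicken(a1: str, a2: str, cfg: ChickenConfig) -> GameOutcome:
    """Resolve one Chicken round (fully deterministic)."""
    _check_action(a1, CHICKEN_ACTIONS)
    _check_action(a2, CHICKEN_ACTIONS)
    if a1 == "swerve" and a2 == "swerve":
        return GameOutcome(a1, a2, cfg.min_payoff, cfg.min_payoff)
    if a1 == "swerve" and a2 == "straight":
        return GameOutcome(a1, a2, 0.0, cfg.max_payoff)
    if a1 == "straight" and a2 == "swerve":
        return GameOutcome(a1, a2, cfg.max_payoff, 0.0)
    return GameOutcome(a1, a2, cfg.collision_payoff, cfg.collision_payoff)


def hawk_dove_components(
    outcome: GameOutcome, cfg: HawkDoveConfig, player: int = 1
) -> tuple[float, float]:
    """Split a Hawk-Dove outcome into (reward, cost) magnitudes.

    Reward is the gross resource share obtained; cost is the injury cost
    incurred.  payoff == reward - cost always holds.
    """
    own = outcome.action_p1 if player == 1 else outcome.action_p2
    other = outcome.action_p2 if player == 1 else outcome.action_p1
    v = cfg.resource_value
    if own == "display" and other == "display":
        return v / 2, 0.0
    if own == "escalate" and other == "display":
        return v, 0.0
    if own == "display" and other == "escalate":
        return 0.0, 0.0
    cost = (
        cfg.serious_injury_cost
        if outcome.injury_severity == "serious"
        else cfg.mild_injury_cost
    )
    return v / 2, cost


def chicken_components(
    outcome: GameOutcome, cfg: ChickenConfig, player: int = 1
) -> tuple[float, float]:
    """Split a Chicken outcome into (reward, cost) magnitudes."""
    payoff = outcome.payoff_p1 if player == 1 else outcome.payoff_p2
    return max(payoff, 0.0), max(-payoff, 0.0)


def random_setup(cfg: StagHuntConfig, rng: np.random.Generator) -> StagHuntState:
    """Place both players, the stag and the hares on distinct random cells."""
    n_tokens = 3 + cfg.n_hares
    n_cells = cfg.board_size**2
    if n_cells < n_tokens:
        raise ValueError("board too small for token count")
    cells = rng.choice(n_cells, size=n_tokens, replace=False)
    coords = [(int(c) // cfg.board_size, int(c) % cfg.board_size) for c in cells]
    return StagHuntState(
        p1=coords[0], p2=coords[1], stag=coords[2], hares=tuple(coords[3:])
    )


def _clamped_move(
    pos: tuple[int, int], move: str, board_size: int
) -> tuple[int, int]:
    if move not in STAG_HUNT_MOVES:
        raise ValueError(
            f"invalid move {move!r}; expected one of {STAG_HUNT_MOVES}"
        )
    dr, dc = _MOVE_DELTAS[move]
    r, c = pos[0] + dr, pos[1] + dc
    if not (0 <= r < board_size and 0 <= c < board_size):
        return pos  # off-board moves clamp to the current position
    return (r, c)


def in_contact(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Capture contact: on the token's cell or 4-adjacent to it."""
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) <= 1


def step_stag_hunt(
    state: StagHuntState,
    move_p1: str,
    move_p2: str,
    cfg: StagHuntConfig,
    hunt_p1: str | None = None,
    hunt_p2: str | None = None,
) -> tuple[StagHuntState, GameOutcome | None]:
    """Advance the Stag Hunt by one simultaneous turn.

    Capture checks run after movement, hare before stag: a player in
    contact with a hare catches it alone (independent hunts, so two
    simultaneous hare captures both pay); the stag falls only when BOTH
    players are in contact with it on the same turn.  Reaching the
    timeout ends the game with zero payoffs.

    ``hunt_p1``/``hunt_p2`` declare what each player is pursuing this
    turn ("stag" or "hare").  Adjacency is the condition to catch the
    pursued token: a declared stag hunter does not pick up a hare by
    walking past it.  With the default ``None`` (intent unknown) any
    hare contact captures.
    """
    if state.terminal:
        raise ValueError("cannot step a terminal Stag Hunt state")
    for hunt in (hunt_p1, hunt_p2):
        if hunt not in (None, "stag", "hare"):
            raise ValueError(f"invalid hunt target {hunt!r}")
    p1 = _clamped_move(state.p1, move_p1, cfg.board_size)
    p2 = _clamped_move(state.p2, move_p2, cfg.board_size)
    turn = state.turn + 1

    hare1 = hunt_p1 in (None, "hare") and any(
        in_contact(p1, h) for h in state.hares
    )
    hare2 = hunt_p2 in (None, "hare") and any(
        in_contact(p2, h) for h in state.hares
    )
    if hare1 or hare2:
        new = replace(
            state, p1=p1, p2=p2, turn=turn, terminal=True, capture_type="hare"
        )
        outcome = GameOutcome(
            "hare" if hare1 else "none",
            "hare" if hare2 else "none",
            cfg.hare_payoff if hare1 else 0.0,
            cfg.hare_payoff if hare2 else 0.0,
        )
        return new, outcome

    if in_contact(p1, state.stag) and in_contact(p2, state.stag):
        new = replace(
            state, p1=p1, p2=p2, turn=turn, terminal=True, capture_type="stag"
        )
        return new, GameOutcome("stag", "stag", cfg.stag_payoff, cfg.stag_payoff)

    if turn >= cfg.timeout:
        new = replace(
            state, p1=p1, p2=p2, turn=turn, terminal=True,
            capture_type="timeout",
        )
        return new, GameOutcome("none", "none", 0.0, 0.0)

    return replace(state, p1=p1, p2=p2, turn=turn), None


def render_board(state: StagHuntState, cfg: StagHuntConfig) -> str:
    """ASCII board sketch: 1/2 players, S stag, h hare, . empty."""
    grid = [["." for _ in range(cfg.board_size)] for _ in range(cfg.board_size)]
    for h in state.hares:
        grid[h[0]][h[1]] = "h"
    grid[state.stag[0]][state.stag[1]] = "S"
    grid[state.p1[0]][state.p1[1]] = "1" if state.p1 != state.p2 else "B"
    if state.p1 != state.p2:
        grid[state.p2[0]][state.p2[1]] = "2"
    return "\n".join(" ".join(row) for row in grid)
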