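"""Actor-Critic agent for the spatial Stag Hunt.

Three state tables — a Reward Critic, a Cost Critic, and an Actor —
are keyed by a coarse featurization of the board: binned Manhattan
distances of the agent and of the other player to the stag and to the
nearest hare (bins 0-1, 2-3, >=4; 3^4 = 81 states).  Including the
other player's distances is what lets the agent condition its hunt on
the partner's apparent commitment.

Each turn the Actor's two preferences (hunt stag / hunt hare) at the
current state pass through a SoftMax to give choice probabilities; the
agent samples a target and takes the greedy move toward it.  Critics
learn by a delta rule: delta = r + V(now) - V(prev), applied to the
previous state's value with a learning rate.  The reward signal is the
payoff obtained; the cost signal is the negated expected payoff of the
chosen target whenever the hunt fails to deliver it (perceived loss).
The Actor is updated with the summed reward and cost deltas in the
standard advantage form, mirroring opponent dopaminergic (reward) and
serotonergic (cost) value channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .games import StagHuntConfig, StagHuntState

CHOICES = ("stag", "hare")

StateFeatures = tuple[int, int, int, int]


@dataclass(frozen=True)
class ACParams:
    critic_learning_rate: float = 0.8
    actor_learning_rate: float = 0.5
    initial_value: float = 0.0

    def __post_init__(self) -> None:
        for lr in (self.critic_learning_rate, self.actor_learning_rate):
            if not 0.0 < lr <= 1.0:
                raise ValueError("learning rates must lie in (0, 1]")


def bin_distance(d: int) -> int:
    """Bin a Manhattan distance: 0 for 0-1, 1 for 2-3, 2 for >=4."""
    if d <= 1:
        return 0
    if d <= 3:
        return 1
    return 2


def manhattan(a: tuple[int, int], b: tuple[int, int]) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


def featurize(state: StagHuntState, player: int = 1) -> StateFeatures:
    """Binned distances (self->stag, self->hare, other->stag, other->hare)."""
    me = state.p1 if player == 1 else state.p2
    other = state.p2 if player == 1 else state.p1
    d_hare_me = min(manhattan(me, h) for h in state.hares)
    d_hare_other = min(manhattan(other, h) for h in state.hares)
    return (
        bin_distance(manhattan(me, state.stag)),
        bin_distance(d_hare_me),
        bin_distance(manhattan(other, state.stag)),
        bin_distance(d_hare_other),
    )


def delta(r: float, v_now: float, v_prev: float) -> float:
    """Prediction-error delta rule: r(t) + V(now) - V(prev)."""
    return r + v_now - v_prev


def softmax_policy(
    actor: dict, state: StateFeatures, initial_value: float = 0.0
) -> dict[str, float]:
    """SoftMax over the Actor's two preferences at ``state``.

    Overflow is guarded by max-subtraction (mathematically a no-op).
    """
    v = np.array([actor.get((state, c), initial_value) for c in CHOICES])
    e = np.exp(v - v.max())
    p = e / e.sum()
    return {c: float(p[i]) for i, c in enumerate(CHOICES)}


def update_critic(
    table: dict, prev_state: StateFeatures, d: float, params: ACParams
) -> None:
    """Move the previous state's value toward its delta-corrected target."""
    v = table.get(prev_state, params.initial_value)
    table[prev_state] = v + params.critic_learning_rate * d


def update_actor(
    actor: dict,
    state: StateFeatures,
    chosen: str,
    d_total: float,
    policy: dict[str, float],
    params: ACParams,
) -> None:
    """Advantage-form preference update at ``state``.

    The chosen target's preference rises by (1 - P[chosen]) * delta,
    the other falls by P[other] * delta (scaled by the learning rate),
    preserving the SoftMax contrast between the two hunts.
    """
    if chosen not in CHOICES:
        raise ValueError(f"unknown choice {chosen!r}")
    other = CHOICES[1] if chosen == CHOICES[0] else CHOICES[0]
    lr = params.actor_learning_rate
    v_c = actor.get((state, chosen), params.initial_value)
    v_o = actor.get((state, other), params.initial_value)
    actor[(state, chosen)] = v_c + lr * (1.0 - policy[chosen]) * d_total
    actor[(state, other)] = v_o - lr * policy[other] * d_total


def greedy_move(
    pos: tuple[int, int],
    target: tuple[int, int],
    rng: np.random.Generator,
) -> str:
    """Greedy Manhattan-descent toward ``target``; ties break uniformly."""
    moves = []
    if target[0] < pos[0]:
        moves.append("up")
    elif target[0] > pos[0]:
        moves.append("down")
    if target[1] < pos[1]:
        moves.append("left")
    elif target[1] > pos[1]:
        moves.append("right")
    if not moves:
        return "stay"
    return moves[int(rng.integers(len(moves)))]


class ActorCriticAgent:
    """Stag Hunt player learning opponent reward/cost value channels.

    Tables are plain dicts keyed by feature tuples (and choice, for the
    Actor); unvisited states read as ``params.initial_value``.
    """

    def __init__(self, cfg: StagHuntConfig, params: ACParams, player: int = 1):
        self.cfg = cfg
        self.params = params
        self.player = player
        self.reward_critic: dict[StateFeatures, float] = {}
        self.cost_critic: dict[StateFeatures, float] = {}
        self.actor: dict[tuple[StateFeatures, str], float] = {}
        self._prev_feat: StateFeatures | None = None
        self._prev_choice: str | None = None
        self._prev_policy: dict[str, float] | None = None

    def policy(self, feat: StateFeatures) -> dict[str, float]:
        return softmax_policy(self.actor, feat, self.params.initial_value)

    def begin_game(self) -> None:
        """Forget the previous game's trailing state (no cross-game delta)."""
        self._prev_feat = None
        self._prev_choice = None
        self._prev_policy = None

    def act(
        self, state: StagHuntState, rng: np.random.Generator
    ) -> tuple[str, str, dict[str, float]]:
        """Sample a target from the SoftMax policy and move toward it.

        Returns (move, chosen target, policy at this state).
        """
        if state.terminal:
            raise ValueError("cannot act in a terminal state")
        feat = featurize(state, self.player)
        pol = self.policy(feat)
        chosen = "stag" if rng.random() < pol["stag"] else "hare"
        me = state.p1 if self.player == 1 else state.p2
        if chosen == "stag":
            target = state.stag
        else:
            target = min(state.hares, key=lambda h: manhattan(me, h))
        move = greedy_move(me, target, rng)
        self._prev_feat = feat
        self._prev_choice = chosen
        self._prev_policy = pol
        return move, chosen, pol

    def learn(
        self, new_state: StagHuntState, own_payoff: float | None
    ) -> tuple[float, float]:
        """Critic/Actor updates after the board advanced.

        ``own_payoff`` is this agent's payoff if the game just ended,
        else None.  Non-terminal turns carry zero reward and cost
        signals; terminal turns deliver the payoff as reward and, if the
        chosen target's expected payoff was not fulfilled, its negation
        as cost (perceived loss).  Terminal states have value 0.
        Returns (delta_reward, delta_cost).
        """
        if self._prev_feat is None:
            raise RuntimeError("learn() requires a preceding act()")
        prev = self._prev_feat
        chosen = self._prev_choice
        terminal = new_state.terminal
        if terminal:
            v_r_now = 0.0
            v_c_now = 0.0
            expected = (
                self.cfg.stag_payoff if chosen == "stag" else self.cfg.hare_payoff
            )
            r_reward = own_payoff
            r_cost = -expected if own_payoff < expected else 0.0
        else:
            feat_now = featurize(new_state, self.player)
            v_r_now = self.reward_critic.get(feat_now, self.params.initial_value)
            v_c_now = self.cost_critic.get(feat_now, self.params.initial_value)
            r_reward = 0.0
            r_cost = 0.0
        v_r_prev = self.reward_critic.get(prev, self.params.initial_value)
        v_c_prev = self.cost_critic.get(prev, self.params.initial_value)
        d_reward = delta(r_reward, v_r_now, v_r_prev)
        d_cost = delta(r_cost, v_c_now, v_c_prev)
        update_critic(self.reward_critic, prev, d_reward, self.params)
        update_critic(self.cost_critic, prev, d_cost, self.params)
        update_actor(
            self.actor, prev, chosen, d_reward + d_cost, self._prev_policy,
            self.params,
        )
        if terminal:
            self.begin_game()
        return d_reward, d_cost

    # -- serialization --------------------------------------------------

    def dump_tables(self) -> str:
        """Flat text serialization: table, feature tuple, choice, weight."""
        lines = []
        for feat, v in sorted(self.reward_critic.items()):
            lines.append(f"reward_critic\t{feat}\t-\t{v!r}")
        for feat, v in sorted(self.cost_critic.items()):
            lines.append(f"cost_critic\t{feat}\t-\t{v!r}")
        for (feat, c), v in sorted(self.actor.items()):
            lines.append(f"actor\t{feat}\t{c}\t{v!r}")
        return "\n".join(lines) + "\n"

    def load_tables(self, text: str) -> None:
        import ast

        self.reward_critic.clear()
        self.cost_critic.clear()
        self.actor.clear()
        for line in text.strip().splitlines():
            table, feat_s, choice, v_s = line.split("\t")
            feat = ast.literal_eval(feat_s)
            v = float(v_s)
            if table == "reward_critic":
                self.reward_critic[feat] = v
            elif table == "cost_critic":
                self.cost_critic[feat] = v
            elif table == "actor":
                self.actor[(feat, choice)] = v
            else:
                raise ValueError(f"unknown table {table!r}")
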