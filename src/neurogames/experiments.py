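"""Seeded experiment runner: sessions, lesion studies, logging, summaries.

A session pits two agents (adaptive or set-strategy) against each other
for a fixed number of rounds (matrix games) or games (Stag Hunt).  The
master seed fans out into named substreams (setup, agent1, agent2,
game) so that paired designs — in particular the lesion study — share
environment randomness across arms.

Every decision produces one TrialRecord (a flat dict with a constant
schema within a run); summaries are pure functions of the records and
can be recomputed exactly from a persisted JSON-lines log.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import games
from .actor_critic import ACParams, ActorCriticAgent, featurize
from .games import (
    CHICKEN_ACTIONS,
    HAWK_DOVE_ACTIONS,
    ChickenConfig,
    GameOutcome,
    HawkDoveConfig,
    StagHuntConfig,
    chicken_components,
    hawk_dove_components,
    random_setup,
    resolve_chicken,
    resolve_hawk_dove,
    step_stag_hunt,
)
from .neural_agent import NetworkParams, NeuralAgent, Reinforcement
from .opponents import (
    Round,
    SetStrategyHunter,
    StrategySpec,
    classify_strategy,
    next_move,
)

MATRIX_GAMES = ("hawk_dove", "chicken")

# aggressive action per matrix game (the "escalation" pole)
_AGGRESSIVE = {"hawk_dove": "escalate", "chicken": "straight"}
_ALPHABET = {"hawk_dove": HAWK_DOVE_ACTIONS, "chicken": CHICKEN_ACTIONS}


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class AgentSpec:
    """One player: an adaptive agent or a named set strategy.

    ``kind`` is "neural", "actor_critic", or any strategy kind from
    :mod:`neurogames.opponents`.  ``lesion`` pre-lesions a neural agent
    ("cost" or "reward"); ``p_aggress``/``win_threshold`` parameterize
    the corresponding set strategies.
    """

    kind: str
    lesion: str | None = None
    p_aggress: float = 1.0
    win_threshold: float = 0.0
    first_move: str | None = None

    def strategy(self) -> StrategySpec:
        return StrategySpec(
            kind=self.kind,
            p_aggress=self.p_aggress,
            first_move=self.first_move,
            win_threshold=self.win_threshold,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a session byte-for-byte."""

    game: str
    agent1: AgentSpec
    agent2: AgentSpec
    n_rounds: int = 500
    seed: int = 0
    hawk_dove: HawkDoveConfig = field(default_factory=HawkDoveConfig)
    chicken: ChickenConfig = field(default_factory=ChickenConfig)
    stag_hunt: StagHuntConfig = field(default_factory=StagHuntConfig)
    network: NetworkParams | None = None
    actor_critic: ACParams = field(default_factory=ACParams)

    def __post_init__(self) -> None:
        if self.game not in MATRIX_GAMES + ("stag_hunt",):
            raise ValueError(f"unknown game {self.game!r}")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")

    def network_params(self) -> NetworkParams:
        if self.network is not None:
            return self.network
        # salient-input amplitude is game dependent
        b = 0.75 if self.game == "hawk_dove" else 0.45
        return NetworkParams(b=b)


@dataclass(frozen=True)
class SessionSummary:
    """Counting statistics of one session, derived from records only."""

    game: str
    n_rounds: int
    escalation_p1: float
    escalation_p2: float
    cooperation_p1: float
    cooperation_p2: float
    mean_payoff_p1: float
    mean_payoff_p2: float
    consistency_p1: dict | None = None
    consistency_p2: dict | None = None
    injury_counts: dict | None = None
    stag_captures: int | None = None
    hare_captures: int | None = None
    timeouts: int | None = None
    stag_to_hare_ratio: float | None = None
    mean_turns: float | None = None
    mean_path_length_p1: float | None = None


# ---------------------------------------------------------------------
# matrix-game sessions (Hawk-Dove, Chicken)
# ---------------------------------------------------------------------


def _matrix_state_index(
    prev: Round | None, alphabet: tuple[str, str]
) -> int:
    """Observable state id: 0 = game start, else 1 + joint prior outcome."""
    if prev is None:
        return 0
    own = alphabet.index(prev.own)
    opp = alphabet.index(prev.opponent)
    return 1 + 2 * own + opp


def _make_matrix_player(
    spec: AgentSpec, cfg: ExperimentConfig, rng_init: np.random.Generator
):
    if spec.kind == "actor_critic":
        raise ValueError("actor_critic agents play the Stag Hunt only")
    if spec.kind == "neural":
        alphabet = _ALPHABET[cfg.game]
        aggressive = _AGGRESSIVE[cfg.game]
        actions = (
            aggressive,
            alphabet[0] if alphabet[1] == aggressive else alphabet[1],
        )
        agent = NeuralAgent(
            n_inputs=5, actions=actions, params=cfg.network_params(),
            rng=rng_init,
        )
        if spec.lesion:
            agent.lesion(spec.lesion)
        return agent
    if spec.lesion:
        raise ValueError("lesions apply to neural agents only")
    return spec.strategy()


def _run_matrix_session(cfg: ExperimentConfig) -> tuple[list[dict], SessionSummary]:
    alphabet = _ALPHABET[cfg.game]
    rng_game = substream(cfg.seed, "game")
    rngs = [substream(cfg.seed, "agent1"), substream(cfg.seed, "agent2")]
    inits = [
        substream(cfg.seed, "agent1-init"),
        substream(cfg.seed, "agent2-init"),
    ]
    players = [
        _make_matrix_player(cfg.agent1, cfg, inits[0]),
        _make_matrix_player(cfg.agent2, cfg, inits[1]),
    ]
    histories: list[list[Round]] = [[], []]
    records: list[dict] = []
    game_cfg = cfg.hawk_dove if cfg.game == "hawk_dove" else cfg.chicken

    for rnd in range(1, cfg.n_rounds + 1):
        actions = []
        internals: list[dict] = []
        for i, player in enumerate(players):
            if isinstance(player, NeuralAgent):
                prev = histories[i][-1] if histories[i] else None
                idx = _matrix_state_index(prev, alphabet)
                a = player.settle_and_select(idx, rngs[i])
                internals.append(
                    {
                        "s_cost": player.s_cost,
                        "s_reward": player.s_reward,
                        "nm": player.nm_tonic(),
                    }
                )
            else:
                a = next_move(player, histories[i], alphabet, rngs[i])
                internals.append({})
            actions.append(a)

        if cfg.game == "hawk_dove":
            outcome = resolve_hawk_dove(actions[0], actions[1], game_cfg, rng_game)
            comps = [
                hawk_dove_components(outcome, game_cfg, player=i + 1)
                for i in range(2)
            ]
        else:
            outcome = resolve_chicken(actions[0], actions[1], game_cfg)
            comps = [
                chicken_components(outcome, game_cfg, player=i + 1)
                for i in range(2)
            ]

        payoffs = (outcome.payoff_p1, outcome.payoff_p2)
        for i, player in enumerate(players):
            if isinstance(player, NeuralAgent):
                reinf = Reinforcement(*comps[i])
                internals[i]["R"] = player.reinforcement(reinf)
                player.apply_plasticity(reinf)
            histories[i].append(
                Round(actions[i], actions[1 - i], payoffs[i])
            )
        records.append(
            {
                "game": cfg.game,
                "round": rnd,
                "action_p1": actions[0],
                "action_p2": actions[1],
                "payoff_p1": payoffs[0],
                "payoff_p2": payoffs[1],
                "injury": outcome.injury_severity,
                "agent1": internals[0],
                "agent2": internals[1],
            }
        )
    return records, summarize(records)


# ---------------------------------------------------------------------
# Stag Hunt sessions
# ---------------------------------------------------------------------


def _make_hunter(spec: AgentSpec, cfg: ExperimentConfig, player: int):
    if spec.kind == "actor_critic":
        return ActorCriticAgent(cfg.stag_hunt, cfg.actor_critic, player=player)
    if spec.kind == "neural":
        raise ValueError("the neural agent plays matrix games only")
    return SetStrategyHunter(spec.strategy(), player=player)


def _run_stag_hunt_session(
    cfg: ExperimentConfig,
    agents: tuple | None = None,
) -> tuple[list[dict], SessionSummary]:
    rng_setup = substream(cfg.seed, "setup")
    rngs = [substream(cfg.seed, "agent1"), substream(cfg.seed, "agent2")]
    if agents is None:
        agents = (
            _make_hunter(cfg.agent1, cfg, 1),
            _make_hunter(cfg.agent2, cfg, 2),
        )
    records: list[dict] = []

    for game_no in range(1, cfg.n_rounds + 1):
        state = random_setup(cfg.stag_hunt, rng_setup)
        for agent in agents:
            if isinstance(agent, ActorCriticAgent):
                agent.begin_game()
        path_len = [0, 0]
        while not state.terminal:
            moves = []
            hunts = []
            meta: list[dict] = []
            for i, agent in enumerate(agents):
                if isinstance(agent, ActorCriticAgent):
                    move, chosen, pol = agent.act(state, rngs[i])
                    meta.append({"choice": chosen, "p_stag": pol["stag"]})
                else:
                    move, chosen = agent.move(state, rngs[i])
                    meta.append({"choice": chosen})
                moves.append(move)
                hunts.append(chosen)
            prev_positions = (state.p1, state.p2)
            state, outcome = step_stag_hunt(
                state, moves[0], moves[1], cfg.stag_hunt,
                hunt_p1=hunts[0], hunt_p2=hunts[1],
            )
            for i, pos in enumerate((state.p1, state.p2)):
                if pos != prev_positions[i]:
                    path_len[i] += 1
            payoffs = (
                (outcome.payoff_p1, outcome.payoff_p2) if outcome else (None, None)
            )
            for i, agent in enumerate(agents):
                if isinstance(agent, ActorCriticAgent):
                    d_r, d_c = agent.learn(state, payoffs[i])
                    meta[i]["delta_reward"] = d_r
                    meta[i]["delta_cost"] = d_c
            records.append(
                {
                    "game": "stag_hunt",
                    "round": game_no,
                    "turn": state.turn,
                    "p1": list(state.p1),
                    "p2": list(state.p2),
                    "move_p1": moves[0],
                    "move_p2": moves[1],
                    "terminal": state.terminal,
                    "capture_type": state.capture_type,
                    "action_p1": outcome.action_p1 if outcome else None,
                    "action_p2": outcome.action_p2 if outcome else None,
                    "payoff_p1": payoffs[0],
                    "payoff_p2": payoffs[1],
                    "path_p1": path_len[0],
                    "path_p2": path_len[1],
                    "agent1": meta[0],
                    "agent2": meta[1],
                }
            )
        for i, agent in enumerate(agents):
            if isinstance(agent, SetStrategyHunter):
                agent.end_game(payoffs[i])
    return records, summarize(records)


def run_session(
    cfg: ExperimentConfig, agents: tuple | None = None
) -> tuple[list[dict], SessionSummary]:
    """Run one full session; deterministic given ``cfg.seed``.

    ``agents`` optionally injects pre-built (e.g. pre-trained or
    pre-lesioned) Stag Hunt agents; matrix-game agents are always built
    from the config.
    """
    if cfg.game in MATRIX_GAMES:
        if agents is not None:
            raise ValueError("agent injection is supported for stag_hunt only")
        return _run_matrix_session(cfg)
    return _run_stag_hunt_session(cfg, agents)


# ---------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------


def summarize(records: list[dict]) -> SessionSummary:
    """Counting summary, recomputable from a persisted log."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    game = records[0]["game"]
    if game in MATRIX_GAMES:
        aggressive = _AGGRESSIVE[game]
        n = len(records)
        esc1 = sum(r["action_p1"] == aggressive for r in records) / n
        esc2 = sum(r["action_p2"] == aggressive for r in records) / n
        alphabet = _ALPHABET[game]
        consistency = []
        for who in ("p1", "p2"):
            other = "p2" if who == "p1" else "p1"
            hist = [
                Round(r[f"action_{who}"], r[f"action_{other}"], r[f"payoff_{who}"])
                for r in records
            ]
            consistency.append(
                classify_strategy(hist, alphabet) if len(hist) >= 2 else None
            )
        injuries = {
            sev: sum(r["injury"] == sev for r in records)
            for sev in ("none", "mild", "serious")
        }
        return SessionSummary(
            game=game,
            n_rounds=n,
            escalation_p1=esc1,
            escalation_p2=esc2,
            cooperation_p1=1.0 - esc1,
            cooperation_p2=1.0 - esc2,
            mean_payoff_p1=sum(r["payoff_p1"] for r in records) / n,
            mean_payoff_p2=sum(r["payoff_p2"] for r in records) / n,
            consistency_p1=consistency[0],
            consistency_p2=consistency[1],
            injury_counts=injuries,
        )
    # stag hunt: summarize over terminal records
    finals = [r for r in records if r["terminal"]]
    n_games = len(finals)
    stag = sum(r["capture_type"] == "stag" for r in finals)
    hare = sum(r["capture_type"] == "hare" for r in finals)
    timeouts = sum(r["capture_type"] == "timeout" for r in finals)
    coop1 = stag / n_games
    coop2 = coop1
    return SessionSummary(
        game=game,
        n_rounds=n_games,
        escalation_p1=1.0 - coop1,
        escalation_p2=1.0 - coop2,
        cooperation_p1=coop1,
        cooperation_p2=coop2,
        mean_payoff_p1=sum(r["payoff_p1"] for r in finals) / n_games,
        mean_payoff_p2=sum(r["payoff_p2"] for r in finals) / n_games,
        stag_captures=stag,
        hare_captures=hare,
        timeouts=timeouts,
        stag_to_hare_ratio=(stag / hare) if hare else None,
        mean_turns=sum(r["turn"] for r in finals) / n_games,
        mean_path_length_p1=sum(r["path_p1"] for r in finals) / n_games,
    )


# ---------------------------------------------------------------------
# lesion study
# ---------------------------------------------------------------------


def run_lesion_study(
    cfg: ExperimentConfig, target: str = "cost"
) -> dict:
    """Paired intact/lesioned sessions sharing all randomness.

    Agent 1 must be the neural agent; the two arms differ only in the
    lesion clamp.  Returns both summaries and the escalation difference
    (lesioned minus intact).
    """
    if cfg.agent1.kind != "neural":
        raise ValueError("the lesion study requires a neural agent as player 1")
    from dataclasses import replace as _replace

    intact_cfg = _replace(cfg, agent1=_replace(cfg.agent1, lesion=None))
    lesion_cfg = _replace(cfg, agent1=_replace(cfg.agent1, lesion=target))
    _, intact = run_session(intact_cfg)
    _, lesioned = run_session(lesion_cfg)
    return {
        "target": target,
        "intact": intact,
        "lesioned": lesioned,
        "escalation_difference": lesioned.escalation_p1 - intact.escalation_p1,
    }


# ---------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------


def write_log(records: list[dict], path) -> None:
    """One JSON object per line, keys in insertion order."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r) + "\n")


def read_log(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def summary_to_json(summary: SessionSummary) -> str:
    return json.dumps(asdict(summary), indent=2)
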