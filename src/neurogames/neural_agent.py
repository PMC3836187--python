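"""Neuromodulated mean-firing-rate network for the matrix games.

The agent is a three-population rate network: Game-Dependent Input
Neurons (one per observable environmental state), two Action Neurons
(one per choice), and two Neuromodulatory Neurons — a Cost neuron
standing for serotonergic (5-HT) tone and a Reward neuron standing for
dopaminergic (DA) tone.  Input->action and input->neuromodulatory
connections are plastic; action<->action excitatory and inhibitory
connections are fixed.

Phasic neuromodulation is modeled as a gain applied to the sensory
(input->action) and intrinsic inhibitory (action->action) connections:
the gain is ``phasic_gain`` times the combined average activity of the
Cost and Reward neurons, 1 elsewhere.  High combined neuromodulation
thereby sharpens the winner-take-all competition (exploitive choice);
low neuromodulation leaves selection noise-dominated (exploratory).

Learning is a neuromodulated Hebbian rule driven by prediction errors:
the Reward neuron's afferents learn from the reward prediction error
(reward received minus Reward-neuron activity), the Cost neuron's from
the cost prediction error, and the winning action's afferents from the
opponent combination of the two.  Accurate predictions therefore leave
the weights unchanged.

A lesion clamps one neuromodulatory neuron to zero AND removes that
channel's perceived outcome component: a cost-lesioned agent neither
signals nor registers cost, mirroring reduced central 5-HT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LESION_TARGETS = ("cost", "reward")


@dataclass(frozen=True)
class NetworkParams:
    """Network constants.

    ``b`` is the salient-input amplitude and is game dependent: 0.75 for
    Hawk-Dove, 0.45 for Chicken.  ``rho`` is the firing-rate persistence
    constant, ``sigmoid_gain`` the slope of the activation sigmoid, and
    ``phasic_gain`` the amplification applied to sensory and inhibitory
    connections.  Noise ranges are uniform-draw bounds; ``noise_enabled``
    switches both noise sources off for exact-replay tests.
    """

    b: float = 0.75
    rho: float = 0.1
    input_noise_range: tuple[float, float] = (0.0, 0.25)
    synaptic_noise_range: tuple[float, float] = (-0.5, 0.0)
    sigmoid_gain: float = 5.0
    phasic_gain: float = 10.0
    alpha: float = 0.5
    alpha_prediction: float = 0.02
    settle_steps: int = 10
    weight_init_range: tuple[float, float] = (0.0, 0.1)
    weight_clip: tuple[float, float] = (0.0, 0.5)
    w_excite: float = 0.25
    w_inhibit: float = -0.5
    w_opponency: float = 1.0
    noise_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.phasic_gain <= 1.0:
            raise ValueError("phasic_gain must exceed 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.settle_steps < 1:
            raise ValueError("settle_steps must be >= 1")


@dataclass(frozen=True)
class Reinforcement:
    """Magnitudes of reward obtained and cost incurred in one round."""

    reward_received: float
    cost_received: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.reward_received) and np.isfinite(self.cost_received)):
            raise ValueError("reinforcement components must be finite")
        if self.reward_received < 0 or self.cost_received < 0:
            raise ValueError("reinforcement components are magnitudes (>= 0)")


def step_neuron(prev: float, I: float, params: NetworkParams) -> float:
    """One mean-firing-rate update: rho-persistent sigmoid of input."""
    sig = 1.0 / (1.0 + np.exp(-params.sigmoid_gain * I))
    return params.rho * prev + (1.0 - params.rho) * sig


def input_activity(
    salient_index: int,
    n_inputs: int,
    params: NetworkParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Input-neuron activities: b + noise at the salient state, noise elsewhere."""
    if not 0 <= salient_index < n_inputs:
        raise IndexError(
            f"salient_index {salient_index} out of range for {n_inputs} inputs"
        )
    lo, hi = params.input_noise_range
    if params.noise_enabled:
        n = rng.uniform(lo, hi, size=n_inputs)
    else:
        n = np.zeros(n_inputs)
    n[salient_index] += params.b
    return n


class NeuralAgent:
    """Adaptive network agent for Hawk-Dove or Chicken.

    ``actions`` orders the two choices; by convention the aggressive
    action (escalate / straight) comes first.  The observable state is
    an integer index supplied by the caller (game start, or the previous
    round's joint outcome).
    """

    def __init__(
        self,
        n_inputs: int,
        actions: tuple[str, str],
        params: NetworkParams,
        rng: np.random.Generator,
    ):
        if len(actions) != 2:
            raise ValueError("the network selects between exactly two actions")
        self.n_inputs = n_inputs
        self.actions = tuple(actions)
        self.params = params
        lo, hi = params.weight_init_range
        self.W_action = rng.uniform(lo, hi, size=(n_inputs, 2))
        self.W_cost = rng.uniform(lo, hi, size=n_inputs)
        self.W_reward = rng.uniform(lo, hi, size=n_inputs)
        self.s_actions = np.full(2, 0.5)
        self.s_cost = 0.5
        self.s_reward = 0.5
        self.lesioned: set[str] = set()
        # bookkeeping for the learning step
        self._last_inputs = np.zeros(n_inputs)
        self._last_choice: int | None = None

    # -- neuromodulation ------------------------------------------------

    def _clamp_lesions(self) -> None:
        if "cost" in self.lesioned:
            self.s_cost = 0.0
        if "reward" in self.lesioned:
            self.s_reward = 0.0

    def nm_tonic(self) -> float:
        """Combined average neuromodulatory activity (plasticity gain)."""
        return 0.5 * (self.s_cost + self.s_reward)

    def nm_phasic(self) -> float:
        """Phasic gain on sensory and inhibitory connections."""
        return self.params.phasic_gain * self.nm_tonic()

    def _syn_noise(self, rng: np.random.Generator) -> float:
        if not self.params.noise_enabled:
            return 0.0
        lo, hi = self.params.synaptic_noise_range
        return float(rng.uniform(lo, hi))

    def synaptic_input(
        self, neuron: str, n_prev: np.ndarray, rng: np.random.Generator,
        action_index: int = 0,
    ) -> float:
        """Total synaptic drive I onto one neuron from last-step activities.

        ``neuron`` is "action", "cost" or "reward"; for "action",
        ``action_index`` picks which of the two.  Sensory and inhibitory
        terms carry the phasic gain; all others have gain 1.
        """
        nm = self.nm_phasic()
        noise = self._syn_noise(rng)
        if neuron == "action":
            k = action_index
            other = 1 - k
            sensory = nm * float(self.W_action[:, k] @ n_prev)
            inhib = nm * self.params.w_inhibit * self.s_actions[other]
            excit = self.params.w_excite * self.s_actions[other]
            # fixed opponency projection (gain 1): the Reward neuron
            # drives the aggressive action (index 0), the Cost neuron
            # the cooperative one — DA invigorates risk taking, 5-HT
            # promotes withdrawal.
            drive = self.s_reward if k == 0 else self.s_cost
            opponency = self.params.w_opponency * drive
            return noise + sensory + inhib + excit + opponency
        if neuron == "cost":
            return noise + float(self.W_cost @ n_prev)
        if neuron == "reward":
            return noise + float(self.W_reward @ n_prev)
        raise ValueError(f"unknown neuron {neuron!r}")

    # -- decision -------------------------------------------------------

    def settle_and_select(
        self, salient_index: int, rng: np.random.Generator
    ) -> str:
        """Run the network to a decision for the given observable state.

        The network is stepped ``settle_steps`` times with fresh noise
        each timestep; the action whose neuron fires higher at the end
        is returned (exact ties break uniformly at random).
        """
        p = self.params
        n_prev = input_activity(salient_index, self.n_inputs, p, rng)
        for _ in range(p.settle_steps):
            I_a0 = self.synaptic_input("action", n_prev, rng, action_index=0)
            I_a1 = self.synaptic_input("action", n_prev, rng, action_index=1)
            I_c = self.synaptic_input("cost", n_prev, rng)
            I_r = self.synaptic_input("reward", n_prev, rng)
            self.s_actions = np.array(
                [
                    step_neuron(self.s_actions[0], I_a0, p),
                    step_neuron(self.s_actions[1], I_a1, p),
                ]
            )
            self.s_cost = step_neuron(self.s_cost, I_c, p)
            self.s_reward = step_neuron(self.s_reward, I_r, p)
            self._clamp_lesions()
            n_prev = input_activity(salient_index, self.n_inputs, p, rng)
        self._last_inputs = n_prev
        if abs(self.s_actions[0] - self.s_actions[1]) < 1e-12:
            choice = int(rng.integers(2))
        else:
            choice = int(np.argmax(self.s_actions))
        self._last_choice = choice
        return self.actions[choice]

    # -- learning -------------------------------------------------------

    def perceived(self, reinf: Reinforcement) -> Reinforcement:
        """Outcome as registered by the (possibly lesioned) agent."""
        return Reinforcement(
            0.0 if "reward" in self.lesioned else reinf.reward_received,
            0.0 if "cost" in self.lesioned else reinf.cost_received,
        )

    def reinforcement(self, reinf: Reinforcement) -> float:
        """Combined reinforcement R: reward surprise minus cost surprise.

        Zero whenever the Reward and Cost neurons exactly predicted the
        received magnitudes.
        """
        p = self.perceived(reinf)
        return (p.reward_received - self.s_reward) - (
            p.cost_received - self.s_cost
        )

    def apply_plasticity(self, reinf: Reinforcement) -> None:
        """Neuromodulated Hebbian update of the plastic connections.

        Only connections from the most active input neuron change.  The
        winning action's weight moves with the combined R; the Reward
        and Cost neurons' weights move with their own prediction errors,
        so each neuron's activity comes to predict its channel.
        """
        if self._last_choice is None:
            raise RuntimeError("apply_plasticity requires a preceding decision")
        p = self.params
        j = int(np.argmax(self._last_inputs))
        s_j = float(self._last_inputs[j])
        nm = self.nm_tonic()
        perceived = self.perceived(reinf)
        err_reward = perceived.reward_received - self.s_reward
        err_cost = perceived.cost_received - self.s_cost
        R = err_reward - err_cost
        k = self._last_choice
        lo, hi = p.weight_clip
        self.W_action[j, k] = np.clip(
            self.W_action[j, k]
            + p.alpha * nm * s_j * self.s_actions[k] * R,
            lo, hi,
        )
        self.W_reward[j] = np.clip(
            self.W_reward[j]
            + p.alpha_prediction * nm * s_j * self.s_reward * err_reward,
            lo, hi,
        )
        self.W_cost[j] = np.clip(
            self.W_cost[j] + p.alpha_prediction * nm * s_j * self.s_cost * err_cost,
            lo, hi,
        )

    # -- lesions --------------------------------------------------------

    def lesion(self, target: str) -> None:
        """Clamp the named neuromodulatory neuron (and its perception) off."""
        if target not in LESION_TARGETS:
            raise ValueError(f"unknown lesion target {target!r}")
        self.lesioned.add(target)
        self._clamp_lesions()

    def unlesion(self, target: str) -> None:
        """Remove a clamp; dynamics resume from the current weights."""
        if target not in LESION_TARGETS:
            raise ValueError(f"unknown lesion target {target!r}")
        self.lesioned.discard(target)
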