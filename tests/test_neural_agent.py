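"""Neural network dynamics: rate equations, plasticity, lesions."""

import numpy as np
import pytest

from neurogames.neural_agent import (
    NetworkParams,
    NeuralAgent,
    Reinforcement,
    input_activity,
    step_neuron,
)

QUIET = NetworkParams(noise_enabled=False)


def make_agent(params=QUIET, n_inputs=3, seed=0):
    return NeuralAgent(
        n_inputs, ("escalate", "display"), params, np.random.default_rng(seed)
    )


# ---------------------------------------------------------------------
# input and rate equations
# ---------------------------------------------------------------------


def test_salient_input_amplitude_hawk_dove(rng):
    n = input_activity(0, 3, QUIET, rng)
    assert n[0] == pytest.approx(0.75)
    assert n[1] == n[2] == 0.0


def test_salient_input_amplitude_chicken(rng):
    params = NetworkParams(b=0.45, noise_enabled=False)
    n = input_activity(1, 3, params, rng)
    assert n[1] == pytest.approx(0.45)


def test_input_noise_within_range(rng):
    params = NetworkParams(b=0.75)
    for _ in range(100):
        n = input_activity(0, 4, params, rng)
        assert np.all(n >= 0) and np.all(n <= 0.75 + 0.25)


def test_input_index_out_of_range(rng):
    with pytest.raises(IndexError):
        input_activity(5, 3, QUIET, rng)


def test_step_neuron_midpoint_fixed_point():
    assert step_neuron(0.5, 0.0, QUIET) == pytest.approx(0.5)


def test_step_neuron_scalar_oracle():
    # 0.1*0 + 0.9 * 1/(1+e^-5)
    expected = 0.9 / (1.0 + np.exp(-5.0))
    assert step_neuron(0.0, 1.0, QUIET) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.89398, abs=1e-5)


def test_step_neuron_saturation():
    assert step_neuron(1.0, 1e9, QUIET) == pytest.approx(1.0)


def test_rate_equation_fixed_point_convergence():
    """Iterating with constant I converges geometrically to the sigmoid."""
    for I in (-1.0, 0.0, 1.0):
        target = 1.0 / (1.0 + np.exp(-5.0 * I))
        s = 0.0
        for _ in range(250):
            s = step_neuron(s, I, QUIET)
        assert s == pytest.approx(target, abs=1e-9)


def test_synaptic_input_phasic_amplification(rng):
    """Sensory drive carries the 10x phasic gain; hand arithmetic oracle."""
    params = NetworkParams(noise_enabled=False, w_opponency=0.0, w_excite=0.0)
    agent = make_agent(params, n_inputs=1)
    agent.W_action[:] = 0.0
    agent.W_action[0, 0] = 0.5
    agent.s_cost = agent.s_reward = 0.4
    agent.s_actions[:] = 0.0
    n = np.array([0.75])
    I = agent.synaptic_input("action", n, rng, action_index=0)
    assert I == pytest.approx(10 * 0.4 * 0.5 * 0.75)  # = 1.5


def test_synaptic_input_unamplified_connection(rng):
    """Input->neuromodulatory connections have gain 1."""
    agent = make_agent(n_inputs=1)
    agent.W_cost[:] = 0.5
    I = agent.synaptic_input("cost", np.array([0.75]), rng)
    assert I == pytest.approx(0.5 * 0.75)  # = 0.375


def test_synaptic_input_empty_weights(rng):
    agent = make_agent(n_inputs=2)
    agent.W_cost[:] = 0.0
    assert agent.synaptic_input("cost", np.zeros(2), rng) == 0.0


# ---------------------------------------------------------------------
# reinforcement and plasticity
# ---------------------------------------------------------------------


def test_reinforcement_zero_when_predictions_accurate():
    agent = make_agent()
    agent.s_reward, agent.s_cost = 0.6, 0.3
    assert agent.reinforcement(Reinforcement(0.6, 0.3)) == pytest.approx(0.0)


def test_reinforcement_pure_surprises():
    agent = make_agent()
    agent.s_reward = agent.s_cost = 0.0
    assert agent.reinforcement(Reinforcement(1.0, 0.0)) == pytest.approx(1.0)
    assert agent.reinforcement(Reinforcement(0.0, 1.0)) == pytest.approx(-1.0)


def test_plasticity_hand_arithmetic():
    """Delta-w = alpha * nm * s_pre * s_post * R on the winning action."""
    params = NetworkParams(
        noise_enabled=False, alpha=0.1, weight_clip=(0.0, 10.0)
    )
    agent = make_agent(params, n_inputs=1)
    agent.W_action[:] = 0.0
    agent.W_cost[:] = 0.0
    agent.W_reward[:] = 0.0
    agent._last_inputs = np.array([0.8])
    agent._last_choice = 0
    agent.s_actions = np.array([0.6, 0.0])
    # nm = mean(s_cost, s_reward) = 0.5; R = (1 - 0.5) - (0 - 0.5) = 1
    agent.s_cost, agent.s_reward = 0.5, 0.5
    agent.apply_plasticity(Reinforcement(1.0, 0.0))
    assert agent.W_action[0, 0] == pytest.approx(0.1 * 0.5 * 0.8 * 0.6 * 1.0)
    assert agent.W_action[0, 0] == pytest.approx(0.024)


def test_plasticity_zero_when_R_zero():
    agent = make_agent()
    agent._last_inputs = np.array([0.8, 0.0, 0.0])
    agent._last_choice = 0
    agent.s_reward, agent.s_cost = 0.4, 0.2
    before = agent.W_action.copy()
    agent.apply_plasticity(Reinforcement(0.4, 0.2))
    assert np.allclose(agent.W_action, before)


def test_plasticity_frozen_under_double_lesion():
    agent = make_agent()
    agent.lesion("cost")
    agent.lesion("reward")
    agent._last_inputs = np.array([0.8, 0.0, 0.0])
    agent._last_choice = 0
    before = (
        agent.W_action.copy(), agent.W_cost.copy(), agent.W_reward.copy()
    )
    agent.apply_plasticity(Reinforcement(1.0, 1.0))
    assert np.allclose(agent.W_action, before[0])
    assert np.allclose(agent.W_cost, before[1])
    assert np.allclose(agent.W_reward, before[2])


def test_weights_clipped_to_range():
    params = NetworkParams(noise_enabled=False, alpha=100.0)
    agent = make_agent(params)
    agent._last_inputs = np.array([0.8, 0.0, 0.0])
    agent._last_choice = 0
    agent.s_actions = np.array([0.9, 0.0])
    agent.s_cost = agent.s_reward = 0.5
    agent.apply_plasticity(Reinforcement(5.0, 0.0))
    lo, hi = params.weight_clip
    assert lo <= agent.W_action[0, 0] <= hi


# ---------------------------------------------------------------------
# decision dynamics
# ---------------------------------------------------------------------


def test_potentiated_pathway_wins():
    params = NetworkParams(noise_enabled=False, w_opponency=0.0)
    agent = make_agent(params)
    agent.W_action[:] = 0.0
    agent.W_action[0, 0] = 0.5  # escalate pathway potentiated
    action = agent.settle_and_select(0, np.random.default_rng(0))
    assert action == "escalate"


def test_symmetric_weights_tie_breaks_both_ways():
    params = NetworkParams(noise_enabled=False, w_opponency=0.0)
    seen = set()
    for seed in range(20):
        agent = make_agent(params)
        agent.W_action[:] = 0.1  # identical pathways
        seen.add(agent.settle_and_select(0, np.random.default_rng(seed)))
    assert seen == {"escalate", "display"}


def test_activities_bounded_over_many_random_steps():
    """10,000 noisy settling steps keep every activity in [0, 1]."""
    agent = make_agent(NetworkParams(), n_inputs=5)
    rng = np.random.default_rng(99)
    steps = 0
    while steps < 10_000:
        agent.settle_and_select(int(rng.integers(5)), rng)
        steps += agent.params.settle_steps
        assert np.all(agent.s_actions >= 0) and np.all(agent.s_actions <= 1)
        assert 0 <= agent.s_cost <= 1 and 0 <= agent.s_reward <= 1


def test_lesion_clamps_and_reverses():
    agent = make_agent(NetworkParams(), n_inputs=3)
    rng = np.random.default_rng(1)
    agent.lesion("cost")
    agent.settle_and_select(0, rng)
    assert agent.s_cost == 0.0
    w_before = agent.W_cost.copy()
    agent.unlesion("cost")
    agent.settle_and_select(0, rng)
    assert agent.s_cost > 0.0
    assert np.allclose(agent.W_cost, w_before)  # no weight destruction


def test_lesion_halves_neuromodulation():
    agent = make_agent()
    agent.s_cost = agent.s_reward = 0.6
    intact = agent.nm_phasic()
    agent.lesion("cost")
    assert agent.nm_phasic() == pytest.approx(intact / 2)


def test_unknown_lesion_target():
    agent = make_agent()
    with pytest.raises(ValueError, match="noradrenaline"):
        agent.lesion("noradrenaline")


# ---------------------------------------------------------------------
# full-cycle oracle
# ---------------------------------------------------------------------


def oracle_cycle(W_action, W_cost, W_reward, s_actions, s_cost, s_reward,
                 salient, params, reward_received, cost_received):
    """Straight-line transcription of one decide->learn cycle, noise off."""
    sig = lambda I: 1.0 / (1.0 + np.exp(-params.sigmoid_gain * I))
    n = np.zeros(W_action.shape[0])
    n[salient] = params.b
    for _ in range(params.settle_steps):
        nm = params.phasic_gain * 0.5 * (s_cost + s_reward)
        I0 = (nm * (W_action[:, 0] @ n) + nm * params.w_inhibit * s_actions[1]
              + params.w_excite * s_actions[1] + params.w_opponency * s_reward)
        I1 = (nm * (W_action[:, 1] @ n) + nm * params.w_inhibit * s_actions[0]
              + params.w_excite * s_actions[0] + params.w_opponency * s_cost)
        Ic = W_cost @ n
        Ir = W_reward @ n
        s_actions = np.array(
            [params.rho * s_actions[0] + (1 - params.rho) * sig(I0),
             params.rho * s_actions[1] + (1 - params.rho) * sig(I1)]
        )
        s_cost = params.rho * s_cost + (1 - params.rho) * sig(Ic)
        s_reward = params.rho * s_reward + (1 - params.rho) * sig(Ir)
    choice = int(np.argmax(s_actions))
    j = int(np.argmax(n))
    nm = 0.5 * (s_cost + s_reward)
    err_r = reward_received - s_reward
    err_c = cost_received - s_cost
    R = err_r - err_c
    lo, hi = params.weight_clip
    W_action = W_action.copy()
    W_cost = W_cost.copy()
    W_reward = W_reward.copy()
    W_action[j, choice] = np.clip(
        W_action[j, choice] + params.alpha * nm * n[j] * s_actions[choice] * R,
        lo, hi)
    W_reward[j] = np.clip(
        W_reward[j] + params.alpha_prediction * nm * n[j] * s_reward * err_r,
        lo, hi)
    W_cost[j] = np.clip(
        W_cost[j] + params.alpha_prediction * nm * n[j] * s_cost * err_c,
        lo, hi)
    return W_action, W_cost, W_reward, s_actions, s_cost, s_reward, choice


def test_one_cycle_matches_straight_line_oracle():
    """Engine equals an independent transcription of the update equations."""
    params = QUIET
    agent = make_agent(params, n_inputs=4, seed=5)
    exp = oracle_cycle(
        agent.W_action, agent.W_cost, agent.W_reward,
        agent.s_actions.copy(), agent.s_cost, agent.s_reward,
        salient=2, params=params, reward_received=1.0, cost_received=0.25,
    )
    action = agent.settle_and_select(2, np.random.default_rng(0))
    agent.apply_plasticity(Reinforcement(1.0, 0.25))
    W_action, W_cost, W_reward, s_actions, s_cost, s_reward, choice = exp
    assert action == agent.actions[choice]
    np.testing.assert_allclose(agent.s_actions, s_actions, atol=1e-12)
    assert agent.s_cost == pytest.approx(s_cost, abs=1e-12)
    assert agent.s_reward == pytest.approx(s_reward, abs=1e-12)
    np.testing.assert_allclose(agent.W_action, W_action, atol=1e-12)
    np.testing.assert_allclose(agent.W_cost, W_cost, atol=1e-12)
    np.testing.assert_allclose(agent.W_reward, W_reward, atol=1e-12)
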