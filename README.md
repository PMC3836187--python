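# neurogames

Serotonin (5-HT) has been linked to cost assessment and harm aversion in
decision-making, in opponency with dopamine's (DA) role in reward seeking.
`neurogames` is a desk-scale simulator for studying that opponency in
socioeconomic games: neuromodulated adaptive agents play Hawk-Dove,
Chicken, and a spatial Stag Hunt against set-strategy and adaptive
opponents, with simulated serotonergic lesions, full experiment logging,
a Win-Stay-Lose-Shift / Tit-for-Tat strategy classifier, and a
hierarchical Bayesian latent-mixture model for detecting opposing
behavioral subgroups in escalation data. It is written for computational
neuroscientists and neuroeconomists who want a fast, fully seeded
sandbox for cost/reward-tradeoff hypotheses.

## Models

**Neuromodulated network (Hawk-Dove, Chicken).** A mean-firing-rate
network with Game-Dependent Input Neurons (one per observable state),
two Action Neurons, and two Neuromodulatory Neurons — Cost (5-HT) and
Reward (DA). Each neuron follows

    s_i(t) = ρ s_i(t−1) + (1 − ρ) σ(5 I_i(t)),
    I_i(t) = noise + Σ_j nm(t−1) w_ij(t−1) s_j(t−1),

with `nm` set to ten times the combined average Cost/Reward activity on
sensory and intrinsic-inhibitory connections (phasic amplification →
winner-take-all, exploitive choice) and 1 elsewhere. Plastic connections
learn a neuromodulated Hebbian rule Δw = α·nm·s_pre·s_post·R, where R is
a prediction error: the Reward neuron's afferents learn from
(reward − s_reward), the Cost neuron's from (cost − s_cost), and the
winning action's from their opponent combination. A fixed opponency
projection lets Reward drive the aggressive action and Cost the
cooperative one. A lesion clamps one neuromodulatory neuron to zero and
silences that channel's perceived outcome.

**Actor-Critic (Stag Hunt).** Three state tables — Reward Critic, Cost
Critic, Actor — keyed by binned Manhattan distances of both players to
the stag and nearest hare. Critics learn by the delta rule
δ(t) = r(t) + V(s,t) − V(s,t−1); the Actor is updated with the summed
reward and cost deltas in advantage form, and the stag/hare choice is
drawn from a SoftMax over the Actor's two preferences.

**Latent-mixture model.** Per subject i and condition c,
logit(p_ic) = baseline_i + effect_{z_i,c}, with latent group z_i ∈
{decrease, increase}, sign-constrained Gaussian effect priors, and
binomial likelihoods; sampled by Metropolis-within-Gibbs with an exact
two-point Gibbs draw of each group label.

## Worked example

```python
import numpy as np
from neurogames import AgentSpec, ExperimentConfig, run_lesion_study

cfg = ExperimentConfig(
    game="hawk_dove",
    agent1=AgentSpec("neural"),
    agent2=AgentSpec("aggressive", p_aggress=1.0),
    n_rounds=500,
    seed=0,
)
result = run_lesion_study(cfg, target="cost")
print(f"intact escalation:   {result['intact'].escalation_p1:.3f}")
print(f"lesioned escalation: {result['lesioned'].escalation_p1:.3f}")
print(f"difference:          {result['escalation_difference']:.3f}")
```

prints

```
intact escalation:   0.144
lesioned escalation: 0.998
difference:          0.854
```

Against an opponent that always escalates, the intact agent learns that
fighting brings injuries and backs down (14% escalation), while the
cost-lesioned agent — which neither signals nor perceives cost —
escalates on essentially every round. The difference is the simulated
serotonergic-lesion effect: loss of cost assessment produces
perseverant, risk-taking behavior.

The same machinery is available from the shell:

```
neurogames simulate --config experiment.yaml --seed 3 --out results/
neurogames lesion   --config experiment.yaml --rounds 500 --out results/
neurogames synth-subjects --subjects 8 --trials 100 --out choices.csv
neurogames fit-cognitive  --data choices.csv --seed 2
```

where `experiment.yaml` names the game, both agents, and any non-default
game parameters:

```yaml
game: hawk_dove
n_rounds: 500
seed: 3
agent1: neural
agent2:
  kind: aggressive
  p_aggress: 1.0
hawk_dove:
  p_serious: 0.75
```

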