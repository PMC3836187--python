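# Methods

This note documents the models implemented in `neurogames`, the
parameter choices that matter, what the synthetic data emulate, and the
numerical conventions — in enough detail that every simulated result
can be traced to a modeling decision.

## Game environments

All three games are pure state machines; every stochastic branch draws
from an explicitly passed, named random stream, so sessions are
reproducible bit-for-bit from a master seed.

**Hawk-Dove.** Two players contest a resource of value V (default 1.0).
Both display → each gets V/2. One escalates → the escalator takes V,
the other 0. Both escalate → a fight: one severity is drawn per fight
(serious with probability `p_serious`, mild otherwise) and applied to
both combatants, each receiving V/2 minus the injury cost. Defaults:
mild cost 0.75·V, serious cost 1.5·V, `p_serious` 0.25 (benign) or 0.75
(harsh). These preserve the ordinal structure — fighting in a split is
net-negative, serious injuries dominate mild ones — while remaining
config parameters. The share-then-injure convention (injury applied on
top of a half share) is the standard Hawk-Dove reading. The spatial
approach phase is abstracted away: the decision variable is the
simultaneous binary choice, and the grid size field exists only for
display purposes. Choices are simultaneous; a sequential variant is not
implemented.

**Chicken.** Deterministic payoffs: swerve/straight → (0, max); both
swerve → (min, min); both straight → (collision, collision). Defaults
max 6, min 2, collision −10, with the lone-swerver payoff fixed at 0 by
definition.

**Stag Hunt.** A 5×5 board with both players, one stag (payoff 5 each,
cooperative capture) and two hares (payoff 1, solo capture), timeout 50
turns, all tokens placed uniformly at random on distinct cells. Moves
are 4-connected or stay, simultaneous, with off-board moves clamped.
Capture contact is Manhattan distance ≤ 1 (on or next to the token).
Hare captures are checked before stag when both would fire on a turn;
two simultaneous hare captures both pay (hunts are independent). The
stag falls only when both players are in contact on the same turn.
Capture honors declared pursuit: when the engine is told what each
player hunts this turn, a declared stag hunter does not pick up a hare
in passing. This matters quantitatively: with intent-blind adjacency
capture, about 70% of two-committed-stag-hunter games abort on an
accidental hare, which destroys the game's defining risk structure (the
cooperative equilibrium becomes unreachable in practice). The
intent-free call remains available and captures on any contact.

## The neuromodulated network

Populations: Game-Dependent Input Neurons (one per observable state —
for the matrix games, the previous round's joint outcome plus a
game-start state, 5 in total), two Action Neurons, and Cost (5-HT) and
Reward (DA) Neuromodulatory Neurons.

Rate dynamics: s(t) = ρ·s(t−1) + (1−ρ)·σ(5I), ρ = 0.1. Salient input
amplitude b = 0.75 (Hawk-Dove) or 0.45 (Chicken); input noise uniform
on [0, 0.25] per neuron per timestep; synaptic noise uniform on
[−0.5, 0] per neuron per timestep. The network settles for 10 timesteps
per decision and the action with the higher final activity is taken
(exact ties break uniformly). A `noise_enabled=False` switch exists for
exact-replay tests.

Connectivity and gains:

- plastic input→action, input→cost, input→reward weights, initialized
  uniformly on [0, 0.1] and clipped to [0, 0.5];
- fixed intrinsic action↔action excitation (0.25) and inhibition
  (−0.5);
- a fixed opponency projection with gain 1: Reward → aggressive action,
  Cost → cooperative action (weight 1.0). This realizes the base
  assumption that DA activation invigorates risk taking while 5-HT
  activation promotes withdrawal, and it is the causal route by which
  reward-dominant neuromodulatory states produce escalation;
- phasic gain: sensory (input→action) and inhibitory action→action
  drives are multiplied by 10 × the mean Cost/Reward activity; all
  other connections have gain 1. High combined neuromodulation thereby
  sharpens the winner-take-all competition (exploitive choice), low
  neuromodulation leaves choice noise-dominated (exploratory).

Learning. After each round the game payoff is decomposed into reward
(gross resource gained) and cost (injury incurred) magnitudes. Only
connections from the most active input neuron update, by
Δw = rate · nm · s_pre · s_post · err with nm the mean Cost/Reward
activity. The error is channel-specific: (reward − s_reward) for the
Reward neuron's afferents, (cost − s_cost) for the Cost neuron's, and
their opponent combination R = (reward − s_reward) − (cost − s_cost)
for the winning action's afferents. Accurate predictions leave all
weights unchanged. A single shared R for all three targets was
considered and rejected: it makes the Cost neuron's weights *shrink*
whenever cost surprises occur, so cost expectation could never form.

Two learning rates matter and their separation is deliberate: action
weights use α = 0.5, prediction (Cost/Reward) weights use 0.02. The
prediction channels must integrate over tens of rounds; while they lag,
the mean prediction error experienced under a candidate habit equals
that action's expected net value, and the fast action weights integrate
exactly this signal. If predictions adapt as fast as preferences, the
error vanishes before any habit consolidates and habit formation
degenerates to a coin flip. The weight ceiling of 0.5 keeps the
amplified sensory drive commensurate with the intrinsic and
neuromodulatory drives; a ceiling far above it makes any acquired habit
noise-proof and removes the explore/exploit continuum the phasic
mechanism is supposed to express.

Lesions. `lesion("cost")` clamps the Cost neuron's activity to zero and
silences perceived cost in the learning rule (the lesioned channel
neither predicts nor registers its outcome); symmetrically for
`lesion("reward")`. Lesions are reversible and never destroy weights.
A double lesion freezes plasticity entirely (nm = 0).

Study conditions for the two headline network results:

- *Lesion study*: opponent = aggressive (always escalate), 500 rounds,
  paired arms sharing all random streams. Escalation must reliably
  incur injury for cost assessment to be decision-relevant: against a
  random opponent escalation has positive expected payoff even in the
  harsh environment (+0.09 per round), so intact escalation is a
  legitimate equilibrium there and the contrast is uninformative.
- *Reward-vs-cost gating*: adaptive self-play (network vs network),
  500 rounds per seed, pooled over 20 seeds. Self-play sustains both
  behavioral regimes within and across sessions, which the conditional
  escalation proportions require; against an i.i.d. opponent every
  state has identical statistics and sessions collapse into a single
  habit.

## The Actor-Critic

State features: Manhattan distances of self and of the other player to
the stag and to the nearest hare, binned {0–1, 2–3, ≥4} → 3⁴ = 81
states. Including the partner's distances is what makes the agent
sensitive to the partner's apparent commitment. Tables are dicts with
initial value 0.0 for unvisited entries, serializable to flat text.

Per turn: the SoftMax of the Actor's two preferences (no temperature
parameter; unit scale) gives P(stag), a target is sampled fresh each
turn, and the agent takes the greedy Manhattan-descent move toward it
(ties uniform). After the board advances, critics update the previous
state's value by lr·δ with δ = r + V(now) − V(prev) and V(terminal) = 0.
The reward signal is the payoff obtained (zero on non-terminal turns);
the cost signal is the negated expected payoff of the chosen target on
terminal turns where that expectation went unfulfilled (perceived
loss). The Actor receives δ_reward + δ_cost in advantage form: chosen
preference += lr·(1−P[chosen])·δ, other −= lr·P[other]·δ.

Learning rates are 0.8 (critics) and 0.5 (actor). The coarse binning
means most transitions stay within a feature state and carry zero
delta; value is transported only at bin boundary crossings, and small
critic rates cannot propagate terminal payoffs back to opening states
within the 300-game sessions used throughout. The printed-form
alternatives — unit-rate critic updates of the *current* state, and
identical positive updates to both actor preferences — diverge under
constant reward and erase the SoftMax contrast respectively, and are
not implemented.

Policy evaluation: "the policy at the start state" is measured as the
median of P(stag) over the featurized start states of 100 fresh random
openings. The median reflects the typical opening; a mean is dominated
by rare corner configurations whose feature states are never visited
during training and sit at the uninformed 0.5 prior.

## Opponents and the strategy classifier

Matrix-game set strategies: fixed actions, unbiased random, WSLS
(repeat after a win — payoff strictly above a configurable threshold,
default 0, the minimum non-negative outcome — else switch), T4T (copy
the opponent's last action), and an aggressive opponent playing the
confrontational action with probability `p_aggress`. WSLS and T4T open
with the cooperative action, the convention in the iterated-game
literature; fixed strategies open with their fixed action. Stag Hunt
set strategies choose a target (always stag, always hare, random per
turn, or WSLS over games) and path greedily.

The classifier scores a realized history against both templates: from
round 2 on, each template predicts a move from the history so far, and
the score is the fraction of matches. Scores depend only on win/loss
labels and copied actions, hence are invariant to payoff scaling. Both
a fixed aggressive opponent and an escalation-biased adaptive agent are
available as "aggressive" conditions; the fixed variant is the default
in the experiments module.

## Experiments module

A master seed fans out through named substreams (setup, agent1, agent2,
game, eval) via hashed seed sequences, so paired designs share
environment randomness exactly. Every decision appends one flat-dict
TrialRecord; logs are JSON-lines; summaries (escalation/cooperation
proportions, mean payoffs, injury counts, strategy consistencies,
stag-to-hare capture ratio, path lengths) are pure functions of the
records and reproduce exactly from a persisted log. The CLI exposes
`simulate`, `tournament`, `lesion`, `summarize`, `synth-subjects` and
`fit-cognitive` subcommands.

## The latent-mixture model

Data: per subject × condition escalate counts k out of n trials, the
first condition being each subject's baseline. Model:
logit(p_ic) = baseline_i + effect_{z_i,c} for non-baseline conditions,
z_i ∈ {decrease, increase} with a uniform prior, binomial likelihood.
Priors: baseline ~ N(0, 1.5²) on the logit scale (weakly informative on
the probability scale); effect magnitudes half-N(0, 1²) with the sign
constraint effect_decrease < 0 < effect_increase. The constraint both
identifies the groups as "decrease" vs "increase" relative to baseline
and prevents label switching (verified: no post-burn-in draw violates
the ordering). Two groups are fixed; the unbiased "middle ground" is
represented as low-confidence assignment (posterior max ≤ 0.75 →
unassigned), not as a third mixture component.

Sampler: per-parameter Gaussian random-walk Metropolis (proposal sd
0.3) for baselines and effects — each step evaluates only the affected
subject rows — and an exact two-point Gibbs draw for each z_i. Default
controls are 4 chains × 5000 draws with 2000 burn-in; the test suite
and the acceptance script use 3 × 1500/500, which recovery experiments
show is ample for the 8-subject scale. Convergence is monitored by the
split-chain R-hat (threshold 1.01) and reported on the summary, never
fatal. Sampling is fully deterministic given a seed. The group-index
summary (posterior mean on the 1–2 scale with central 95% credible
bounds) matches the usual group-membership plot.

Synthetic subjects: the generator's defaults are the study scale — 8
subjects, 4 per group, baselines ~ N(0, 0.5) on the logit scale,
condition effects ±1.5 logits, 100 trials per cell, two conditions
(baseline, treatment) — with ground-truth latents stored alongside.
What this emulates is the *structure* of a small within-subject
manipulation study: stable individual baselines and an opposing-sign
condition effect. What it does not emulate: trial-order effects,
learning or fatigue within a session, overdispersion beyond binomial
noise, and condition effects on anything but the escalation logit.
Recovery results on these data therefore show the model identifies
well-separated opposing subgroups at this sample size; they do not show
robustness to model misspecification.

## Numerical conventions and limitations

- SoftMax uses max-subtraction; activities are hard-bounded in [0, 1]
  by construction of the rate equation.
- Exact action-activity ties (probability ~0 with noise on) break
  uniformly from the decision stream.
- Plastic weights are clipped to a non-negative range; the clip is a
  stabilization device, not a biological claim.
- The network agent's observable state is the previous joint outcome
  only; longer histories, and any spatial component of the matrix
  games, are out of scope.
- The Actor-Critic has no eligibility traces or discounting (implicit
  γ = 1), and its cost channel covers only forfeited expectations, not
  effort or path length.
- All reported behavioral contrasts are properties of the stated study
  conditions (opponents, round counts, payoff defaults); other
  opponents or payoff structures can legitimately produce different
  equilibria (e.g. sustained intact escalation against opponents that
  reward it).
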