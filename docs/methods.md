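# Methods

`transtep` studies how agents learn probabilistic action→state transition
maps and how that learning expresses in choice. This note records the
models, the synthetic study conditions, the numerical choices, and what the
package's validation does and does not establish.

## Tasks

**One-step revaluation.** Two actions each lead to one of three states with
fixed frequencies out of 10 forced choices per action (common 5, uncommon
3, rare 2; the rare state is shared by both actions). Outcome sequences are
exact permutations of the scheduled counts, not i.i.d. draws — the task
presents frequencies as facts, and scoring logic depends on them exactly. A
practice block uses 16-of-20 common outcomes. The test phase queries, per
block, which action most often produced each state; the rare-state query
has no optimal action and is never scored. A block counts as learned only
when **both** scored queries are answered optimally, so a uniformly random
responder gets a block right with probability 0.25 and expects
5 × 0.25 = 1.25 correct blocks of 5. Five experimental blocks carry
distractor-condition labels (`neutral`, `negative/positive ×
common/rare`); image content is not modeled, the labels exist as a
condition random effect.

**Two-step task.** First-stage actions lead to one of two second-stage
states with common probability 0.7. Second-stage reward probabilities
follow independent Gaussian random walks (s.d. 0.025) reflected at
[0.25, 0.75]; default session length 200 trials. These schedule constants
are the paradigm's conventional values and are configurable.

**Multi-goal pursuit.** Two actions, two outcome states (reward,
punishment). The four P(state | action) drift independently (Gaussian s.d.
0.04, reflected at [0.1, 0.9]); states are reached independently, so a
trial may reach both, one, or neither. Each trial instructs a goal:
seek-reward (+1 point iff the reward state is reached) or avoid-punishment
(−1 iff the punishment state is reached); states the instruction does not
mention have no consequence. Defaults: 180 trials, balanced randomized goal
order. The walk parameters and trial count are this package's choices of a
plausible regime for a changing environment, not values taken from a
specific experiment.

## Agents

**ISTL (incremental state-transition learning).** Beliefs P(s|a) start at
0.5. After taking `a` and reaching `s`, P(s|a) moves toward 1 by
γ·(1 − P(s|a)) — a state prediction error scaled by learning rate γ — and
the complement is set so the row sums to 1. The untaken action's beliefs
decay toward the 0.5 prior; we use the same rate γ for this decay (the
decay rate is genuinely open; it is configurable, and sharing γ keeps the
model one-parameter). In the multi-goal variant each of the chosen
action's two reach probabilities moves independently toward its binary
outcome; whether the untaken action also decays is configurable
(default on).

**Typical (counting) learner.** A running tally C[s, a] of observed
transitions; the inferred matrix is the candidate whose common transitions
(diagonal vs off-diagonal tallies) dominate, with the element-wise average
on ties.

**Hybrid two-step chooser.** Q_MB(a) = Σ_s P(s|a)·max_a′ Q2(s, a′).
First-stage policy: softmax over β_MB·Q_MB + β_MF·Q_MF +
π_stick·1[a = previous a]. Second stage: softmax(β₂·Q2(s,·)). Model-free
learning: the chosen value moves toward its target with rate α (so the
chosen-value decay is the complement 1 − α), first-stage targets are the
trial's reward directly (TD with λ = 1, not exposed as a parameter), and
every unchosen value decays toward 0 by (1 − D). Q2 initializes at 0.
π_stick is the paradigm's standard perseveration nuisance parameter; set it
to 0 to disable.

**Multi-goal integrated model.** Four strategies: model-based values gate
learned reach probabilities by the instructed-goal vector ((1, 0) on seek
trials, (0, −1) on avoid trials); goal perseveration uses the fixed vector
(1, −1); a model-free value per action tracks points with rate α_MF; action
perseveration adds a stay bonus. Strategy values combine as a weighted sum
(β_MBreward, β_MBpunish, β_GPreward, β_GPpunish, β_MF, β_AP) into a
softmax. Softmax temperatures are absorbed into the β weights throughout —
a separate temperature would be unidentifiable against them.

## Hierarchical fitting (iterative importance sampling)

Each iteration draws K parameter vectors from group-level priors (Beta for
rates, Normal for signed weights, Gamma for non-negative weights; naive
starting values Beta(1,1), Normal(0,10), Gamma(1,1)), weights every draw by
each subject's choice likelihood, scores each subject's log evidence as the
log mean likelihood, and refits the group priors by weighted moment
matching over the pooled subject-weighted draws. Iterations stop when total
evidence improves by less than 0.5 nats (defaults: K = 5000, ≤ 30
iterations; all configurable). Desk-scale validation runs in this
repository use K = 3000 with a 12000-draw final pass, sized so a full
200-subject recovery completes in minutes on one core.

Numerical safeguards: importance weights are computed with max-subtraction;
per-subject effective sample size (ESS) is monitored and K escalates
(doubling, capped at 4K) when the minimum ESS drops below 5 *after* the
first two iterations — under naive priors the first passes are expectedly
degenerate and tightening the prior is the cure, not more samples. After
convergence a final weighting pass with 2K draws under the converged prior
produces the reported per-subject posterior-mean estimates (means, not
modes, for stability) and evidences. Model comparison is the difference in
total log evidence (a log Bayes factor under the empirical-Bayes priors).
Non-convergence and weight degeneracy are flagged on the result, never
raised.

**Generating conditions for recovery studies.** `moderate_prior("istl")`
defines the simulate-and-refit study population: γ, α, D ~ Beta(2, 2);
β_MB ~ Gamma(k = 2.2, θ = 2.2) (mean ≈ 4.8 with a genuine low tail);
β_MF ~ N(1.0, 0.7); β₂ ~ Gamma(5, 1); π_stick ~ N(0.2, 0.3). These were
chosen by a design analysis, not by eyeballing test outcomes: a
Bayes-optimal oracle (importance sampling with 60k draws under the true
generating prior) shows that γ is only identifiable from 200 trials when
model-based control is strong enough for beliefs to express in choices —
under weaker β_MB regimes *no* estimator recovers γ at r ≥ 0.5, while under
this population the oracle ceiling is ≈ 0.6 and the hierarchical fitter
reaches r ≈ 0.57–0.65. The low-β_MB tail is kept deliberately: restricting
to subjects with fitted β_MB > 2.5 then visibly improves γ recovery, the
subsampling phenomenon the analysis pipeline replicates. The β_MB-threshold
grid search uses 0.5-unit increments.

`stable_population_prior("istl")` is used for posterior-predictive cohorts
and emulates a population *fitted* in a stable environment: γ ~
Beta(1.5, 6) (mean ≈ 0.2), β_MB ~ Gamma(k = 1.3, θ = 3.5) (strongly
right-skewed with substantial mass near zero), β_MF ~ N(0.8, 0.4)
(shrunken dispersion, as hierarchical estimates show). The distributional
shape matters for the model-basedness regression signatures, in two ways
worth recording. First, the positive β_MB coefficient is carried by the
near-zero-β_MB subjects: compliance saturates once model-based control
dominates, so a population without barely-model-based members shows only a
weak slope. Second, the γ sign depends on where γ is centered: with γ low,
faster learning erodes compliance (negative coefficient); in populations
with γ centered near 0.5, strong model-based control amplifies post-rare
belief flips so thoroughly that the β_MB sign itself reverses. The package
treats the low-γ, skewed-β_MB population as the empirically relevant
regime for these checks.

## Model-agnostic signatures and analyses

**Model-basedness** is the proportion of post-rare-transition trials that
follow model-based prescriptions: switch after a rewarded rare transition,
stay after an unrewarded one. It is NaN (not an error) for logs without
rare transitions. A pure model-free agent scores ≈ 0.40, *below* 0.5:
reward-driven staying actively violates the prescriptions rather than
ignoring them.

**Stay-probability tables** report P(repeat first-stage action) by previous
transition type × reward, averaged over per-participant proportions.

**Trait–parameter regressions** are OLS on standardized variables
(statsmodels), two-sided t tests, α = 0.05. **Mediation** runs the three
regressions trait~γ, trait~β_MB, trait~γ+β_MB on log-transformed
parameters (their relation is nonlinear on native scales; non-positive
values raise with guidance) and declares full mediation when γ is
significant alone, non-significant jointly, and β_MB remains significant
jointly.

**Optimality sweeps** play `n_reps` independent games per learning rate
with all other parameters fixed, report min–max-normalized mean total
reward, and re-simulate a refined grid around the coarse argmax.
Non-swept parameters come from `group_fixed_params`: medians for
distributions with |skew-test z| > 4, means otherwise, and β_MB set high
(97.5th percentile) so the sweep isolates the learning-rate channel. In
the stable two-step task the reward differences across γ are genuinely
small (the model-based advantage itself is modest), so validation uses
≥ 20 000 plays per grid point at 120 trials; in the changing multi-goal
task the curve is strongly peaked (optimum near γ ≈ 0.2) and slow learning
(γ = 0.05) is clearly penalized.

## Bayesian inference for the revaluation study

The block-correctness regression is a hierarchical logistic model: grand
intercept (prior N(0.6, 1) on the log-odds scale), participant and
condition random effects (non-centered, s.d. ~ Uniform(0, 3) sampled via a
logit transform with Jacobian), three fixed trait effects (N(0, 3)).
Sampling is plain Hamiltonian Monte Carlo with analytic gradients:
dual-averaging step-size adaptation to a 0.9 target acceptance, jittered
trajectories of ~25 leapfrog steps, and a diagonal mass matrix estimated
from a warmup window; 4 chains × 500 draws by default. (The max-tree-depth
control of tree-building samplers has no analog in fixed-length HMC.)
Categorical effect draws are sum-to-zero rescaled — per draw, each family's
mean moves into the intercept, leaving every linear predictor unchanged —
before summarization. Divergent transitions, r-hat ≥ 1.1, and ESS < 1000
are flagged on the result, never silently dropped; light two-chain
configurations used in fast calibration runs routinely flag intercept and
variance ESS while leaving trait-effect inference unaffected.

Decisions use a ROPE of ±0.01 (10% of the baseline-effect posterior s.d.,
recomputable) against the 95% highest-density interval: "significant" when
disjoint, "not-significant" when the HDI sits inside the ROPE, otherwise
undecided. The HDI is the narrowest interval containing 95% of sorted
draws; posterior modes come from a Gaussian KDE on a 256-point grid.

**EFA.** Items are standardized; extraction is maximum-likelihood
(scikit-learn) with varimax, followed by an in-package promax (power 4):
oblique target = signed fourth power of the varimax loadings,
least-squares transform column-normalized to unit factor variances, factor
correlations Φ = (UᵀU)⁻¹. Factor scores use the regression method
(R⁻¹ × structure matrix). Bartlett sphericity, KMO adequacy, and parallel
analysis (95th percentile of eigenvalues from simulated uncorrelated data,
counting the leading run of exceedances) are computed in-package; a
non-positive-definite correlation matrix is eigenvalue-smoothed with a
warning.

## Synthetic cohorts

`CohortSpec` plants: three latent trait factors (default pairwise r = 0.3),
questionnaire items loading 0.6 on their own factor (Likert-discretized at
(−1.5, −0.5, 0.5, 1.5)), covariates (age, sex, IQ), and trait→parameter
couplings applied on transformed scales — logit for rates, log for
non-negative weights — so native-scale range invariants hold by
construction. Ground truth (couplings, loadings, seeds) is stored
separately from the generated tables and suffices to recompute every
planted effect independently of the pipeline. Revaluation-study
correctness is generated directly from the logistic ground-truth model
(baseline 60% correct, participant s.d. 0.5, condition s.d. 0.2, planted
trait log-odds slopes), because that is the unit the downstream regression
consumes. Mediation cohorts plant either a full chain
(trait ← β_MB ← γ) or a direct γ→trait effect with independent β_MB.

**What the generators do not emulate:** real questionnaire psychometrics
beyond a planted loading structure; response omissions and exclusions;
session effects, reaction times, or any within-trial dynamics; couplings
beyond linear-on-transformed-scale. Passing tests therefore demonstrate
that the pipeline recovers what it plants under the model's own
assumptions — they do not certify behavior on empirical datasets.

## Problem sizes and determinism

Validation sizes are chosen for desk-scale runs on one core: recovery
studies 200 subjects × 200 trials (K = 3000), model recovery 100 × 200,
sweeps 20 000 plays per grid point × 120 trials, hierarchical-logistic
calibration 20 replicates at n = 174, EFA at n = 1000. Every stochastic
path takes an explicit integer seed (numpy `default_rng` /
`SeedSequence`); identical seed and configuration reproduce outputs
exactly, and CLI runs record a manifest (command, options, version) next
to their outputs.

## Known limitations

- Fixed-length HMC mixes the intercept and variance parameters more slowly
  than tree-building samplers; trait-effect inference is unaffected but
  intercept ESS can fall short in short runs (and is flagged).
- Importance-sampling estimates degrade for subjects whose posteriors are
  far from the group (low ESS); escalation mitigates but cannot remove
  this.
- The Typical model's belief path is data-determined, so its evidence
  advantage on Typical-generated data is modest when the ISTL model can
  imitate counting behavior with a suitable γ.
- The two-step optimality curve is shallow by construction; claims about
  its interior shape beyond "γ = 1 is suboptimal" would need far more than
  20 000 plays per point.
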