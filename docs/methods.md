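# Methods

## The scientific setting

`ergochoice` models a two-condition risky-choice experiment in which the
*dynamic* of in-game wealth is the manipulated variable. In the additive
condition, nine stimuli add fixed increments to wealth (−428 … +428 DKK,
equally spaced); in the multiplicative condition, nine stimuli multiply
wealth by growth factors equally spaced on a log scale between halving and
doubling (2^(k/4), k = −4…4). Multiplicative wealth changes are
non-ergodic: the expectation value of the change and its time average
disagree, so an agent who cares about the long-run growth of their wealth
must adapt their utility function to the dynamic — linear utility
maximizes the time-average growth rate under additive dynamics,
logarithmic utility under multiplicative dynamics ("time optimality").
The package builds the paradigm, simulates cohorts of utility-maximizing
agents, and performs the two model-based analyses that test time
optimality: hierarchical Bayesian estimation of dynamic-specific risk
aversion, and latent-mixture model selection among three utility families.

## Paradigm construction

**Passive sequences.** Each of the 9 stimuli appears exactly 37 times
(333 trials). A random permutation is accepted only if the running wealth
stays strictly inside the open interval (0, 5000) DKK; rejected
permutations are redrawn (capped at 10^5 attempts, after which the
generator raises with the attempt count). Because every stimulus appears
equally often, wealth returns exactly (additive) or to floating tolerance
(multiplicative) to the 1000 DKK endowment at trial 333; one further
uniformly drawn stimulus leaves the session at a random wealth. Measured
acceptance rates for the canonical sets are a few percent, so generation
takes well under a second.

**Active sessions.** All gambles are mixed (one gain, one loss; the
neutral stimulus is excluded), giving 4 × 4 = 16 gambles. Ordered
left/right pairs whose four outcome values are pairwise distinct number
16 × 9 = 144; each is presented twice (288 trials), plus 24 statewise-
dominated "no-brainer" pairs sampled without replacement from the 48
dominated pairs that share exactly one stimulus, with random orientation —
312 trials in total, shuffled reproducibly from a seed. An unordered-pair
mode (72 unique pairs, each shown in both orientations twice) is available
behind a flag.

**Discrepant trials.** A trial is discrepant when a linear-utility and a
log-utility agent prefer different sides: the two expected-change criteria
must be strictly nonzero and of opposite sign. Ties are detected at a
relative tolerance of 1e−9 *scaled by the individual per-outcome changes*,
not by the (cancelling) means: the canonical factor set contains
structurally tied pairs — e.g. {2, 1/2} versus {√2, 1/√2}, both with mean
log factor exactly zero — that float arithmetic would otherwise flag
through 1e−16 residues. With tie handling, the canonical multiplicative
session has 14 discrepant ordered pairs = 28 of 312 trials (even,
session-constant, and wealth-invariant, since both criteria's orderings
are wealth-free under multiplicative dynamics); the additive session has
12 discrepant trials at the 1000 DKK reference wealth. The reference
wealth for discrepancy and for CP_log is the fixed active-session wealth
(1000 DKK for synthetic data).

## Utility models and choice rule

Three utility families over wealth changes are compared:

* **PT** (prospect theory): δu = (δx)^α_gain for gains,
  −λ·|δx|^α_loss for losses (zero at δx = 0), with α_gain, α_loss ∈ (0,1)
  and λ ∈ (1,5); no probability weighting, since all outcome
  probabilities are 0.5 by design.
* **ISO** (isoelastic/CRRA): u(x) = (x^{1−η} − 1)/(1 − η) over absolute
  wealth, with an explicit logarithmic branch at η = 1 (exactness over a
  numeric limit; continuity is property-tested at |η−1| = 1e−8).
* **TIME** (time-optimal): the isoelastic utility at the dynamic's
  growth-optimal risk aversion — η = 0 additive, η = 1 multiplicative.
  ISO at η ∈ {0, 1} coincides with TIME to machine precision.

Wealth is held fixed during an active session at its end-of-passive value;
outcomes are hidden and realized only at day's end, so no within-session
updating occurs. Choices are Bernoulli draws with
P(left) = 1/(1 + exp(−β·Δu)), where Δu is the left-minus-right expected
utility change and β > 0 a per-condition sensitivity. The logistic is
evaluated through a log-sum-exp guard and is stable for |βΔu| beyond 700.

## Synthetic cohorts

The generative side mirrors the hierarchical model: subject risk aversions
are Normal around condition-specific group means (TIME-style) or a single
shared mean (ISO-style); log-sensitivities, log-curvatures and
log-loss-aversions are Normal on the log scale. Bounded parameters are
enforced by resampling (log α ≤ 0, log λ ∈ (0, log 5)); resample counts
are logged.

The default study replica is 18 subjects × 2 conditions × 312 trials,
TIME cohort with group means (0, 1) and sd 0.3, wealth fixed at 1000 DKK.
Sensitivity is calibrated so the median |β·Δu| over the constrained gamble
space is about 2 under the condition's optimal utility — choices that are
informative but stochastic in both conditions, whose wealth-change scales
differ by three orders of magnitude (DKK versus log-units). The calibrated
value is then constrained into the support of the group-level sensitivity
prior (log β ∈ (−2.3, 3.4)): recovery exercises generate agents from the
same hierarchical model they refit, and a generating value outside the
prior support cannot be covered by the posterior by construction (we
measured severe credible-interval undercoverage, down to 6/20, before
adding this constraint). For recovery cohorts placed at other η values,
the calibration is evaluated under the cohort's own generating utility for
the same reason. For the additive condition this lands β at the lower
support edge (0.1), making synthetic additive choices sharper than the
median-2 target; the multiplicative calibration (β ≈ 11.5) is interior.

Long-horizon simulations draw a uniformly random pair from the 144-pair
space each trial, let the agent choose through the logistic rule, and
realize one of the chosen gamble's outcomes by a fair coin. Multiplicative
wealth is tracked on the log scale so 10^4-trial runs neither overflow nor
underflow; additive wealth may go negative in this open-ended setting (the
passive bounds do not apply), and log-branch utilities assign ruinous
outcomes a large negative utility so maximizing agents avoid them. The
default horizon is 10^4 trials (the experiment's ~10 s trial spacing makes
a week ≈ 60,000 trials; the growth-rate orderings are already unambiguous
at the shorter horizon, which keeps simulation cost low).

## Hierarchical estimation

The dynamic-specific isoelastic model: per subject i and condition c,
η_{i,c} ~ Normal(μ^η_c, σ^η_c) and log β_{i,c} ~ Normal(μ^β_c, σ^β_c),
with uniform hyperpriors μ^η_c ∈ (−2.5, 2.5), σ^η_c ∈ (0.01, 1.6),
μ^β_c ∈ (−2.3, 3.4) (β roughly 0.1–30), σ^β_c ∈ (0.01, 1.6), and a
Bernoulli likelihood through the logistic rule. The σ lower bound 0.01 is
used throughout (degenerate zero-variance groups excluded).

**Sampler.** No gradient-based probabilistic-programming backend is
required: the model's structure — subject-level parameters conditionally
independent given the group level, and a likelihood that factorizes over
subject-condition blocks — makes an adaptive Metropolis-within-Gibbs
scheme both simple and fast. Datasets are packed so that each block's
trial utilities are gathers from at most nine unique post-outcome wealth
levels; a full-data likelihood evaluation for all chains is a handful of
vectorized array operations. Per sweep: elementwise random-walk Metropolis
on all subject-level parameters simultaneously (proposal scales adapted
per parameter toward 0.44 acceptance during burn-in by Robbins–Monro, then
frozen), truncated-normal Gibbs steps for group means, and log-scale
Metropolis for group standard deviations. Chains run vectorized in a
single process. The desk preset is 4 chains × 2000 retained draws after
500 adaptation sweeps (an 18-subject fit takes ~15 s on one core); a
paper-scale preset (10 chains × 10^4 draws) is provided. Split-R-hat and
ESS come from arviz; parameters with R-hat outside [1, 1.01] are flagged
rather than silently accepted — at the desk preset some subject-level
sensitivities exceed the threshold while group-level recovery is already
stable, so the flags are reported and the user decides whether to sample
longer.

Group-level MAP estimates use a Gaussian KDE with Silverman's bandwidth on
pooled draws, maximized on a 512-point grid; a nearly flat density (range
< 10% of its peak) triggers an ill-defined-mode warning.

## Latent-mixture model selection

One superordinate model nests TIME, PT and ISO with a per-subject
indicator z under a uniform prior. Sub-model structure: TIME has group
means fixed at (0, 1) with free dispersions σ ∈ (0.01, 1.6); ISO has one
η per subject shared across conditions with μ^η ∈ (−2.5, 2.5); PT has
lognormal α_gain, α_loss (log-scale means in (−2.3, 0), truncated to
α < 1) and lognormal λ (log-scale mean in (0, 1.6), truncated to
λ ∈ (1, 5)); every sub-model carries its own per-condition β with the
shared sensitivity hyperpriors. Subject-level priors for bounded PT
parameters are truncated, so their hyperparameter conditionals are
non-conjugate and are updated by Metropolis with the exact
truncated-normal likelihood (including the normalization term).

Two z treatments share one interface. The default *marginalizes* z:
the per-subject likelihood is the mean of the three sub-model likelihoods,
and per-subject model probabilities are posterior-averaged
responsibilities. The *indicator* variant samples z by Gibbs steps and
reports its posterior frequencies; parameters of currently unselected
models evolve under their own hierarchical priors (the pseudo-prior
choice). In both variants, every subject-level family is updated twice
per sweep: a random-walk move and an *independence move proposed from the
hierarchical prior* (the prior cancels against the proposal, leaving only
the mixture-likelihood ratio). The independence move is what keeps
parameters of currently unfavoured sub-models mixing — without it the
indicator chain is sticky and the marginalized chain explores unfavoured
models by slow diffusion. Likelihood caches are refreshed by direct
assignment (not increments) to avoid floating-point drift when early
exploration visits extreme log-likelihoods, and a cache-consistency guard
runs at the end of every fit. The two variants agree on per-subject model
probabilities within Monte-Carlo error on toy data; residual differences
concentrate on subjects whose data genuinely support two models.

**Population-level comparison.** Per-subject posterior model probabilities
(log-transformed, floored at 1e−12) serve as the subject-wise evidence
proxy for random-effects model selection: a Dirichlet(1,1,1) prior over
population frequencies, variational updates of the frequency posterior,
exceedance probabilities by Monte Carlo over the Dirichlet posterior
(10^5 seeded draws), the Bayes omnibus risk from the free-energy
comparison against the equal-frequency null, and
PXP = EP·(1 − BOR) + BOR/K. Estimated frequencies and their SDs are the
Dirichlet posterior's mean and standard deviation.

## Behavioral statistics

CP_log is the per-subject fraction of discrepant trials decided as a
log-utility agent would decide them. Distances in risk-aversion space:
to the time-optimal coordinate, √(η_add² + (η_mult − 1)²); to the
dynamic-invariant diagonal, |η_mult − η_add|/√2. The realized growth rate
of a subject's choices is the mean over trials of the chosen gamble's
time-average growth rate (DKK/trial or log-units/trial). Group-level
inferential statistics (Bayesian t-tests, ANOVA and similar) are
deliberately left to standard statistical tooling; `subject_metrics`
emits the tidy per-subject table those tools consume.

## What the synthetic data does and does not show

The generator reproduces the paradigm's structure (stimuli, trial counts,
fixed wealth, Bernoulli choices through the logistic rule) and the
hierarchical parameter structure. It does not emulate learning or
forgetting of stimulus values during the passive phase, trial-order or
fatigue effects, reaction times, or any within-session wealth updating.
Passing recovery tests therefore show that the inference machinery
identifies the models' parameters and identities *when the generative
assumptions hold* — they cannot certify the models against the
misspecifications real behaviour may carry.

## Test and simulation scales

Test sizes are chosen to keep the default suite in the tens of minutes on
one core: the study-replica fit uses 18 subjects at 4 chains × 2000
draws; the credible-interval coverage study uses 4 η-grid points × 20
replicate cohorts of 8 subjects, fit jointly in a single stacked sampler
run at 2 chains × 2000 draws; model recovery pools three 9-agent cohorts
at 2 chains × 2000 draws; growth orderings use 50 runs of 10^4 trials.
All seeds are fixed constants in the test suite.

## Known limitations

* Random-walk mixing at the desk preset leaves some subject-level R-hats
  above 1.01; they are flagged, and longer presets resolve them.  A joint
  translation move (shifting a group mean together with all its subject
  values) is included to decouple the funnel that appears at small group
  dispersions.
* Under additive dynamics, η and β form a weakly identified ridge (raising
  η shrinks all utility differences, which a larger β can compensate), so
  additive risk-aversion posteriors are wider and can sit off the
  generating value for a single cohort even when credible-interval
  coverage is nominal across replicates.  Multiplicative η is sharply
  identified.
* The additive condition's calibrated sensitivity sits at the lower edge
  of the group prior's support, so synthetic additive choices are sharper
  than the nominal median-|βΔu| = 2 target.
* Marginalized and indicator mixtures agree within MC error, but
  subjects with genuinely bimodal model support converge slowly in both.
* The exact growth factors of the original stimulus set are taken as the
  canonical 2^(k/4) family; any deviation in the original instrument
  would shift the discrepant-trial count.
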