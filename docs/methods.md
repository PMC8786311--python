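# Methods

## Task model

The environment is a five-option bandit. Three machines pay fixed points
(20, 40, 80); two pay 0 or a win amount (40 or 80) with probability 1/2
each. The two equal-expected-value pairs (20 vs 0/40, 40 vs 0/80) make
risk preference observable without making any learning asymmetry optimal;
the 0/80-vs-20 pair adds unequal-EV risky choices, and dominance pairs
("test" trials) measure learning accuracy.

A session is 183 trials: 42 equal-EV risky (21 per pair), 24 unequal-EV
risky, 75 forced single-option trials (15 per machine), and 42 test trials
spread as evenly as possible over the seven dominance pairs (6 each).
Dominance is evaluated at matched win/lose quantiles (a deterministic
machine contributes its fixed payoff to both), which covers
probabilistic-vs-probabilistic pairs. Each third of every trial type
appears in each of three 61-trial blocks, shuffled within block by a
seeded permutation; left/right placement is uniform. Probabilistic
outcomes are scheduled in bags of eight — four wins and four zeros drawn
without replacement, the bag refilled when empty — so every run of eight
draws from one machine pays exactly half wins. Missed trials are supported
on ingestion (no outcome, no image, excluded from the likelihood) but
never generated by the simulator: they are rare enough in real use
(tens out of ten thousand trials) that simulating them adds nothing.

## Learning models

Rewards are rescaled by the maximum payoff (r = points/80 ∈ [0, 1]) and
values initialized at Q = 0.5. The update is Q ← Q + α·δ with
δ = target − Q:

| model   | free parameters (k)                     | target | rate selection |
|---------|-----------------------------------------|--------|----------------|
| TD      | α, β (2)                                | r      | α always |
| RSTD    | α⁺, α⁻, β (3)                           | r      | α⁺ if δ>0 else α⁻ |
| FourLR  | α⁺, α⁻ for free and forced, β (5)       | r      | valence × agency |
| Utility | α, β, ρ (3)                             | r^ρ    | α always |

δ = 0 exactly dispatches to the negative-valence rate ("not better than
expected"); an arbitrary but fixed, documented tie-break. It matters only
for machines whose payoff equals the current value — notably the 40-point
machine at initialization, whose PE is exactly zero until its value moves.

Choice probability on two-option trials is a softmax in the value
difference, computed as 1/(1+exp(−β·ΔQ)) (equivalent to max-subtraction;
immune to overflow). Forced outcomes update values for every model but
contribute no choice terms. The asymmetry index AI = (α⁺−α⁻)/(α⁺+α⁻) is
defined as 0 at (0,0) — a removable singularity that the fitting priors
make measure-zero.

The Experiment-2-style **explicit prediction** model carries one value per
scene category (both initialized at the rescaled midpoint 0.5), updates
with valenced rates against its own running estimate, and has no β; it is
fit by least squares to the participant's stated trial-by-trial
predictions. A Beta(2,2) penalty on the rates is available but off by
default (pure least squares). Streams in which no prediction error ever
occurs leave the rates unconstrained; such fits are flagged
`unidentifiable` rather than reported as estimates.

## Fitting

Maximum a posteriori: the objective is the negative log choice likelihood
minus log priors. Priors (shape–scale convention for the Gamma family,
matching MATLAB's `gampdf`; a shape–rate switch exists on `PriorSpec`):

| parameter       | bounds        | prior          | mode |
|-----------------|---------------|----------------|------|
| learning rates  | [0, 1]        | Beta(2, 2)     | 0.5  |
| β               | [1e-6, 30]    | Gamma(2, 3)    | 3    |
| ρ               | [0, 2.5]      | Gamma(1.5, 1.5)| 0.75 |

The optimizer is L-BFGS with finite-difference gradients in an
unconstrained space (scaled logit per bounded parameter); prior densities
are evaluated on the natural scale, so the optimum is the natural-scale
MAP. Ten restarts by default: the first from the vector of prior modes,
the rest jittered by N(0, 2) in the unconstrained space; objective
tolerance 1e-8; the best restart wins and all restart objectives are kept
for audit. Sigmoids are clipped to (1e-12, 1−1e-12) so the objective stays
finite. The likelihood replay is compiled with numba; a plain-Python
replay of the same recursion exists in `riskrl.sessions` and the test
suite holds them to 1e-10 agreement.

BIC = −2·logL(MAP) + k·ln(n) uses the likelihood (not the posterior) at
the MAP and n = non-missed free choices (≤ 108: risky and test trials both
offer two options and enter the softmax stage). A group-level winner is
declared only when the median BIC margin exceeds 6.

With zero free choices the MAP sits at the prior modes and BIC is
undefined (NaN in results; `compute_bic` raises).

## Recovery analyses

Parameter recovery draws each model's parameters uniformly within the
fitting bounds, simulates each synthetic subject on an independent fresh
seeded session, refits the same model, and reports Pearson correlations
(Spearman as a secondary diagnostic) over converged fits. Model recovery
fits competing models to the same simulated subjects and reports pairwise
BIC win proportions. Default sizes are 500 subjects for parameter
recovery and 300 per generating model for model recovery — the package's
desk-scale choice; both are arguments.

The posterior predictive check re-simulates each subject at their MAP
parameters on their own trial sequence (fresh outcome draws) and
correlates mean simulated with observed equal-EV risky-choice proportion
across subjects; that proportion is the check's summary statistic because
it is the task's designed behavioral readout of risk preference. Cohorts
with zero variance in either vector return a flagged degenerate result.

A note on calibration: the multistart optimizer reliably finds the global
MAP (the test suite verifies it against dense grid search), so recovery
correlations here run a few hundredths *above*, and identification of the
larger models slightly above, values published for the same procedure with
a single-start unconstrained optimizer. The recovery machinery makes no
attempt to emulate optimizer failure modes of other implementations.

## Memory pipeline

Responses 1–2 ("definitely/maybe old") binarize to *old*. Signal detection
corrects extreme rates to 1/(2N) and 1−1/(2N) before the quantile
transform; d′ = z(hit) − z(FA).

The regression table holds truly-old images with a valid PE (one row per
image); foil behavior enters through the subject's false-alarm-rate
covariate. Continuous predictors are z-scored grand across included rows
(a within-subject switch exists). The main model is

    correct ~ AI × PE-valence × PE-magnitude + age + age² + FA-rate + test-position

with, by subject, a random intercept and uncorrelated random slopes for
the within-subject predictors (valence, magnitude, their product, test
position). Between-subject covariates get no slopes — they are constant
within subject, so their slopes are unidentified. Estimation uses
statsmodels' binomial mixed GLM with diffuse priors via mean-field
variational Bayes — the estimator of this family that scales to
cohort-sized tables; its posterior standard deviations are known to be
mildly anti-conservative, which synthetic-coverage tests bound in
practice. On failure a declared ladder is walked and logged: uncorrelated
slopes (the variance-component formulation fits no slope correlations by
construction) → intercept only → plain logistic GLM with cluster-robust
standard errors. Complete separation (single-level outcome) short-circuits
to a flagged result with no estimates.

Marginal means are fixed-effects-only predicted probabilities on an
AI × valence × magnitude grid with other covariates at their z-means,
with CIs from the coefficient covariance. Subset analyses refit the main
model on probabilistic-machine rows only, and fit an agency-moderated
model (agency × the full three-way factorial) on all rows.

## Age statistics

Outcomes are regressed on z-scored age, linear vs linear+quadratic,
arbitrated by the nested F test at 0.05. Cohen's f² per term is the
R²-change ratio; its CI inverts the noncentral-F distribution. The
two-lines test fits separate segments left/right of a breakpoint
(breakpoint observation goes left; heteroskedasticity-robust HC3 standard
errors by default, classical switch available) and certifies a u-shape
only when both slopes are individually significant with opposite signs.
The breakpoint is user-supplied or found by grid search over interior ages
maximizing summed segment R² — a declared, simple stand-in for the
published automatic break-point algorithm, whose internals this package
does not reproduce; exact breakpoint agreement with published values is
therefore not claimed.

## Synthetic cohort generator

The generator's defaults are the study conditions for every pipeline test;
all constants are invented plumbing chosen once to produce qualitatively
realistic structure, not empirical estimates. Per subject: age ~ U(8, 27);
α⁻ = 0.2 + 0.3·(1 − ((age−17)/9)²) + N(0, 0.05) clipped to [0,1] (an
adolescent peak, giving a u-shaped AI over age); α⁺ = 0.25 + N(0, 0.05);
β log-normal(ln 4, 0.3) clipped to the fitting bounds. Each subject plays
one full session as an RSTD agent. Memory: for old images,
P(said old) = logistic(0.1 + 0.2·z|δ| + 0·z(val) + 0.15·z(AI)·z(val)·z|δ|
− 0.2·z(position)), with predictors standardized grand across the cohort's
old items and δ taken from the *generating*-parameter replay; foils are
endorsed at a subject rate drawn Beta(4, 12) (mean 0.25). Confidence is a
cosmetic 0.7/0.3 definite/maybe split — the analyses binarize. These
settings land hit rates near 0.52, false alarms near 0.25, and d′ near
0.8, and plant the u-shape and the positive three-way memory interaction
that the pipeline tests must detect (and must *not* detect when the bump
or b_int is zeroed).

What the generator does not emulate: missed responses, reaction times,
within-subject parameter drift, confidence that carries information,
age-correlated false-alarm rates, and any dependence of memory on agency.
Passing pipeline tests therefore demonstrate statistical machinery
correctness under the generative model, not validity of that model for
human data.

## Problem sizes and numerical choices

Recovery runs use 500 subjects per model (parameter) and 300 per
generating model (model recovery); pipeline power checks use ~10 replicate
cohorts of 40–62 subjects — the package's standard desk-scale sizes.
Grid-oracle comparisons use a 25 × 20 (α, β) grid; because α and β trade
off along a curved likelihood valley, a rectangular grid's argmin can sit
about one cell from the continuous optimum, so optimizer-vs-grid agreement
is asserted to 1.5 cell widths. Ties, degenerate inputs, and flagged
states (unidentifiable least-squares fits, degenerate PPC, separation) are
returned as data, never exceptions, wherever a batch pipeline must keep
moving; true input errors (inconsistent tables, out-of-range rewards)
raise with row-level context.

## Known limitations

- Recovery benchmarks are desk-scale (hundreds, not ten thousand,
  subjects); correlations carry sampling noise of a few hundredths.
- The mixed-model standard deviations come from mean-field variational
  Bayes and are mildly anti-conservative; headline inferences in the
  analyses are strongly signed, but borderline p-values near 0.05 should
  not be over-read.
- The explicit-prediction fit assumes the model's own running estimate
  (not the stated prediction) is the PE baseline, and that reports are
  value plus Gaussian noise.
- The two-lines breakpoint search is a grid heuristic; breakpoints are
  data-dependent and not comparable across cohorts with different designs.
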