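# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## Model and assumptions

The modelled unit is the change in the total DESIGN-R 2020 score of one
pressure injury between two consecutive assessments, `d_i(t, s) =
y_{i,t+s} - y_{i,t}`, where `s` is the gap in days (DurationForNext) and
`t` the elapsed time since the first assessment (DurationFromDay0). The
change is Gaussian around a linear predictor with lesion-specific
coefficients:

    d_i(t,s) = x(t,s)' beta_i + eps,   eps ~ Normal(0, sigma^2)
    x(t,s)   = [1, s, (s^2), x_1(t), ..., x_k(t)]
    beta_i   ~ MultiNormal(mu, Sigma),  Sigma = B B',  B = diag(zeta) L

`L` is the Cholesky factor of a correlation matrix. Lesions — not
patients — are the exchangeable unit: multiple wounds of one patient are
treated as independent draws from the population distribution, because
the model carries a single lesion index and nothing in the data schema
identifies shared patients. The likelihood is continuous although
observed changes are integers; no transformation is applied because
changes are frequently negative (healing).

Priors (raw data units; changes are score points, durations days, age
years):

| parameter | prior | default scale | role |
|---|---|---|---|
| sigma | half-Normal(0, 100) | 100 | residual SD of one change |
| mu_intercept | Normal(0, 10) | 10 | population mean at x = 0 |
| mu_j (slopes) | Normal(0, 1) | 1 | population effect per predictor unit |
| zeta_j | half-Student-t(4, 0, 1) | 1 | between-lesion SD of effect j |
| L | LKJ-Cholesky(4) | shape 4 | mild shrinkage toward no correlation |

Truncated densities (half-normal, half-t) include their ×2 constants and
the LKJ density its full normalizer, because marginal likelihoods are
compared across models of different dimension: an absolute density scale
is required, not just one correct up to constants.

Predictors enter in raw units by default. The Normal(0, 1) slope prior is
therefore informative in a scale-dependent way: a plausible effect of a
wide-ranging covariate (a duration slope of −0.5 per day, swinging tens
of points over a trajectory) is well inside the prior, while a 6-point
jump attached to a binary flag is 6 prior SDs out and is penalized in
model comparison. This matches the magnitudes of the effects the model
family was designed around. A standardization switch was considered and
rejected for the default because the prior scales are calibrated to raw
units; standardizing silently would change every marginal likelihood.

## Dummy coding of subscales

Each non-depth subscale is encoded as a (large, small) indicator pair:
score 0 → (0,0); a severe (uppercase) value → (1,0); a mild (lowercase)
value → (0,1). The exudate partition is large={6}, small={1,3}. The
partitions for S, I, G, N, P ship as a documented configuration table
derived from the DESIGN-R 2020 instrument's uppercase/lowercase
convention (e.g. S15 is the only "large" size; N has no lowercase
values besides n0) and can be overridden via `SubscaleCoding` — they are
instrument conventions, not outputs of this package's own analysis.

## Inference: collapsed NUTS

Because likelihood and random effects are jointly Gaussian, the per-PI
coefficient vectors integrate out in closed form:

    d_i | mu, Sigma, sigma ~ Normal(X_i mu, X_i Sigma X_i' + sigma^2 I).

The sampler therefore targets only the hyperparameters — `2p + p(p-1)/2
+ 1` dimensions for a p-column design — which removes the funnel
geometry of centered hierarchical parameterizations entirely (it is the
limit of marginalizing rather than re-centering). Per-lesion effects are
recovered per posterior draw from their exact Gaussian conditionals, so
the returned draws cover the full joint posterior.

The kernel is a standard dynamic Hamiltonian Monte Carlo: multinomial
sampling along the doubling trajectory, dual-averaging step-size
adaptation (target acceptance 0.9), and windowed estimation of a dense
metric. Unconstrained coordinates are `[mu, log zeta, corr-Cholesky
coordinates (tanh of canonical partial correlations), log sigma]`, with
all Jacobians included in the density. Gradients are hand-derived and
verified against finite differences in the test suite; the density value
itself is verified against a naive per-lesion marginal-normal
implementation.

Two implementation details matter for speed on this posterior:

- **Laplace initialization.** Raw-unit predictors give coefficients whose
  posterior scales span four orders of magnitude (intercept ~10 vs a
  squared-duration slope ~0.01); a unit metric would force hundreds of
  leapfrog steps per iteration during early warmup. The sampler first
  finds the posterior mode by L-BFGS (the analytic gradient makes this
  cheap), takes the local inverse Hessian as the initial dense mass
  matrix, and jitters chain starts from the mode. Warmup windows then
  re-estimate the metric from the chain as usual.
- **Padded vectorization.** Per-lesion designs are zero-padded to a
  common assessment count so the density and gradient evaluate as single
  batched linear-algebra expressions; the padding's spurious
  log-determinant and trace contributions are subtracted exactly.

Default configuration ("desk profile"): 4 chains, 1,000 warmup, 2,000
retained draws — chosen because the posterior dimensions here (6–36) mix
within a few hundred effective samples and anything larger only burns
time. A `published_profile` (3 chains, 40,000 draws after 10,000 warmup)
reproduces the published run configuration. Convergence is gated on the
split Gelman–Rubin statistic of every parameter being below 1.1
(delegated to arviz; the test suite checks it against an independently
coded textbook formula); trace plots are exportable artifacts for visual
checks, not an automated gate. Divergent trajectories (energy error
> 1000) are counted and reported.

## Marginal likelihood: Warp-III bridge sampling

Evidence is estimated on the collapsed unconstrained space, where
`exp(logp)` integrates to exactly the full model's marginal likelihood.
Each repetition: permute the posterior draws, use one half to
moment-match an affine map onto a standard-normal proposal, symmetrize
the other half with random sign flips (removing third-moment error —
"warp-III"), and iterate the optimal (Meng–Wong) bridge update in log
space to relative tolerance 1e-10 (cap 1,000 iterations; non-convergence
raises an error carrying the last two iterates). The estimate is the
mean of 5 repetitions; their SD is the estimator's precision and defines
the tie band in model selection. On a conjugate normal regression the
estimator agrees with the closed-form evidence to ~0.001 log units.

## Predictor selection

Stage 1 screens each candidate `p` by the posterior probability of the
one-addition model against the duration-only base model under equal
model priors, `P = Z_p / (Z_p + Z_0)`; candidates with `P > 0.95`
(strictly; the boundary `ln 19` case is excluded) are selected. Stage 2
fits every non-empty subset of the selected set and takes the highest
evidence. Stage 3 repeats stages 1–2 on five random 80% lesion-level
subsets of the training data (sampled without replacement, seeded), then
re-scores all distinct fold candidates on the full training data;
the highest evidence wins. Ties within the winner's repetition-SD go to
the smaller model, then lexicographically — a reproducibility rule, not a
statistical claim. A fold whose screen selects nothing nominates the
base model. The quadratic gap term `s^2` participates as a screenable
candidate, and squared terms may be selected without their linear
companions (the report makes such specs visible).

## Prediction and the fail-safe statistic

Three predictive modes differ in where the lesion's coefficient vector
comes from:

- `population`: beta = mu per posterior draw. This implements the
  "random-effect scales set to zero" rule for the first prediction of a
  lesion with no observed history. It deliberately ignores between-lesion
  variability and therefore *undercovers* for genuinely new lesions.
- `pi_specific`: beta ~ MultiNormal(mu, Sigma) per draw — a new lesion
  exchangeable with the fitted ones; the calibrated choice.
- `updating`: beta conditioned on the lesion's accumulated observed
  changes (exact Gaussian conditional per draw). Sequential prediction
  uses population mode for the first step always, and `updating` for
  later steps when requested; both choices are recorded in the report,
  because the sequential protocol is ambiguous between them.

Intervals are central empirical quantiles of the predictive draws
(requiring ≥ 100 draws), translated to the total-score scale by adding
the last observed total. Coverage counts closed-interval membership —
scores are integers, ties at the boundary occur and count as covered —
and totals are not clipped when checking membership. Pooling is
count-wise: sum of covered over sum of assessed.

## Synthetic cohorts

The generator emulates the home-care consultation cohort the analysis
targets. Defaults: 18 lesions (an 80:20 split by longest follow-up then
yields 14 training and 4 test lesions), 2–6 assessments per lesion
spaced Normal(14.7, 6) days (truncated at 1), age Normal(79.4, 8.4),
baseline totals Normal(15, 6) clipped into [1, 66], and binary risk and
comorbidity covariates at the training cohort's prevalences. The default
generating hyperparameters are the published posterior means of the best
model; the residual SD, which the published summary omits, is set to 2.0
score points as a clinically plausible value (chosen once). Trajectories
follow the hierarchical model exactly: one coefficient vector per lesion,
Gaussian changes, then (by default) rounding to integers and clipping
into [0, 66], with clipping events counted in the provenance. Integer
totals are decomposed into permissible subscale values summing *exactly*
to the total, by proportional allocation over the coarse subscales and an
exact lookup over the fine-grained granulation/exudate pair; the model
consumes only totals and dummies, so any consistent scheme suffices.

Two switches exist for model checks: `integer_scores=False` keeps
continuous totals, and `clip_scores=False` disables the floor/ceiling.
The calibration and selection-power checks use both, because clipping
truncates the Gaussian likelihood the refitted model assumes: with the
default trajectories a substantial fraction of transitions hits the
floor (wounds heal to 0 and stay), which inflates measured interval
coverage by several points and can erase a predictor's signal entirely.
What those checks demonstrate is therefore calibration and selection
power *under the model's own data-generating process*; they do not
demonstrate robustness to the truncation, rounding, or care-process
feedback present in real assessment data.

## What the acceptance computations measure

- **Coverage calibration**: cohorts of 30 lesions (3–6 assessments) are
  simulated from fixed hyperparameters, refit with the desk profile, and
  nominal 90% intervals for fresh single-change lesions (pi_specific
  mode) are checked; three replicates pool ~240 held-out points.
  Residual overcoverage of a point or two is expected at this data size:
  hyperparameter uncertainty widens honest predictive intervals.
- **Convergence gate**: the best-model predictor structure (age, both
  durations with squares, baseline total; 36 hyperparameters) fitted to a
  14-lesion integer cohort with 3 chains must keep every split R-hat
  below 1.1.
- **Threshold boundary**: two evidences differing by ln 19 give
  posterior model probability 0.95 exactly, and the screen admits a
  predictor only strictly above it.

Problem sizes throughout (cohort sizes, draw counts, replicate counts)
are chosen so the full suite runs in minutes on one CPU while leaving
every comparison's Monte-Carlo error well inside its tolerance.

## Known limitations

- The Gaussian likelihood ignores the integer, bounded support of real
  scores; the mismatch is visible in the generator's clipping counter.
- Lesion-level exchangeability ignores within-patient correlation.
- The evidence-based screen is calibrated for prior-plausible effect
  sizes in raw units; rescaling covariates without rescaling priors
  changes selection behaviour.
- The care-recommendation algorithm itself (the flowchart content rated
  in the vignette study) is out of scope; only its evaluation statistics
  are implemented, and the packaged per-vignette rating files are
  synthetic reconstructions consistent with the published per-field
  counts (the individual ratings are unpublished). The published round-1
  expected-healing mean (2.67) is representable only with three rated
  vignettes (8/3); the fixture reflects that.
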