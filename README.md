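# pitrend

Hierarchical Bayesian prediction of pressure-injury healing trends on the
DESIGN-R 2020 scale.

## The problem

Home-visiting nurses manage pressure injuries (PIs) without easy access to
certified wound-care experts. A clinical decision support system for this
setting needs a *fail-safe*: a quantitative signal that a wound is not
healing the way it should under expert-informed care, so that a real
consultation can be requested. `pitrend` implements the statistical core of
such a fail-safe — a distributional prediction of how a wound's severity
score will change by the next assessment, with the observed score checked
against a 90% prediction interval — plus the evaluation statistics used to
validate the expert care-recommendation algorithm on clinical vignettes.

Severity is measured with DESIGN-R 2020: seven subscales (Depth, Exudate,
Size, Inflammation/infection, Granulation, Necrotic tissue, Pocket), whose
total score sums the six non-depth subscales (0–66; higher = more severe).
Each subscale's values split into severe ("large", uppercase) and mild
("small", lowercase) categories, encoded as a pair of mutually exclusive
dummies (E=6 → large E; E=1 or 3 → small e; E=0 → neither).

## The model

For lesion *i* with total score *y<sub>it</sub>* at day *t*, the modelled
unit is the change over the next assessment gap of *s* days,
*d<sub>i</sub>(t, s) = y<sub>i,t+s</sub> − y<sub>it</sub>*, regressed on a
design row **x**(t, s) = [1, s, s², x₁(t), …, x<sub>k</sub>(t)] with
lesion-specific coefficients:

```
d_i(t,s) = x(t,s)' β_i + ε,      ε   ~ Normal(0, σ²)
β_i      ~ MultiNormal(μ, Σ),    Σ_chol = diag(ζ) · Ω_chol
```

with priors σ ~ Normal⁺(0, 100), μ_intercept ~ Normal(0, 10), remaining
μ ~ Normal(0, 1), ζ ~ Student-t⁺(4, 0, 1), Ω_chol ~ LKJ(4). μ carries the
population (fixed) effects, ζ the between-lesion (random) effect scales.

Everything downstream follows from the posterior:

- **Inference** — an in-package No-U-Turn sampler runs on the *collapsed*
  posterior (the Gaussian β_i integrate out analytically), with exact
  per-lesion conditionals recovering the β_i afterwards; convergence is
  gated on split Gelman–Rubin R-hat < 1.1.
- **Predictor selection** — marginal likelihoods via Warp-III bridge
  sampling; a candidate enters when its posterior model probability
  against the duration-only base model exceeds 0.95; combinations are
  searched exhaustively; five random 80% lesion-subsets each nominate a
  candidate and the best all-data evidence wins.
- **Validation** — sequential 90% prediction intervals for held-out
  lesions; the pooled fraction of observed scores inside their intervals
  is the fail-safe statistic.
- **Vignette metrics** — agreement proportion (ratings in {0,3,4} over
  all), improvement proportion (ratings in {3,4} over {1,2,3,4}, NULL for
  all-zero fields), and mean expected healing on a 1–4 scale.

A synthetic-cohort generator simulates longitudinal assessment records
with the covariate marginals of the home-care consultation cohort the
model targets, so the full pipeline runs without any clinical data.

## Worked example

```python
from pitrend import (CohortConfig, McmcConfig, ModelSpec, ScoreChangeModel,
                     generate_cohort, split_train_test)

cohort = generate_cohort(CohortConfig(seed=42))
train, test = split_train_test(cohort, test_fraction=0.2)

spec = ModelSpec(predictors=("baseline_score", "age"),
                 include_quadratic_duration=True)
results = ScoreChangeModel.from_dataset(train, spec=spec).fit(
    McmcConfig(n_chains=4, n_warmup=500, n_draws=1000, seed=1))
print(results.summary().head(7).round(2))
coverage = results.coverage(test, level=0.90, mode="population")
```

which prints (18 lesions split into 14 training / 4 test by longest
follow-up; converged with max R-hat 1.007):

```
                        mean    sd     q5  median    q95  rhat
sigma                   6.88  1.18   5.21    6.74   9.12  1.00
mu[intercept]          -1.10  9.22 -15.99   -0.83  13.41  1.00
zeta[intercept]         0.91  0.80   0.07    0.70   2.42  1.00
mu[duration_next]      -0.48  0.72  -1.66   -0.48   0.71  1.00
zeta[duration_next]     0.27  0.20   0.02    0.23   0.64  1.00
mu[duration_next_sq]    0.04  0.03  -0.01    0.04   0.09  1.01
zeta[duration_next_sq]  0.02  0.01   0.00    0.02   0.04  1.01
```

`sigma` is the residual SD of a score change (score points); each
`mu[...]`/`zeta[...]` pair is a predictor's population effect and its
between-lesion spread. `results.log_marginal_likelihood()` gives the
bridge-sampled evidence (here −128.50 with SD 0.02 over five
repetitions), and the held-out coverage comes back as per-lesion counts:

```
per-lesion coverage: PI006 3/5, PI008 4/5, PI015 3/4, PI017 4/5
pooled coverage of 90% intervals: 0.74 (14/19)
```

Population-mode prediction (the "random-effect scales set to zero" rule
for a lesion with no history) ignores between-lesion variability, so its
intervals undercover — the same behaviour reported for this design on
clinical data. `mode="pi_specific"` draws the new lesion's coefficients
from the population distribution and is the calibrated choice; see
`docs/methods.md`.

A thin CLI wraps the same stages:

```sh
pitrend simulate -o out && pitrend fit -r out/records.csv -o out
pitrend predict -r out/records.csv -t test.csv -f out -o out
pitrend evaluate -o out     # vignette metrics from the packaged counts
```

`pitrend evaluate` prints the per-round pooled metrics, e.g.
`round 1: agreement 0.92 (33/36), improvement 0.73 (8/11)`.

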