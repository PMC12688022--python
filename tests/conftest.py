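import numpy as np
import pytest

from pitrend import (CohortConfig, McmcConfig, ModelSpec, ScoreChangeModel,
                     generate_cohort, make_truth)
from pitrend.model import ScoreChangeObservation


def small_observations(seed: int = 0, n_pis: int = 6,
                       predictors=("age", "baseline_score"),
                       quadratic=True):
    """A handful of synthetic score-change observations for density tests."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(predictors=tuple(predictors),
                     include_quadratic_duration=quadratic)
    obs = []
    for pid in range(n_pis):
        t = 0.0
        age = float(rng.normal(79, 8))
        base = float(rng.integers(5, 25))
        for _ in range(int(rng.integers(2, 5))):
            s = float(rng.integers(5, 20))
            obs.append(ScoreChangeObservation(
                pi_id=f"pi{pid:02d}", duration_day0=t, duration_next=s,
                d=float(rng.normal(0, 3)),
                covariates={"age": age, "baseline_score": base}))
            t += s
    return obs, spec


@pytest.fixture(scope="session")
def fitted_base_model():
    """One shared small fit of the duration-only base model (smoke MCMC)."""
    spec = ModelSpec.base()
    truth = make_truth(spec)
    dataset = generate_cohort(CohortConfig(
        n_pis=10, assessments_per_pi=(3, 5), spec=spec, truth=truth,
        seed=7, integer_scores=False, clip_scores=False))
    model = ScoreChangeModel.from_dataset(dataset, spec=spec)
    results = model.fit(McmcConfig(n_chains=2, n_warmup=300, n_draws=500,
                                   seed=7))
    return dataset, results
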