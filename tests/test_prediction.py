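"""Predictive distributions, intervals, and coverage accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pitrend.model import ScoreChangeObservation
from pitrend.prediction import (CoverageResult, PredictionInterval,
                                coverage_probability, prediction_interval,
                                predictive_distribution, sequential_predict)


def _new_obs(**cov):
    return ScoreChangeObservation(pi_id="new", duration_day0=0.0,
                                  duration_next=10.0, d=0.0, covariates=cov)


class TestPredictionInterval:
    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(200_000)
        interval = prediction_interval(draws, 0.90)
        assert interval.lower == pytest.approx(stats.norm.ppf(0.05), abs=0.02)
        assert interval.upper == pytest.approx(stats.norm.ppf(0.95), abs=0.02)
        assert interval.point == pytest.approx(0.0, abs=0.02)

    def test_level_near_one_approaches_range(self):
        rng = np.random.default_rng(1)
        draws = rng.uniform(-1, 1, 10_000)
        interval = prediction_interval(draws, 1 - 1e-6)
        assert interval.lower == pytest.approx(draws.min(), abs=1e-3)
        assert interval.upper == pytest.approx(draws.max(), abs=1e-3)

    def test_constant_draws_zero_width(self):
        interval = prediction_interval(np.full(500, 3.0), 0.90)
        assert interval.lower == interval.upper == interval.point == 3.0

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            prediction_interval(np.zeros(50), 0.90)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            PredictionInterval(lower=1.0, upper=0.0, level=0.9, point=0.5)


class TestCoverage:
    def test_published_per_pi_counts_pool_exactly(self):
        """Per-PI fractions 4/6, 5/6, 6/7, 8/10 pool to 23/29."""
        result = CoverageResult.from_counts({
            "PI1": (4, 6), "PI2": (5, 6), "PI3": (6, 7), "PI4": (8, 10)})
        assert result.pooled == (23, 29)
        assert result.pooled_probability == pytest.approx(23 / 29)
        assert result.pooled_probability == pytest.approx(0.793, abs=5e-4)
        per = result.per_pi_probability()
        assert per["PI1"] == pytest.approx(4 / 6)
        assert per["PI4"] == pytest.approx(0.80)

    def test_full_coverage(self):
        ivs = [PredictionInterval(-1, 1, 0.9, 0.0)] * 3
        result = coverage_probability(ivs, [0.0, 0.5, -0.9])
        assert result.pooled_probability == 1.0

    def test_boundary_value_counts_as_covered(self):
        iv = PredictionInterval(-1.0, 1.0, 0.9, 0.0)
        result = coverage_probability([iv, iv], [1.0, -1.0])
        assert result.pooled == (2, 2)

    def test_misalignment_rejected(self):
        iv = PredictionInterval(-1, 1, 0.9, 0.0)
        with pytest.raises(ValueError, match="misaligned"):
            coverage_probability([iv], [0.0, 1.0])

    def test_pooled_equals_per_pi_sums(self):
        rng = np.random.default_rng(2)
        ivs = [PredictionInterval(-1, 1, 0.9, 0.0) for _ in range(20)]
        actual = rng.uniform(-2, 2, 20)
        ids = rng.choice(["a", "b", "c"], 20)
        result = coverage_probability(ivs, actual, ids)
        covered = sum(c for c, _ in result.per_pi.values())
        assessed = sum(a for _, a in result.per_pi.values())
        assert result.pooled == (covered, assessed)


class TestPredictiveDistribution:
    def test_modes_and_variance_ordering(self, fitted_base_model):
        """Between-lesion variance widens the new-lesion predictive."""
        _, results = fitted_base_model
        obs = _new_obs()
        pop = predictive_distribution(results.samples, obs,
                                      mode="population", seed=0)
        pi_spec = predictive_distribution(results.samples, obs,
                                          mode="pi_specific", seed=0)
        assert len(pop) == results.samples.n_chains * results.samples.n_draws
        assert pi_spec.var() > pop.var()

    def test_quantiles_match_closed_form_for_known_parameters(
            self, fitted_base_model):
        """With the posterior collapsed to a point, the population-mode
        predictive is exactly Normal(x'mu, sigma^2)."""
        _, results = fitted_base_model
        s = results.samples
        point = s.theta.reshape(-1, s.theta.shape[-1]).mean(axis=0)
        degenerate = type(s)(
            spec=s.spec, pi_ids=s.pi_ids,
            mu=np.broadcast_to(s.mu.mean((0, 1)), s.mu.shape).copy(),
            zeta=np.zeros_like(s.zeta), sigma=np.full_like(s.sigma, 2.0),
            omega_chol=s.omega_chol, beta=None, theta=s.theta,
            chain_stats=s.chain_stats, target=s.target)
        obs = _new_obs()
        draws = predictive_distribution(degenerate, obs, mode="population",
                                        seed=3)
        x = np.array([1.0, 10.0])
        expected_mean = float(s.mu.mean((0, 1)) @ x)
        assert draws.mean() == pytest.approx(expected_mean, abs=0.1)
        assert draws.std() == pytest.approx(2.0, abs=0.1)
        interval = prediction_interval(draws, 0.90)
        assert interval.lower == pytest.approx(
            expected_mean + 2.0 * stats.norm.ppf(0.05), abs=0.15)

    def test_unknown_mode_rejected(self, fitted_base_model):
        _, results = fitted_base_model
        with pytest.raises(ValueError, match="mode"):
            predictive_distribution(results.samples, _new_obs(),
                                    mode="bogus")


class TestSequentialPredict:
    def _records(self, days, totals):
        rows = []
        for day, total in zip(days, totals):
            rows.append({"pi_id": "x", "day": day, "total": total,
                         "e": 0, "s": 0, "i": 0, "g": 0, "n": 0, "p": 0})
        return pd.DataFrame(rows)

    def test_n_minus_one_intervals(self, fitted_base_model):
        _, results = fitted_base_model
        records = self._records([0, 10, 20, 35], [20, 18, 15, 12])
        report = sequential_predict(results.samples, records)
        assert len(report) == 3
        assert report["from_day"].tolist() == [0, 10, 20]
        assert report["to_day"].tolist() == [10, 20, 35]
        # intervals are on the total-score scale
        assert (report["upper"] - report["lower"] > 0).all()

    def test_first_prediction_population_mode(self, fitted_base_model):
        _, results = fitted_base_model
        records = self._records([0, 10, 20], [20, 18, 15])
        report = sequential_predict(results.samples, records,
                                    mode="updating")
        assert report["mode"].tolist() == ["population", "updating"]

    def test_zero_gap_rejected(self, fitted_base_model):
        _, results = fitted_base_model
        records = self._records([0, 10, 10], [20, 18, 18])
        with pytest.raises(ValueError, match="strictly increase"):
            sequential_predict(results.samples, records)

    def test_single_assessment_rejected(self, fitted_base_model):
        _, results = fitted_base_model
        with pytest.raises(ValueError, match="at least 2"):
            sequential_predict(results.samples, self._records([0], [20]))
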