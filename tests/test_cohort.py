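"""Synthetic cohort generation and the train/test split."""

import numpy as np
import pytest

from pitrend import CohortConfig, generate_cohort, make_truth, split_train_test
from pitrend.cohort import decompose_total
from pitrend.designr import DEFAULT_CODING
from pitrend.model import Hyperparameters, ModelSpec


class TestDecomposeTotal:
    def test_exact_for_every_representable_total(self):
        for total in range(0, DEFAULT_CODING.max_total + 1):
            values = decompose_total(total)
            assert sum(values.values()) == total
            for sub, value in values.items():
                assert value in DEFAULT_CODING.permissible[sub]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decompose_total(67)
        with pytest.raises(ValueError):
            decompose_total(-1)


class TestGenerateCohort:
    def test_determinism_byte_identical(self):
        cfg = CohortConfig(n_pis=8, seed=123)
        a = generate_cohort(cfg).records.to_csv(index=False)
        b = generate_cohort(cfg).records.to_csv(index=False)
        assert a == b

    def test_structure_invariants(self):
        ds = generate_cohort(CohortConfig(n_pis=12, seed=1))
        for pid, grp in ds.records.groupby("pi_id"):
            days = grp.sort_values("day")["day"].to_numpy()
            assert days[0] == 0
            assert np.all(np.diff(days) > 0)
            assert len(days) >= 2
        totals = ds.records[["e", "s", "i", "g", "n", "p"]].sum(axis=1)
        assert (ds.records["total"] == totals).all()

    def test_follow_up_emulates_study_training_marginal(self):
        """14 PIs with ~3 assessments a fortnight apart give a mean
        follow-up near the study's 29.4 days."""
        means = []
        for seed in range(8):
            cfg = CohortConfig(n_pis=14, assessments_per_pi=(2, 4),
                               spacing_mean_days=14.7, spacing_sd_days=6.0,
                               seed=seed)
            means.append(generate_cohort(cfg).follow_up_days().mean())
        assert np.mean(means) == pytest.approx(29.4, abs=4.0)

    def test_covariate_prevalences_converge(self):
        """Law-of-large-numbers check at n=2000 PIs within 3 SE."""
        cfg = CohortConfig(n_pis=2000, assessments_per_pi=(2, 2), seed=9)
        ds = generate_cohort(cfg)
        per_pi = ds.records.groupby("pi_id").first()
        for name, prob in cfg.covariate_prevalences.items():
            se = np.sqrt(prob * (1 - prob) / 2000)
            assert abs(per_pi[name].mean() - prob) < 3 * se + 1e-9, name

    def test_degenerate_truth_gives_deterministic_trajectories(self):
        spec = ModelSpec.base()
        truth = Hyperparameters(mu=np.array([-1.0, -0.1]),
                                zeta=np.zeros(2), omega_chol=np.eye(2),
                                sigma=1e-12)
        cfg = CohortConfig(n_pis=3, assessments_per_pi=(3, 3),
                           spacing_mean_days=10, spacing_sd_days=0.0,
                           spec=spec, truth=truth, integer_scores=False,
                           clip_scores=False, seed=0)
        ds = generate_cohort(cfg)
        for pid, grp in ds.records.groupby("pi_id"):
            totals = grp.sort_values("day")["total"].to_numpy()
            d = np.diff(totals)
            np.testing.assert_allclose(d, -1.0 - 0.1 * 10, atol=1e-6)

    def test_truth_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            generate_cohort(CohortConfig(
                spec=ModelSpec.base(),
                truth=make_truth(ModelSpec.published_best_structure())))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_pis=0)
        with pytest.raises(ValueError):
            CohortConfig(covariate_prevalences={"malnutrition": 1.5})
        with pytest.raises(ValueError):
            CohortConfig(assessments_per_pi=(1, 3))


class TestSplitTrainTest:
    def test_study_shape_18_to_14_4(self):
        ds = generate_cohort(CohortConfig(n_pis=18, seed=3))
        train, test = split_train_test(ds, 0.2)
        assert (train.n_pis, test.n_pis) == (14, 4)
        # the test lesions are the longest-followed ones
        assert train.follow_up_days().max() <= test.follow_up_days().min()
        # PI-level split: no lesion in both
        assert not set(train.pi_ids) & set(test.pi_ids)

    def test_tie_break_lexicographic(self):
        ds = generate_cohort(CohortConfig(
            n_pis=5, assessments_per_pi=(3, 3), spacing_mean_days=10,
            spacing_sd_days=0.0, seed=4))
        assert ds.follow_up_days().nunique() == 1
        _, test = split_train_test(ds, 0.2)
        assert test.pi_ids == (sorted(ds.pi_ids)[0],)

    def test_zero_test_fraction_boundary(self):
        ds = generate_cohort(CohortConfig(n_pis=4, seed=5))
        with pytest.raises(ValueError):
            split_train_test(ds, 0.01)
        with pytest.raises(ValueError):
            split_train_test(ds, 1.2)
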