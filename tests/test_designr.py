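"""DESIGN-R 2020 scoring: totals, dummy coding, score changes."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pitrend.designr import (DEFAULT_CODING, SUBSCALES, DesignRAssessment,
                             MissingSubscaleError, SubscaleDummies,
                             SubscaleValueError, binarize_subscale,
                             score_change, total_score)


def make_assessment(**kwargs):
    base = dict(exudate=0, size=0, inflammation_infection=0, granulation=0,
                necrotic=0, pocket=0)
    base.update(kwargs)
    return DesignRAssessment(**base)


class TestTotalScore:
    def test_all_zero(self):
        assert total_score(make_assessment()) == 0

    def test_example_sum(self):
        a = make_assessment(exudate=3, size=8, inflammation_infection=1,
                            granulation=4, necrotic=3, pocket=0)
        assert total_score(a) == 19

    def test_depth_excluded(self):
        a = make_assessment(exudate=3, size=8, inflammation_infection=1,
                            granulation=4, necrotic=3, pocket=0, depth=4)
        assert total_score(a) == 19

    def test_infection_worsening_event(self):
        """A 9-point jump between consecutive totals (19 -> 28)."""
        before = make_assessment(exudate=3, size=8, inflammation_infection=1,
                                 granulation=4, necrotic=3, pocket=0)
        after = make_assessment(exudate=6, size=8, inflammation_infection=9,
                                granulation=5, necrotic=0, pocket=0)
        assert total_score(after) - total_score(before) == 9
        assert score_change(total_score(before), total_score(after)) == 9

    def test_missing_subscale(self):
        with pytest.raises(MissingSubscaleError, match="necrotic"):
            total_score(make_assessment(necrotic=None))

    def test_invalid_value_names_subscale(self):
        with pytest.raises(SubscaleValueError, match="exudate"):
            total_score(make_assessment(exudate=2))

    def test_monotone_in_each_subscale(self):
        baseline = total_score(make_assessment())
        for sub in SUBSCALES:
            previous = baseline
            for value in sorted(DEFAULT_CODING.permissible[sub] - {0}):
                now = total_score(make_assessment(**{sub: value}))
                assert now > previous - 1 and now == value
                previous = now


class TestDummies:
    @pytest.mark.parametrize("score,expected", [
        (6, (1, 0)), (3, (0, 1)), (1, (0, 1)), (0, (0, 0)),
    ])
    def test_exudate_rule(self, score, expected):
        dummies = binarize_subscale("exudate", score)
        assert (dummies.large, dummies.small) == expected

    @pytest.mark.parametrize("sub", SUBSCALES)
    def test_partition_consistency_all_values(self, sub):
        """Every permissible value maps to exactly one of zero/large/small,
        and the pair never sums above 1."""
        for value in sorted(DEFAULT_CODING.permissible[sub]):
            dummies = binarize_subscale(sub, value)
            assert dummies.large + dummies.small <= 1
            if value == 0:
                assert (dummies.large, dummies.small) == (0, 0)
            elif value in DEFAULT_CODING.large[sub]:
                assert (dummies.large, dummies.small) == (1, 0)
            else:
                assert (dummies.large, dummies.small) == (0, 1)

    def test_round_trip_partition_label(self):
        """The dummy pair identifies the value's partition losslessly."""
        for sub in SUBSCALES:
            for value in sorted(DEFAULT_CODING.permissible[sub]):
                dummies = binarize_subscale(sub, value)
                label = ("zero" if value == 0
                         else "large" if value in DEFAULT_CODING.large[sub]
                         else "small")
                recovered = {(0, 0): "zero", (1, 0): "large",
                             (0, 1): "small"}[(dummies.large, dummies.small)]
                assert recovered == label

    def test_invalid_score_rejected(self):
        with pytest.raises(SubscaleValueError, match="pocket"):
            binarize_subscale("pocket", 5)

    def test_both_dummies_set_rejected(self):
        with pytest.raises(ValueError):
            SubscaleDummies(1, 1)


class TestScoreChange:
    @pytest.mark.parametrize("y0,y1,expected", [
        (10, 10, 0), (19, 28, 9), (12, 5, -7),
    ])
    def test_examples(self, y0, y1, expected):
        assert score_change(y0, y1) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 66), st.integers(0, 66))
    def test_antisymmetric(self, a, b):
        assert score_change(a, b) == -score_change(b, a)


@settings(max_examples=30, deadline=None)
@given(st.permutations(list(SUBSCALES)))
def test_total_permutation_invariant(order):
    values = dict(zip(order, [3, 8, 1, 4, 3, 0]))
    a = DesignRAssessment(**{sub: values[sub] for sub in SUBSCALES})
    try:
        total = total_score(a)
    except SubscaleValueError:
        return  # permuted values need not be permissible for every subscale
    assert total == sum(values.values())
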