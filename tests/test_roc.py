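"""Unit and property tests for the ROC primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rocnet import (
    ConfigurationError,
    InvalidInputError,
    TransformParams,
    TwoGroupSample,
    auc,
    empirical_roc,
    median_mad_transform,
    roc_correlation,
    roc_distance,
    s_a_statistic,
)

from conftest import pairwise_auc

group = st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=30)


class TestEmpiricalROC:
    def test_identical_groups_give_diagonal(self):
        curve = empirical_roc(TwoGroupSample("f", [1, 2, 3], [1, 2, 3]))
        assert np.allclose(curve.tpr_points, curve.fpr_points)
        assert auc(curve) == pytest.approx(0.5, abs=1e-15)

    def test_perfect_separation(self, perfect_curve):
        assert (0.0, 1.0) in zip(perfect_curve.fpr_points, perfect_curve.tpr_points)
        assert auc(perfect_curve) == 1.0

    def test_endpoints_and_monotonicity(self, toy_sample):
        curve = empirical_roc(toy_sample)
        assert curve.fpr_points[0] == curve.tpr_points[0] == 0.0
        assert curve.fpr_points[-1] == curve.tpr_points[-1] == 1.0
        assert np.all(np.diff(curve.fpr_points) >= 0)
        assert np.all(np.diff(curve.tpr_points) >= 0)

    def test_tied_example_matches_pairwise_count(self, toy_sample):
        assert auc(empirical_roc(toy_sample)) == pytest.approx(7 / 9, abs=1e-15)

    @pytest.mark.parametrize("bad", [([], [1.0]), ([1.0], []), ([np.nan], [1.0])])
    def test_invalid_groups_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            TwoGroupSample("f", *bad)

    def test_evaluation_interpolates(self, toy_sample):
        curve = empirical_roc(toy_sample)
        ts = np.linspace(0, 1, 101)
        vals = curve(ts)
        assert np.all(np.diff(vals) >= -1e-15)
        assert np.all((vals >= 0) & (vals <= 1))


class TestAUC:
    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(200):
            n, m = rng.integers(1, 31, size=2)
            u = rng.integers(0, 8, size=n).astype(float)
            v = rng.integers(0, 8, size=m).astype(float)
            s = TwoGroupSample("f", u, v)
            assert auc(empirical_roc(s)) == pytest.approx(pairwise_auc(u, v), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(u=group, v=group)
    def test_group_swap_complements_auc(self, u, v):
        a = auc(empirical_roc(TwoGroupSample("f", u, v)))
        b = auc(empirical_roc(TwoGroupSample("f", v, u)))
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestSAStatistic:
    def test_identical_groups_zero(self):
        assert s_a_statistic(TwoGroupSample("f", [5, 5, 6], [5, 5, 6])) == 0.0

    def test_tied_example(self, toy_sample):
        assert s_a_statistic(toy_sample) == pytest.approx(np.sqrt(3) * 5 / 18, abs=1e-12)

    def test_perfect_separation_n4(self):
        s = TwoGroupSample("f", [10, 11, 12, 13], [1, 2, 3, 4])
        assert s_a_statistic(s) == pytest.approx(1.0, abs=1e-12)

    def test_protective_factor_also_scores(self):
        # AUC < 1/2 must produce the same statistic as its mirror image
        s = TwoGroupSample("f", [1, 2, 3], [4, 5, 6])
        sm = TwoGroupSample("f", [4, 5, 6], [1, 2, 3])
        assert s_a_statistic(s) == s_a_statistic(sm) == pytest.approx(np.sqrt(3) * 0.5)


class TestROCDistance:
    def test_self_distance_zero(self, toy_sample):
        curve = empirical_roc(toy_sample)
        for metric in ("l1", "l2", "sup", "auc_diff"):
            assert roc_distance(curve, curve, metric) == 0.0

    def test_diagonal_to_perfect(self, diagonal_curve, perfect_curve):
        assert roc_distance(diagonal_curve, perfect_curve) == pytest.approx(0.5, abs=1e-12)
        assert roc_distance(diagonal_curve, perfect_curve, "l2") == pytest.approx(
            np.sqrt(1 / 3), abs=1e-12
        )
        assert roc_distance(diagonal_curve, perfect_curve, "sup") == pytest.approx(1.0)
        assert roc_distance(diagonal_curve, perfect_curve, "auc_diff") == pytest.approx(0.5)

    def test_symmetry_on_random_curves(self, rng):
        for _ in range(25):
            a = empirical_roc(
                TwoGroupSample("a", rng.integers(0, 6, 12), rng.integers(0, 6, 9))
            )
            b = empirical_roc(
                TwoGroupSample("b", rng.integers(0, 6, 7), rng.integers(0, 6, 11))
            )
            for metric in ("l1", "l2", "sup"):
                assert roc_distance(a, b, metric) == pytest.approx(
                    roc_distance(b, a, metric), abs=1e-14
                )

    def test_l1_splits_sign_changes_exactly(self, rng):
        # quadrature oracle on a fine grid, one-sided limits irrelevant a.e.
        a = empirical_roc(TwoGroupSample("a", rng.normal(1, 1, 15), rng.normal(0, 1, 20)))
        b = empirical_roc(TwoGroupSample("b", rng.normal(0, 1, 15), rng.normal(1, 1, 20)))
        ts = np.linspace(0, 1, 200001)
        approx = np.trapezoid(np.abs(a(ts) - b(ts)), ts)
        assert roc_distance(a, b) == pytest.approx(approx, abs=1e-3)

    def test_unknown_metric_rejected(self, diagonal_curve):
        with pytest.raises(ConfigurationError):
            roc_distance(diagonal_curve, diagonal_curve, "hausdorff")


class TestROCCorrelation:
    def test_zero_distance_gives_one(self):
        assert roc_correlation(0.0) == 1.0
        assert roc_correlation(0.0, "exp_decay") == 1.0

    def test_inv1p_value(self):
        assert roc_correlation(0.5) == pytest.approx(2 / 3)

    @settings(max_examples=40, derandomize=True)
    @given(
        d1=st.floats(0, 10, allow_nan=False),
        d2=st.floats(0, 10, allow_nan=False),
        form=st.sampled_from(["inv1p", "exp_decay"]),
    )
    def test_strictly_decreasing(self, d1, d2, form):
        if d1 < d2:
            assert roc_correlation(d1, form) > roc_correlation(d2, form)

    def test_negative_distance_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_correlation(-0.1)
        with pytest.raises(ConfigurationError):
            roc_correlation(0.5, "linear")


class TestMonotoneInvariance:
    """Strictly increasing transforms leave every ROC-based quantity unchanged."""

    transforms = [np.exp, lambda x: 3.0 * x - 7.0, lambda x: x**3]

    @pytest.mark.parametrize("transform", transforms)
    def test_vertices_bit_identical(self, rng, transform):
        u = rng.normal(0.5, 1, 25)
        v = rng.normal(0, 1, 30)
        raw = empirical_roc(TwoGroupSample("f", u, v))
        mapped = empirical_roc(TwoGroupSample("f", transform(u), transform(v)))
        assert np.array_equal(raw.fpr_points, mapped.fpr_points)
        assert np.array_equal(raw.tpr_points, mapped.tpr_points)

    def test_s_a_unchanged(self, rng):
        u, v = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        assert s_a_statistic(TwoGroupSample("f", u, v)) == s_a_statistic(
            TwoGroupSample("f", np.exp(u), np.exp(v))
        )


class TestMedianMADTransform:
    def test_center_maps_to_half(self, rng):
        values = rng.normal(3, 2, 41)
        params = TransformParams.from_values(values)
        assert median_mad_transform([params.center], params)[0] == pytest.approx(0.5)

    def test_preserves_order_and_range(self, rng):
        values = np.sort(rng.normal(0, 5, 50))
        z = median_mad_transform(values)
        assert np.all(np.diff(z) > 0)
        assert np.all((z > 0) & (z < 1))

    def test_roc_unchanged_by_transform(self, rng):
        u, v = rng.normal(1, 1, 18), rng.normal(0, 1, 22)
        params = TransformParams.from_values(np.concatenate([u, v]))
        raw = empirical_roc(TwoGroupSample("f", u, v))
        z = empirical_roc(
            TwoGroupSample(
                "f", median_mad_transform(u, params), median_mad_transform(v, params)
            )
        )
        assert np.array_equal(raw.fpr_points, z.fpr_points)
        assert np.array_equal(raw.tpr_points, z.tpr_points)

    def test_zero_mad_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="median absolute deviation"):
            params = TransformParams.from_values([2.0, 2.0, 2.0])
        assert params.scale == 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            median_mad_transform([1.0, np.inf])
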