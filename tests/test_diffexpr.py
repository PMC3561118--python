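import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoxdep.diffexpr import (
    DEConfig,
    ThresholdPolicy,
    call_differential,
    differential_expression,
    estimate_s0,
    fold_change,
    permutation_qvalues,
    sam_statistic,
)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(4.0, 6.0, 4.0), (6.0, 4.0, -4.0), (5.0, 5.0, 1.0), (0.0, 1.0, 2.0)],
    )
    def test_signed_convention(self, a, b, expected):
        assert fold_change(a, b) == pytest.approx(expected)

    @given(
        a=st.floats(-10, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_for_non_unit_ratios(self, a, b):
        f_ab, f_ba = fold_change(a, b), fold_change(b, a)
        if f_ab == 1.0:  # unit ratio (incl. differences below float resolution)
            assert f_ba == 1.0
        else:
            assert f_ab == pytest.approx(-f_ba, rel=1e-9)

    def test_rejects_non_finite_means(self):
        with pytest.raises(ValueError):
            fold_change(float("nan"), 1.0)


class TestSamStatistic:
    def test_identical_groups_give_zero(self):
        assert sam_statistic([4.0, 4.2, 3.8], [4.0, 4.2, 3.8], s0=0.1) == 0.0

    def test_hand_computed_pooled_se(self):
        # SS_a = 0.02, SS_b = 0.08, s = sqrt((1/3+1/3)*0.1/4), d = 1/(s+0.1)
        s = math.sqrt((2 / 3) * 0.1 / 4)
        expected = 1.0 / (s + 0.1)
        got = sam_statistic([4.0, 4.1, 3.9], [5.0, 5.2, 4.8], s0=0.1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(4.3649, abs=1e-4)

    def test_antisymmetric_under_group_swap(self):
        a, b = [1.0, 1.5, 0.5], [2.0, 2.5, 3.0]
        assert sam_statistic(a, b, 0.05) == pytest.approx(-sam_statistic(b, a, 0.05))

    @given(s0=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_larger_s0_shrinks_magnitude(self, s0):
        a, b = [1.0, 1.2, 0.8], [2.0, 2.3, 1.7]
        assert abs(sam_statistic(a, b, 2 * s0)) < abs(sam_statistic(a, b, s0))

    def test_requires_two_values_per_group(self):
        with pytest.raises(ValueError):
            sam_statistic([1.0], [2.0, 3.0], 0.1)


class TestEstimateS0:
    def _matrix(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(7, 1, size=(n, 6))

    def test_fixed_mode(self):
        values = self._matrix()
        mask = np.array([True] * 3 + [False] * 3)
        assert estimate_s0(values, mask, ~mask, "fixed", 0.2) == 0.2

    def test_median_s_equals_common_s(self):
        # identical within-group deviations for every probe -> all s equal
        base = np.array([0.0, 0.1, -0.1, 0.0, 0.1, -0.1])
        values = np.tile(base, (15, 1)) + np.arange(15)[:, None]
        mask = np.array([True] * 3 + [False] * 3)
        s_common = math.sqrt((2 / 3) * 0.04 / 4)
        assert estimate_s0(values, mask, ~mask, "median_s") == pytest.approx(s_common)

    def test_cv_minimization_matches_loop_oracle(self):
        values = self._matrix(n=60, seed=3)
        mask = np.array([True] * 3 + [False] * 3)

        # independent oracle: plain-Python grid search over the same
        # percentile candidates and standard-error windows
        def pooled_s(row):
            a, b = row[:3], row[3:]
            ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            return math.sqrt((1 / 3 + 1 / 3) * ss / 4)

        s = np.array([pooled_s(row) for row in values])
        diff = values[:, 3:].mean(axis=1) - values[:, :3].mean(axis=1)
        n_groups = min(100, max(2, len(values) // 10))
        best, best_cv = None, math.inf
        for alpha in np.percentile(s, np.arange(0, 101, 5)):
            d = diff / (s + alpha)
            order = np.argsort(s, kind="mergesort")
            mads = []
            for chunk in np.array_split(order, n_groups):
                dd = d[chunk]
                mads.append(np.median(np.abs(dd - np.median(dd))) / 0.64)
            mads = np.array(mads)
            cv = mads.std(ddof=1) / mads.mean()
            if cv < best_cv:
                best, best_cv = alpha, cv
        assert estimate_s0(values, mask, ~mask, "cv_minimization") == pytest.approx(best)

    def test_cv_minimization_needs_enough_probes(self):
        values = self._matrix(n=5)
        mask = np.array([True] * 3 + [False] * 3)
        with pytest.raises(ValueError):
            estimate_s0(values, mask, ~mask, "cv_minimization")


class TestPermutationQvalues:
    mask_a = np.array([True] * 3 + [False] * 3)

    def test_constant_matrix_gives_q_one(self):
        values = np.full((20, 6), 5.0)
        d, q, meta = permutation_qvalues(
            values, self.mask_a, ~self.mask_a, DEConfig(s0_mode="fixed", s0_fixed=0.1)
        )
        assert np.all(d == 0)
        assert np.all(q == 1.0)
        assert meta["exhaustive"]

    def test_dominant_probe_gets_q_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 0.05, size=(30, 6))
        values[0, 3:] += 50.0  # |d| beyond any permuted value
        d, q, _ = permutation_qvalues(
            values, self.mask_a, ~self.mask_a, DEConfig(s0_mode="fixed", s0_fixed=0.05)
        )
        assert abs(d[0]) == max(abs(d))
        assert q[0] == 0.0

    def test_swap_negates_d_and_preserves_q(self):
        rng = np.random.default_rng(1)
        values = rng.normal(7, 1, size=(25, 6))
        cfg = DEConfig(s0_mode="fixed", s0_fixed=0.1)
        d1, q1, _ = permutation_qvalues(values, self.mask_a, ~self.mask_a, cfg)
        d2, q2, _ = permutation_qvalues(values, ~self.mask_a, self.mask_a, cfg)
        np.testing.assert_allclose(d1, -d2)
        np.testing.assert_allclose(q1, q2)

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(2)
        values = rng.normal(7, 1, size=(50, 6))
        d, q, _ = permutation_qvalues(
            values, self.mask_a, ~self.mask_a, DEConfig(s0_mode="fixed", s0_fixed=0.1)
        )
        order = np.argsort(-np.abs(d))
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_degenerate_grouping_rejected(self):
        values = np.zeros((5, 6))
        with pytest.raises(ValueError):
            permutation_qvalues(
                values,
                np.array([True] + [False] * 5),
                np.array([False] + [True] * 5),
                DEConfig(),
            )


class TestCallDifferential:
    def _result(self, fold, q):
        mean_a = 5.0
        mean_b = mean_a + math.log2(abs(fold)) * (1 if fold > 0 else -1)
        return pd.DataFrame(
            {
                "mean_log2_a": [mean_a],
                "mean_log2_b": [mean_b],
                "fold_change_signed": [fold],
                "d_statistic": [1.0],
                "q_value": [q],
            },
            index=pd.Index(["p0"], name="probe_id"),
        )

    @pytest.mark.parametrize(
        "fold, q, included, direction",
        [
            (1.6, 0.005, True, "up"),
            (1.4, 0.001, False, None),  # fold gate dominates a perfect q
            (-1.6, 0.009, True, "down"),
            (1.6, 0.01, False, None),  # gate is strict: q must be < max_q
        ],
    )
    def test_gating(self, fold, q, included, direction):
        gs = call_differential(self._result(fold, q), ThresholdPolicy(1.5, 0.01), "t")
        if included:
            assert gs.members == {"p0": direction}
        else:
            assert len(gs) == 0


def test_differential_expression_orientation(tiny_matrix):
    """'a vs b' reports b relative to a: hypoxic induction is positive."""
    res = differential_expression(
        tiny_matrix,
        ("control", "normoxia"),
        ("control", "hypoxia"),
        DEConfig(s0_mode="fixed", s0_fixed=0.1),
    )
    assert res.loc["p0", "fold_change_signed"] > 1.5
    assert res.loc["p0", "q_value"] <= res["q_value"].min() + 1e-12
    assert res.attrs["exhaustive"]
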