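"""ddCq quantification, rank-sum testing and cross-threshold comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qpcrarray.core import CqMatrix
from qpcrarray.expression import (
    compare_thresholds,
    cross_method_agreement,
    ddcq_fold_change,
    delta_cq,
    differential_expression,
    group_test,
)


def _matrix(values: pd.DataFrame, groups=None) -> CqMatrix:
    if groups is None:
        groups = {s: "g" for s in values.columns}
    return CqMatrix(values, groups)


def _enumerated_ranksum_p(x, y):
    """Independent oracle: full enumeration of the rank-sum null (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    eps = 1e-9
    p_le = np.mean([s <= w + eps for s in sums])
    p_ge = np.mean([s >= w - eps for s in sums])
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestDeltaCq:
    def test_simple_difference(self):
        values = pd.DataFrame({"s1": [25.0, 20.0]}, index=["T", "REF"])
        d = delta_cq(_matrix(values), "T", "REF")
        assert d["s1"] == pytest.approx(5.0)

    def test_target_equals_reference_all_zero(self):
        values = pd.DataFrame({f"s{i}": [22.0, 22.0] for i in range(5)},
                              index=["T", "REF"])
        assert (delta_cq(_matrix(values), "T", "REF") == 0).all()

    def test_missing_target_cq_excluded(self):
        row = [25.0] * 9 + [np.nan]
        values = pd.DataFrame(
            dict(zip([f"s{i}" for i in range(10)], zip(row, [20.0] * 10))),
            index=["T", "REF"],
        )
        assert len(delta_cq(_matrix(values), "T", "REF")) == 9

    def test_normalization_missing_for_observed_sample_error(self):
        values = pd.DataFrame({"s1": [25.0], "s2": [26.0]}, index=["T"])
        norm = pd.Series({"s1": 20.0})
        with pytest.raises(ValueError, match="s2"):
            delta_cq(_matrix(values), "T", norm)


class TestFoldChange:
    @pytest.mark.parametrize(
        "ddcq, fc",
        [(0.0, 1.0), (-1.0, 2.0), (2.0, -4.0), (1.0, -2.0), (-2.0, 4.0)],
    )
    def test_negative_inverse_convention(self, ddcq, fc):
        got_ddcq, got_fc = ddcq_fold_change([ddcq], [0.0])
        assert got_ddcq == pytest.approx(ddcq)
        assert got_fc == pytest.approx(fc)

    def test_fold_change_never_in_open_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, fc = ddcq_fold_change(rng.normal(0, 2, 5), rng.normal(0, 2, 5))
            assert abs(fc) >= 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
            _, fc = ddcq_fold_change(a, b)
            _, fc_swapped = ddcq_fold_change(b, a)
            if abs(fc) > 1:
                assert fc_swapped == pytest.approx(-fc)
            else:
                assert fc_swapped == pytest.approx(1.0)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            ddcq_fold_change([], [1.0])


class TestGroupTest:
    def test_identical_small_groups_p_one(self):
        assert group_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_most_extreme_arrangement(self):
        # most extreme of C(6,3)=20 orderings: one-sided 1/20, two-sided 0.1
        assert group_test([10, 11, 12], [1, 2, 3]) == pytest.approx(0.1)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        assert group_test(x, y) == pytest.approx(group_test(x + 100, y + 100))

    def test_matches_enumeration_all_sizes_to_five(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                x = rng.normal(0, 1, n1)
                y = rng.normal(0.5, 1, n2)
                assert group_test(x, y) == pytest.approx(
                    _enumerated_ranksum_p(x, y), abs=1e-12
                )

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(0, 3, 5).astype(float)
            y = rng.integers(0, 3, 5).astype(float)
            assert group_test(x, y) == pytest.approx(
                _enumerated_ranksum_p(x, y), abs=1e-12
            )

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            group_test([], [1.0])


class TestDifferentialExpression:
    def test_known_shift_recovered(self):
        rng = np.random.default_rng(5)
        n = 10
        samples = [f"s{i}" for i in range(2 * n)]
        groups = {s: ("case" if i < n else "control") for i, s in enumerate(samples)}
        ref = rng.normal(20, 0.01, 2 * n)
        target = ref + 3.0  # dCq 3 in both groups
        target[:n] -= 1.0   # case expressed 1 cycle earlier -> FC 2 up
        values = pd.DataFrame([target, ref], index=["T", "REF"], columns=samples)
        res = differential_expression(_matrix(values, groups), "REF", "case", "control")
        row = res.set_index("target_id").loc["T"]
        assert row["delta_delta_cq"] == pytest.approx(-1.0, abs=0.02)
        assert row["fold_change"] == pytest.approx(2.0, abs=0.05)
        assert row["p_value"] < 0.01

    def test_constant_added_to_all_cq_cancels(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(12)]
        groups = {s: ("case" if i < 6 else "control") for i, s in enumerate(samples)}
        values = pd.DataFrame(
            rng.uniform(18, 28, (3, 12)), index=["T1", "T2", "REF"], columns=samples
        )
        a = differential_expression(_matrix(values, groups), "REF", "case", "control")
        b = differential_expression(
            _matrix(values + 5.0, groups), "REF", "case", "control"
        )
        pd.testing.assert_frame_equal(a, b)


class TestCompareThresholds:
    def _three_matrices(self, shift=0.0, seed=0, n=30):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        groups = {s: "g" for s in samples}
        base = rng.normal(25, 0.5, (1, n))
        out = {}
        for i, method in enumerate(("fixed", "automatic", "relative")):
            vals = base.copy()
            if method == "fixed":
                vals = vals + shift
            out[method] = _matrix(
                pd.DataFrame(vals, index=["T"], columns=samples), groups
            )
        return out

    def test_identical_matrices_no_flags(self):
        comp = compare_thresholds(self._three_matrices(shift=0.0))
        assert comp.per_target["kw_p"].iloc[0] == pytest.approx(1.0)
        assert not comp.per_target["flagged"].any()

    def test_shifted_method_flagged_and_isolated(self):
        comp = compare_thresholds(self._three_matrices(shift=3.0, seed=1))
        assert comp.per_target["flagged"].iloc[0]
        dunn = comp.dunn
        involves = dunn.apply(
            lambda r: "fixed" in (r["group_a"], r["group_b"]), axis=1
        )
        assert (dunn.loc[involves, "p_adjusted"] < 0.05).all()
        assert (dunn.loc[~involves, "p_adjusted"] >= 0.05).all()

    def test_flags_monotone_in_alpha(self):
        matrices = self._three_matrices(shift=1.0, seed=2)
        strict = compare_thresholds(matrices, flag_alpha=0.01)
        loose = compare_thresholds(matrices, flag_alpha=0.05)
        strict_set = set(strict.per_target.loc[strict.per_target["flagged"], "target_id"])
        loose_set = set(loose.per_target.loc[loose.per_target["flagged"], "target_id"])
        assert strict_set <= loose_set

    def test_fewer_than_two_methods_error(self):
        m = self._three_matrices()
        with pytest.raises(ValueError):
            compare_thresholds({"fixed": m["fixed"]})


class TestCrossMethodAgreement:
    def _results(self, fc, p, label):
        return pd.DataFrame(
            {"target_id": [f"T{i}" for i in range(len(fc))],
             "fold_change": fc, "p_value": p, "method_label": label}
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(7)
        fc, p = rng.normal(0, 2, 10), rng.uniform(0, 1, 10)
        res = {m: self._results(fc, p, m) for m in ("a", "b")}
        fc_corr, p_corr = cross_method_agreement(res)
        assert fc_corr.loc["a", "b"] == pytest.approx(1.0)
        assert p_corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(fc_corr), 1.0)

    def test_perturbed_method_correlates_less(self):
        rng = np.random.default_rng(8)
        fc = rng.normal(0, 2, 40)
        p = rng.uniform(0, 1, 40)
        res = {
            "crt": self._results(fc + rng.normal(0, 0.05, 40), p, "crt"),
            "automatic": self._results(fc + rng.normal(0, 0.05, 40), p, "automatic"),
            "fixed": self._results(fc + rng.normal(0, 2.0, 40),
                                   np.clip(p + rng.normal(0, 0.4, 40), 1e-6, 1), "fixed"),
        }
        fc_corr, _ = cross_method_agreement(res)
        assert fc_corr.loc["crt", "automatic"] > fc_corr.loc["crt", "fixed"]
        assert fc_corr.loc["crt", "automatic"] > fc_corr.loc["automatic", "fixed"]
        assert (fc_corr.to_numpy() == fc_corr.to_numpy().T).all()

    def test_too_few_shared_targets_error(self):
        res = {m: self._results([1.0, 2.0], [0.5, 0.5], m) for m in ("a", "b")}
        with pytest.raises(ValueError):
            cross_method_agreement(res)
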