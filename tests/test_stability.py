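"""Reference-stability statistics against hand computations and brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qpcrarray.core import CqMatrix
from qpcrarray.simulate import simulate_cq_dataset
from qpcrarray.stability import (
    bestkeeper_stats,
    comprehensive_rank,
    deltact_stability,
    factor_group_stability,
    genorm_m,
    genorm_stepwise_ranking,
    geometric_mean_factor,
    normfinder_stability,
    reference_vs_factor_agreement,
    stability_report,
)


def _matrix(values: pd.DataFrame, groups=None) -> CqMatrix:
    if groups is None:
        groups = {s: "g" for s in values.columns}
    return CqMatrix(values, groups)


def _brute_force_pairwise(values: pd.DataFrame) -> pd.Series:
    """Independent double-loop mean pairwise SD (the geNorm/delta-Ct oracle)."""
    out = {}
    for j in values.index:
        sds = []
        for k in values.index:
            if k == j:
                continue
            diff = values.loc[j] - values.loc[k]
            sds.append(np.std(diff.to_numpy(), ddof=1))
        out[j] = float(np.mean(sds))
    return pd.Series(out)


@pytest.fixture
def abc_matrix():
    values = pd.DataFrame(
        {"s1": [20.0, 20, 20], "s2": [21.0, 21, 22], "s3": [22.0, 22, 24]},
        index=["A", "B", "C"],
    )
    return _matrix(values)


class TestBestKeeper:
    def test_hand_computed_sd_cv(self):
        values = pd.DataFrame({"s1": [20.0], "s2": [22.0], "s3": [24.0]}, index=["T"])
        sd, cv = bestkeeper_stats(_matrix(values), "T")
        assert sd == pytest.approx(2.0)
        assert cv == pytest.approx(100 * 2.0 / 22.0)

    def test_constant_target_zero(self):
        values = pd.DataFrame({f"s{i}": [25.0] for i in range(4)}, index=["T"])
        sd, cv = bestkeeper_stats(_matrix(values), "T")
        assert sd == 0.0 and cv == 0.0

    def test_shift_changes_cv_not_sd(self):
        base = pd.DataFrame({"s1": [20.0], "s2": [22.0], "s3": [24.0]}, index=["T"])
        sd0, cv0 = bestkeeper_stats(_matrix(base), "T")
        sd1, cv1 = bestkeeper_stats(_matrix(base + 10.0), "T")
        assert sd1 == pytest.approx(sd0)
        assert cv1 != pytest.approx(cv0)

    def test_too_few_samples_error(self):
        values = pd.DataFrame({"s1": [20.0], "s2": [22.0]}, index=["T"])
        with pytest.raises(ValueError):
            bestkeeper_stats(_matrix(values), "T")


class TestPairwiseStability:
    def test_genorm_hand_example(self, abc_matrix):
        m = genorm_m(abc_matrix)
        assert m["A"] == pytest.approx(0.5)
        assert m["B"] == pytest.approx(0.5)
        assert m["C"] == pytest.approx(1.0)

    def test_deltact_same_hand_example(self, abc_matrix):
        d = deltact_stability(abc_matrix)
        assert d.to_dict() == pytest.approx({"A": 0.5, "B": 0.5, "C": 1.0})

    def test_identical_profiles_all_zero(self):
        values = pd.DataFrame(
            {f"s{i}": [20.0 + i, 20 + i, 20 + i] for i in range(4)},
            index=["A", "B", "C"],
        )
        assert (genorm_m(_matrix(values)) == 0).all()

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            values = pd.DataFrame(
                rng.uniform(18, 32, size=(6, 10)),
                index=[f"T{i}" for i in range(6)],
                columns=[f"s{j}" for j in range(10)],
            )
            m = _matrix(values)
            oracle = _brute_force_pairwise(values)
            assert np.allclose(genorm_m(m), oracle.reindex(values.index), atol=1e-10)
            assert np.allclose(deltact_stability(m), oracle.reindex(values.index), atol=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.uniform(18, 30, (4, 8)),
                              index=list("WXYZ"), columns=[f"s{j}" for j in range(8)])
        assert np.allclose(genorm_m(_matrix(values)), genorm_m(_matrix(values + 5.0)))

    def test_incomplete_candidate_rejected(self):
        values = pd.DataFrame(
            {"s1": [20.0, 21, 22], "s2": [20.0, np.nan, 22], "s3": [20.0, 21, 22]},
            index=["A", "B", "C"],
        )
        with pytest.raises(ValueError, match="100%"):
            genorm_m(_matrix(values))

    def test_fewer_than_three_candidates_error(self):
        values = pd.DataFrame({"s1": [20.0, 21], "s2": [20.0, 21], "s3": [21.0, 22]},
                              index=["A", "B"])
        with pytest.raises(ValueError):
            genorm_m(_matrix(values))

    def test_stepwise_ranking_orders_worst_last(self, abc_matrix):
        ranks = genorm_stepwise_ranking(abc_matrix)
        assert ranks["C"] == 3.0
        assert ranks["A"] == ranks["B"] == 1.5


class TestNormFinder:
    def test_zero_variance_candidate_attains_minimum(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            rng.normal(25, 1.0, (5, 10)),
            index=[f"T{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(10)],
        )
        values.loc["T0"] = 25.0  # flat profile
        nf = normfinder_stability(_matrix(values))
        assert nf.idxmin() == "T0"

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.normal(25, 0.8, (5, 12)),
            index=[f"T{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(12)],
        )
        groups = {f"s{j}": ("a" if j < 6 else "b") for j in range(12)}
        a = normfinder_stability(_matrix(values, groups))
        b = normfinder_stability(_matrix(values + 7.0, groups))
        assert np.allclose(a, b, atol=1e-9)  # invariant up to float roundoff

    def test_group_shifted_candidate_ranks_worse(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            values = pd.DataFrame(
                rng.normal(25, 0.3, (6, 20)),
                index=[f"T{i}" for i in range(6)],
                columns=[f"s{j}" for j in range(20)],
            )
            groups = {f"s{j}": ("a" if j < 10 else "b") for j in range(20)}
            values.loc["T0", [f"s{j}" for j in range(10, 20)]] += 1.0
            nf = normfinder_stability(_matrix(values, groups))
            if nf["T0"] == nf.max():
                hits += 1
        assert hits >= 19

    def test_small_group_error(self):
        values = pd.DataFrame(
            np.random.default_rng(0).normal(25, 0.5, (3, 3)),
            index=["A", "B", "C"], columns=["s0", "s1", "s2"],
        )
        groups = {"s0": "a", "s1": "a", "s2": "b"}
        with pytest.raises(ValueError, match="at least 2"):
            normfinder_stability(_matrix(values, groups))


class TestComprehensiveRank:
    def test_geometric_mean_of_alternating_ranks(self):
        ranks = pd.DataFrame(
            {"m1": [1, 2], "m2": [2, 1], "m3": [1, 2], "m4": [2, 1]}, index=["X", "Y"]
        )
        out = comprehensive_rank(ranks)
        assert out.loc["X", "comprehensive_score"] == pytest.approx(np.sqrt(2))
        # tie broken lexicographically
        assert out.loc["X", "final_rank"] == 1
        assert out.loc["Y", "final_rank"] == 2

    def test_unanimous_first_is_first(self):
        ranks = pd.DataFrame(
            {"m1": [1, 2, 3], "m2": [1, 3, 2], "m3": [1, 2, 3], "m4": [1, 3, 2]},
            index=["best", "b", "c"],
        )
        out = comprehensive_rank(ranks)
        assert out.loc["best", "comprehensive_score"] == pytest.approx(1.0)
        assert out.loc["best", "final_rank"] == 1

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ranks = pd.DataFrame(
                {m: rng.permutation(5) + 1 for m in ("m1", "m2", "m3", "m4")},
                index=[f"T{i}" for i in range(5)],
            )
            out = comprehensive_rank(ranks)
            brute = sorted(
                ranks.index,
                key=lambda t: (float(np.prod(ranks.loc[t])) ** 0.25, t),
            )
            by_rank = out.sort_values("final_rank").index.tolist()
            assert by_rank == brute

    def test_mismatched_candidate_sets_error(self):
        ranks = pd.DataFrame({"m1": [1, 2], "m2": [1, np.nan]}, index=["X", "Y"])
        with pytest.raises(ValueError):
            comprehensive_rank(ranks)


class TestGeometricMeanFactor:
    def test_two_and_eight_give_four(self):
        values = pd.DataFrame({"s1": [2.0, 8.0]}, index=["A", "B"])
        nf = geometric_mean_factor(_matrix(values), ["A", "B"])
        assert nf.values["s1"] == pytest.approx(4.0)
        assert nf.kind == "geometric_mean"

    def test_constant_targets_give_constant(self):
        values = pd.DataFrame({f"s{i}": [20.0, 20.0, 20.0] for i in range(4)},
                              index=["A", "B", "C"])
        nf = geometric_mean_factor(_matrix(values))
        assert np.allclose(nf.values, 20.0)

    def test_nonpositive_values_rejected_at_boundary(self):
        # the Cq container itself refuses zero/negative values, so a
        # geometric mean over matrix targets is always well defined
        values = pd.DataFrame({"s1": [0.0, 20.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            _matrix(values)

    def test_incomplete_targets_excluded_by_default(self):
        values = pd.DataFrame(
            {"s1": [2.0, 8.0, 5.0], "s2": [2.0, 8.0, np.nan]},
            index=["A", "B", "C"],
        )
        nf = geometric_mean_factor(_matrix(values))
        assert nf.values["s1"] == pytest.approx(4.0)  # C not included


class TestFactorStability:
    def test_identical_groups_stable(self):
        values = pd.Series(
            [20.0, 21, 22, 20, 21, 22], index=[f"s{i}" for i in range(6)]
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        p, verdict = factor_group_stability(values, groups)
        assert p == pytest.approx(1.0)
        assert verdict == "stable"

    def test_shifted_group_unstable(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(20):
            a = rng.normal(20.0, 0.1, 15)
            b = rng.normal(22.0, 0.1, 15)
            values = pd.Series(
                np.concatenate([a, b]), index=[f"s{i}" for i in range(30)]
            )
            groups = {f"s{i}": ("a" if i < 15 else "b") for i in range(30)}
            p, verdict = factor_group_stability(values, groups)
            if verdict == "unstable":
                hits += 1
        assert hits == 20

    def test_all_tied_small_groups_p_one(self):
        values = pd.Series([20.0] * 6, index=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        p, verdict = factor_group_stability(values, groups)
        assert p == pytest.approx(1.0)
        assert verdict == "stable"

    def test_groups_below_three_warn_and_use_exact_test(self):
        values = pd.Series([20.0, 21.0, 22.0, 23.0], index=list("wxyz"))
        groups = {"w": "a", "x": "a", "y": "b", "z": "b"}
        with pytest.warns(UserWarning, match="exact"):
            p, _ = factor_group_stability(values, groups)
        assert 0 < p <= 1.0


class TestReferenceVsFactor:
    def test_factor_equal_to_reference_r_one(self):
        values = pd.DataFrame(
            {f"s{i}": [20.0 + i, 25.0] for i in range(5)}, index=["REF", "T"]
        )
        m = _matrix(values)
        r, p = reference_vs_factor_agreement(m, "REF", values.loc["REF"])
        assert r == pytest.approx(1.0)

    def test_global_shift_card_high_agreement(self):
        rng = np.random.default_rng(7)
        shifts = rng.normal(0.0, 1.0, 30)
        values = pd.DataFrame(
            {
                f"s{j}": 22.0 + shifts[j] + rng.normal(0, 0.05, 10)
                for j in range(30)
            },
            index=[f"T{i}" for i in range(10)],
        )
        m = _matrix(values)
        nf = geometric_mean_factor(m)
        r, _ = reference_vs_factor_agreement(m, "T0", nf)
        assert r > 0.95

    def test_too_few_samples_error(self):
        values = pd.DataFrame({"s1": [20.0], "s2": [21.0]}, index=["T"])
        m = _matrix(values)
        with pytest.raises(ValueError):
            reference_vs_factor_agreement(m, "T", values.loc["T"])


class TestStabilityReport:
    def test_rank_recovery_single_replicate(self):
        ds = simulate_cq_dataset(
            n_targets=20,
            groups={"patient": 25, "control": 25},
            stable_targets=1,
            target_sd=0.5,
            stable_sd=0.05,
            seed=12,
        )
        report = stability_report(ds.matrix)
        assert report.iloc[0]["target_id"] == ds.stable_targets[0]

    def test_report_has_all_columns_and_ranks(self):
        ds = simulate_cq_dataset(n_targets=6, groups={"a": 5, "b": 5}, seed=1)
        report = stability_report(ds.matrix)
        for col in (
            "bestkeeper_sd", "bestkeeper_cv", "genorm_m", "normfinder_value",
            "deltact_mean_sd", "rank_bestkeeper", "rank_genorm",
            "rank_normfinder", "rank_deltact", "comprehensive_score", "final_rank",
        ):
            assert col in report.columns
        assert sorted(report["final_rank"]) == list(range(1, 7))
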