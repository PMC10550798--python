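"""Relative quantification (2^-ddCq) and cross-threshold comparison.

Fold changes follow the comparative-Cq convention: ddCq is the difference
of group mean dCq (case minus control), RQ = 2^-ddCq, and reductions are
reported as the negative inverse (-1/RQ) so that |FC| >= 1 always and the
sign encodes direction.  Group comparisons use the two-sided Wilcoxon
rank-sum test, exact by full enumeration of the rank-sum null for small
groups and normal approximation with tie correction otherwise.

The cross-threshold operations quantify how much the choice of Cq
threshold algorithm changes the final results: per-target Kruskal-Wallis
tests with Dunn's post hoc comparisons across the methods' Cq
distributions, and Pearson correlation matrices of the per-target fold
changes and p values between methods.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CqMatrix
from .stability import NormalizationFactor

__all__ = [
    "ThresholdComparison",
    "compare_thresholds",
    "cross_method_agreement",
    "ddcq_fold_change",
    "delta_cq",
    "differential_expression",
    "dunn_posthoc",
    "group_test",
]

#: largest number of rank-sum arrangements enumerated exactly
_EXACT_LIMIT = 20000


def delta_cq(
    matrix: CqMatrix,
    target: str,
    normalization: NormalizationFactor | pd.Series | str,
) -> pd.Series:
    """Per-sample dCq: target Cq minus the normalization value.

    ``normalization`` is a per-sample factor (or a reference target id,
    resolved against the matrix).  Samples with missing target Cq are
    excluded, never imputed; a sample with an observed target Cq but no
    normalization value is an error.
    """
    if isinstance(normalization, str):
        norm = matrix.values.loc[normalization]
    elif isinstance(normalization, NormalizationFactor):
        norm = normalization.values
    else:
        norm = normalization
    cq = matrix.values.loc[target]
    observed = cq.dropna()
    missing_norm = [s for s in observed.index if s not in norm.index or not np.isfinite(norm[s])]
    if missing_norm:
        raise ValueError(f"normalization undefined for samples {missing_norm}")
    return observed - norm.reindex(observed.index)


def ddcq_fold_change(
    delta_cq_case: Sequence[float], delta_cq_control: Sequence[float]
) -> tuple[float, float]:
    """(ddCq, fold change) from case and control dCq values.

    ddCq = mean(case dCq) - mean(control dCq); FC = 2^-ddCq when >= 1,
    else the negative inverse, so FC never falls in (-1, 1).
    """
    case = np.asarray(delta_cq_case, dtype=float)
    control = np.asarray(delta_cq_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one dCq value")
    ddcq = float(case.mean() - control.mean())
    rq = 2.0 ** (-ddcq)
    fc = rq if rq >= 1.0 else -1.0 / rq
    return ddcq, fc


def group_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact by full enumeration of the rank-sum distribution (midranks for
    ties) when the number of arrangements is manageable; otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n = x.size, x.size + y.size
    if math.comb(n, n1) <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w = float(ranks[:n1].sum())
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(ranks, n1)),
            dtype=float,
            count=math.comb(n, n1),
        )
        eps = 1e-9
        p_le = np.mean(sums <= w + eps)
        p_ge = np.mean(sums >= w - eps)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def differential_expression(
    matrix: CqMatrix,
    normalization: NormalizationFactor | pd.Series | str,
    case: str,
    control: str,
    method_label: str = "",
) -> pd.DataFrame:
    """Per-target ddCq analysis between two groups.

    Returns one row per target: group mean and median dCq, ddCq, fold
    change (negative-inverse convention) and the Wilcoxon rank-sum
    p value.  The group means drive the fold change; medians are
    reported alongside for robustness checks.  Targets with fewer than
    two observed samples in either group are skipped.
    """
    groups = matrix.groups
    rows = []
    for target in matrix.target_ids:
        if isinstance(normalization, str) and target == normalization:
            continue
        dcq = delta_cq(matrix, target, normalization)
        dcq_case = dcq[[s for s in dcq.index if groups[s] == case]]
        dcq_ctrl = dcq[[s for s in dcq.index if groups[s] == control]]
        if len(dcq_case) < 2 or len(dcq_ctrl) < 2:
            continue
        ddcq, fc = ddcq_fold_change(dcq_case, dcq_ctrl)
        p = group_test(dcq_case.to_numpy(), dcq_ctrl.to_numpy())
        rows.append(
            {
                "target_id": target,
                "mean_dcq_case": float(dcq_case.mean()),
                "mean_dcq_control": float(dcq_ctrl.mean()),
                "median_dcq_case": float(dcq_case.median()),
                "median_dcq_control": float(dcq_ctrl.median()),
                "delta_delta_cq": ddcq,
                "fold_change": fc,
                "p_value": p,
                "method_label": method_label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# threshold-method comparison
# ---------------------------------------------------------------------------

def dunn_posthoc(
    samples: Mapping[str, np.ndarray], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's post hoc pairwise comparisons after a Kruskal-Wallis test.

    Z statistics are differences of mean pooled ranks scaled by the
    tie-corrected null SD; p values are two-sided and adjusted for the
    number of pairs (Holm by default).
    """
    labels = list(samples)
    values = [np.asarray(samples[g], dtype=float) for g in labels]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, v in zip(labels, values):
        sizes[g] = v.size
        mean_ranks[g] = float(ranks[start : start + v.size].mean())
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(max(base_var, 0.0) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    return out


@dataclass
class ThresholdComparison:
    """Per-target cross-method distribution tests and their flags."""

    per_target: pd.DataFrame  # target_id, kw_statistic, kw_p, flagged
    dunn: pd.DataFrame        # target_id, group_a, group_b, z, p_value, p_adjusted
    flag_alpha: float


def compare_thresholds(
    cq_by_method: Mapping[str, CqMatrix],
    flag_alpha: float = 0.01,
    adjust: str = "holm",
) -> ThresholdComparison:
    """Compare Cq distributions produced by different threshold methods.

    For every target shared by all methods, a Kruskal-Wallis test across
    the methods' observed Cq values, followed by Dunn's post hoc pairwise
    comparisons; targets with KW p below ``flag_alpha`` are flagged as
    threshold-sensitive.
    """
    if len(cq_by_method) < 2:
        raise ValueError("need at least two threshold methods to compare")
    methods = list(cq_by_method)
    shared = set(cq_by_method[methods[0]].target_ids)
    for m in methods[1:]:
        shared &= set(cq_by_method[m].target_ids)
    shared = sorted(shared)
    if not shared:
        raise ValueError("no shared targets across methods")

    kw_rows, dunn_rows = [], []
    for target in shared:
        per_method = {
            m: cq_by_method[m].values.loc[target].dropna().to_numpy()
            for m in methods
        }
        if any(v.size < 2 for v in per_method.values()):
            continue
        pooled = np.concatenate(list(per_method.values()))
        if np.allclose(pooled, pooled[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*per_method.values())
        kw_rows.append(
            {
                "target_id": target,
                "kw_statistic": float(stat),
                "kw_p": float(p),
                "flagged": bool(p < flag_alpha),
            }
        )
        if p < flag_alpha:
            d = dunn_posthoc(per_method, adjust=adjust)
            d.insert(0, "target_id", target)
            dunn_rows.append(d)
    dunn = (
        pd.concat(dunn_rows, ignore_index=True)
        if dunn_rows
        else pd.DataFrame(
            columns=["target_id", "group_a", "group_b", "z", "p_value", "p_adjusted"]
        )
    )
    return ThresholdComparison(
        per_target=pd.DataFrame(kw_rows), dunn=dunn, flag_alpha=flag_alpha
    )


def cross_method_agreement(
    results_by_method: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrices of fold changes and p values between
    threshold methods, over the targets shared by all methods.

    Each input frame is a :func:`differential_expression` result.
    Returns (fc_corr, p_corr), symmetric with unit diagonal.
    """
    methods = list(results_by_method)
    indexed = {
        m: results_by_method[m].set_index("target_id") for m in methods
    }
    shared = set(indexed[methods[0]].index)
    for m in methods[1:]:
        shared &= set(indexed[m].index)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared targets for correlation")
    fc = pd.DataFrame({m: indexed[m].loc[shared, "fold_change"] for m in methods})
    pv = pd.DataFrame({m: indexed[m].loc[shared, "p_value"] for m in methods})
    return fc.corr(method="pearson"), pv.corr(method="pearson")
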