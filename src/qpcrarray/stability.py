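"""Reference-miRNA stability ranking and normalization factors.

Implements the four standard stability statistics and their consensus:

* BestKeeper — sample SD and CV of a candidate's Cq across samples;
* geNorm — M value: mean pairwise SD of Cq differences with every other
  candidate (Cq is already log2-scale, so a Cq difference is the log2
  expression ratio);
* comparative delta-Ct — the same pairwise SDs, averaged per candidate
  without geNorm's stepwise exclusion;
* NormFinder — model-based decomposition into intragroup variance and
  intergroup deviation, with empirical-Bayes shrinkage of the group
  effects;

plus the comprehensive rank: the geometric mean of a candidate's 1-based
ranks under the four methods (ties receive average ranks), ordered
ascending.  Lower is more stable for every statistic.

All functions require complete candidates (call rate 100%): stability of
a target that is missing in some samples is undefined here, and passing
one raises an error rather than silently dropping samples.

The global-normalization alternative is also provided: the per-sample
geometric mean of Cq over all complete targets of a card, with a
group-stability check (a normalization factor that differs systematically
between the compared groups would bias every fold change).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CqMatrix

__all__ = [
    "NormalizationFactor",
    "bestkeeper_stats",
    "comprehensive_rank",
    "deltact_stability",
    "factor_group_stability",
    "genorm_m",
    "genorm_stepwise_ranking",
    "geometric_mean_factor",
    "normfinder_stability",
    "reference_vs_factor_agreement",
    "stability_report",
]


def _candidate_frame(matrix: CqMatrix, candidates: Sequence[str] | None) -> pd.DataFrame:
    ids = list(candidates) if candidates is not None else matrix.target_ids
    unknown = [t for t in ids if t not in matrix.values.index]
    if unknown:
        raise ValueError(f"unknown candidate targets: {unknown}")
    frame = matrix.values.loc[ids]
    incomplete = frame.index[frame.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(
            "stability input requires call rate 100%; incomplete candidates: "
            f"{incomplete}"
        )
    return frame


def bestkeeper_stats(matrix: CqMatrix, target: str) -> tuple[float, float]:
    """BestKeeper descriptive stability: (sample SD, CV percent) of Cq."""
    frame = _candidate_frame(matrix, [target])
    x = frame.loc[target].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("BestKeeper needs at least 3 samples")
    sd = float(np.std(x, ddof=1))
    cv = float(100.0 * sd / np.mean(x))
    return sd, cv


def _pairwise_sd(frame: pd.DataFrame) -> pd.DataFrame:
    """SD over samples of Cq differences, for every candidate pair."""
    ids = list(frame.index)
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        v = float(np.std(frame.loc[a] - frame.loc[b], ddof=1))
        out.loc[a, b] = out.loc[b, a] = v
    return out


def genorm_m(matrix: CqMatrix, candidates: Sequence[str] | None = None) -> pd.Series:
    """geNorm M value per candidate: mean pairwise variation with all others."""
    frame = _candidate_frame(matrix, candidates)
    if frame.shape[0] < 3:
        raise ValueError("geNorm M needs at least 3 candidates")
    vjk = _pairwise_sd(frame)
    k = frame.shape[0]
    return vjk.sum(axis=1) / (k - 1)


def genorm_stepwise_ranking(
    matrix: CqMatrix, candidates: Sequence[str] | None = None
) -> pd.Series:
    """geNorm stepwise-exclusion ranks (1 = most stable).

    Iteratively recomputes M after dropping the least stable candidate;
    the final surviving pair cannot be resolved by M and shares the top
    average rank (1.5).
    """
    frame = _candidate_frame(matrix, candidates)
    if frame.shape[0] < 3:
        raise ValueError("geNorm stepwise ranking needs at least 3 candidates")
    remaining = list(frame.index)
    ranks: dict[str, float] = {}
    rank = len(remaining)
    while len(remaining) > 2:
        sub = matrix.subset_targets(remaining)
        m = genorm_m(sub, remaining)
        worst = m.sort_values(ascending=False, kind="mergesort").index[0]
        ranks[worst] = rank
        remaining.remove(worst)
        rank -= 1
    for t in remaining:
        ranks[t] = 1.5
    return pd.Series(ranks).reindex(frame.index)


def deltact_stability(
    matrix: CqMatrix, candidates: Sequence[str] | None = None
) -> pd.Series:
    """Comparative delta-Ct stability: mean pairwise SD per candidate."""
    frame = _candidate_frame(matrix, candidates)
    if frame.shape[0] < 3:
        raise ValueError("comparative delta-Ct needs at least 3 candidates")
    vjk = _pairwise_sd(frame)
    k = frame.shape[0]
    return vjk.sum(axis=1) / (k - 1)


def normfinder_stability(
    matrix: CqMatrix,
    candidates: Sequence[str] | None = None,
    groups: pd.Series | Mapping[str, str] | None = None,
) -> pd.Series:
    """NormFinder stability value per candidate (lower = more stable).

    Model-based variance decomposition on sample-centered log-scale data
    (Cq).  With group labels, a candidate's value combines the shrunken
    absolute intergroup deviation of its group means with the standard
    error of its intragroup variation, averaged over groups; without
    groups (or with a single group) it reduces to the intragroup-only
    variant, the square root of the bias-corrected candidate variance.
    """
    frame = _candidate_frame(matrix, candidates)
    k = frame.shape[0]
    if k < 2:
        raise ValueError("NormFinder needs at least 2 candidates")
    if groups is None:
        groups = matrix.groups
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(frame.columns)
    labels = groups.dropna().unique().tolist()

    # center each sample by its mean over candidates: removes the global
    # per-sample abundance factor (and any constant added to all cells)
    z = frame - frame.mean(axis=0)

    def _group_stats(cols: list[str]):
        zg = z[cols]
        n_g = len(cols)
        if n_g < 2:
            raise ValueError("each group needs at least 2 samples")
        a = zg.mean(axis=1)
        s2 = zg.var(axis=1, ddof=1)
        if k >= 3:
            total = float(s2.sum())
            sigma2 = (s2 - total / (k * (k - 1))) / (1.0 - 2.0 / k)
            sigma2 = sigma2.clip(lower=0.0)
        else:
            sigma2 = s2
        return a, sigma2, n_g

    if len(labels) <= 1:
        _, sigma2, _ = _group_stats(list(frame.columns))
        return np.sqrt(sigma2)

    per_group = {
        g: _group_stats([c for c in frame.columns if groups[c] == g]) for g in labels
    }
    a_mat = pd.DataFrame({g: per_group[g][0] for g in labels})
    d = a_mat.sub(a_mat.mean(axis=1), axis=0)  # intergroup deviation per gene

    stab = pd.Series(0.0, index=frame.index)
    for g in labels:
        _, sigma2, n_g = per_group[g]
        gamma_num = max(float(d[g].var(ddof=1)) - float((sigma2 / n_g).mean()), 0.0)
        denom = gamma_num + sigma2 / n_g
        shrink = (gamma_num / denom.where(denom > 0, np.inf)).fillna(0.0)
        d_tilde = d[g] * shrink
        stab += d_tilde.abs() + np.sqrt(sigma2 / n_g)
    return stab / len(labels)


def comprehensive_rank(ranks: pd.DataFrame) -> pd.DataFrame:
    """Consensus ranking: geometric mean of per-method ranks.

    ``ranks`` has one row per candidate and one column per method, each
    column a complete 1-based ranking of the same candidate set.  Returns
    a frame with ``comprehensive_score`` and ``final_rank`` (ascending by
    score, ties broken lexicographically by target id).
    """
    if ranks.isna().any().any():
        raise ValueError("per-method rankings must cover the same candidate set")
    score = np.exp(np.log(ranks.astype(float)).mean(axis=1))
    # order by the product of ranks (monotone in the geometric mean but
    # exact for rank values, so ties break deterministically by id)
    product = ranks.astype(float).prod(axis=1)
    order = sorted(score.index, key=lambda t: (product[t], t))
    final = pd.Series({t: i + 1 for i, t in enumerate(order)})
    return pd.DataFrame(
        {"comprehensive_score": score, "final_rank": final.reindex(score.index)}
    )


@dataclass
class NormalizationFactor:
    """Per-sample normalization values for one card."""

    values: pd.Series  # index sample_id -> Cq-scale value
    kind: str          # "reference_target" or "geometric_mean"


def geometric_mean_factor(
    matrix: CqMatrix, targets: Sequence[str] | None = None
) -> NormalizationFactor:
    """Per-sample geometric mean of Cq over the card's complete targets.

    By default uses every target with call rate 100% (excluding the
    negative-control assay).  The geometric mean is undefined when a
    contributing value is zero or negative, which is rejected.
    """
    if targets is None:
        complete = matrix.values.notna().all(axis=1)
        noneg = matrix.targets["control"] != "negative"
        targets = matrix.values.index[complete & noneg].tolist()
    if len(targets) == 0:
        raise ValueError("no targets with call rate 100% to build the factor from")
    frame = _candidate_frame(matrix, targets)
    if (frame.to_numpy() <= 0).any():
        raise ValueError("geometric mean undefined for zero or negative Cq values")
    values = pd.Series(stats.gmean(frame.to_numpy(), axis=0), index=frame.columns)
    return NormalizationFactor(values=values, kind="geometric_mean")


def factor_group_stability(
    factor: NormalizationFactor | pd.Series,
    groups: pd.Series | Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[float, str]:
    """Is the normalization factor stable between the two groups?

    Wilcoxon rank-sum test of the per-sample factor values; a factor
    differing between groups (p < alpha) would bias fold changes, so the
    verdict is "unstable".
    """
    from .expression import group_test  # local import: avoid module cycle

    values = factor.values if isinstance(factor, NormalizationFactor) else factor
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(values.index)
    labels = groups.dropna().unique().tolist()
    if len(labels) != 2:
        raise ValueError(f"factor stability needs exactly two groups, got {labels}")
    x = values[groups == labels[0]].to_numpy(dtype=float)
    y = values[groups == labels[1]].to_numpy(dtype=float)
    if min(len(x), len(y)) < 3:
        warnings.warn("group smaller than 3; exact rank-sum test used", stacklevel=2)
    p = group_test(x, y)
    return p, ("unstable" if p < alpha else "stable")


def reference_vs_factor_agreement(
    matrix: CqMatrix,
    reference_target: str,
    factor: NormalizationFactor | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation between a reference target's raw Cq and the
    per-sample normalization factor, across samples."""
    values = factor.values if isinstance(factor, NormalizationFactor) else factor
    ref = matrix.values.loc[reference_target]
    common = [s for s in matrix.sample_ids if s in values.index and np.isfinite(ref[s])]
    if len(common) < 3:
        raise ValueError("correlation needs at least 3 shared samples")
    r, p = stats.pearsonr(ref[common].to_numpy(), values[common].to_numpy())
    return float(r), float(p)


def stability_report(
    matrix: CqMatrix,
    candidates: Sequence[str] | None = None,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Full stability report: statistics, per-method ranks, consensus.

    One row per candidate with BestKeeper SD/CV, geNorm M, NormFinder
    value, delta-Ct mean pairwise SD, each method's 1-based rank (ties as
    average ranks), the comprehensive score and the final rank.
    """
    frame = _candidate_frame(matrix, candidates)
    ids = list(frame.index)
    if len(ids) < 3:
        raise ValueError("stability report needs at least 3 candidates")
    sub = matrix.subset_targets(ids)

    bk = pd.DataFrame(
        [bestkeeper_stats(sub, t) for t in ids],
        index=ids,
        columns=["bestkeeper_sd", "bestkeeper_cv"],
    )
    m = genorm_m(sub, ids)
    dct = deltact_stability(sub, ids)
    nf = normfinder_stability(sub, ids, groups if groups is not None else sub.groups)

    def _rank(s: pd.Series) -> pd.Series:
        return pd.Series(stats.rankdata(s.to_numpy()), index=s.index)

    ranks = pd.DataFrame(
        {
            "rank_bestkeeper": _rank(bk["bestkeeper_sd"]),
            "rank_genorm": _rank(m),
            "rank_normfinder": _rank(nf),
            "rank_deltact": _rank(dct),
        }
    )
    consensus = comprehensive_rank(ranks)
    report = pd.concat(
        [
            pd.Series(ids, index=ids, name="target_id"),
            bk,
            m.rename("genorm_m"),
            nf.rename("normfinder_value"),
            dct.rename("deltact_mean_sd"),
            ranks,
            consensus,
        ],
        axis=1,
    )
    return report.sort_values(["final_rank", "target_id"], kind="mergesort")
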