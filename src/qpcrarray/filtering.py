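"""Reliability filtering of QC-annotated Cq matrices.

The gate order is fixed: curve QC first, then the call-rate filter, then
the median-Cq expression filter.  A cell counts as a reliable call only
when a Cq is present *and* its QC scores pass the gate — call rate is
computed after QC, so a well with a crossing but a failing amp score does
not count.  The negative-control assay (non-human plant miRNA) is never
counted in call-rate accounting; endogenous control assays are retained
and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CqMatrix

__all__ = [
    "CallRateTable",
    "FilterResult",
    "call_rate",
    "call_rate_series",
    "call_rate_table",
    "filter_by_call_rate",
    "filter_by_median_cq",
    "reliable_mask",
]

#: Table rows: cumulative call-rate categories (percent), highest first.
CALL_RATE_CATEGORIES = (100, 98, 96, 94, 92, 90)


@dataclass
class FilterResult:
    """A filtered matrix plus the ledger of what was dropped and why."""

    matrix: CqMatrix
    removed: list[str]
    rule: str

    @property
    def retained(self) -> list[str]:
        return self.matrix.target_ids


@dataclass
class CallRateTable:
    """Cumulative call-rate accounting across reliability categories."""

    table: pd.DataFrame  # columns: category, count, percent
    total: int           # targets with at least one reliable call


def reliable_mask(
    matrix: CqMatrix,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> pd.DataFrame:
    """Boolean frame: cell is a reliable amplification call.

    Requires an observed Cq; when QC annotations are attached, the cell
    must additionally pass the score gate (amp_score > min and
    cq_conf > min).  An unannotated matrix treats every observed Cq as
    reliable.
    """
    mask = matrix.values.notna()
    if matrix.qc is not None:
        if "amp_score" in matrix.qc:
            mask &= matrix.qc["amp_score"] > amp_score_min
        if "cq_conf" in matrix.qc:
            mask &= matrix.qc["cq_conf"] > cq_conf_min
    return mask


def call_rate(
    matrix: CqMatrix,
    target: str,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> float:
    """Percentage of samples with reliable amplification for ``target``."""
    if matrix.n_samples == 0:
        raise ValueError("call rate undefined for zero samples")
    mask = reliable_mask(matrix, amp_score_min, cq_conf_min)
    return float(100.0 * mask.loc[target].sum() / matrix.n_samples)


def call_rate_series(
    matrix: CqMatrix,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> pd.Series:
    """Per-target call rate (percent) for all targets."""
    if matrix.n_samples == 0:
        raise ValueError("call rate undefined for zero samples")
    mask = reliable_mask(matrix, amp_score_min, cq_conf_min)
    return 100.0 * mask.sum(axis=1) / matrix.n_samples


def filter_by_call_rate(
    matrix: CqMatrix,
    min_percent: float = 90.0,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> FilterResult:
    """Retain targets detected reliably in at least ``min_percent`` of samples."""
    rates = call_rate_series(matrix, amp_score_min, cq_conf_min)
    keep = [t for t in matrix.target_ids if rates[t] >= min_percent]
    removed = [t for t in matrix.target_ids if t not in set(keep)]
    return FilterResult(
        matrix=matrix.subset_targets(keep),
        removed=removed,
        rule=f"call_rate>={min_percent:g}",
    )


def filter_by_median_cq(
    matrix: CqMatrix,
    mode: float | str = 32.0,
) -> FilterResult:
    """Drop barely-expressed targets by median observed Cq.

    ``mode`` is either a fixed cycle cutoff (drop targets whose median
    Cq exceeds it; the conventional value is 32) or ``"adaptive"``:
    drop targets whose median exceeds the median of all per-target
    medians, which avoids discarding low-but-consistent expressors.
    Apply after the call-rate filter; medians use observed Cq only.
    """
    medians = matrix.values.median(axis=1, skipna=True)
    if isinstance(mode, str):
        if mode != "adaptive":
            raise ValueError(f"mode must be a number or 'adaptive', got {mode!r}")
        cutoff = float(medians.median())
    else:
        cutoff = float(mode)
    keep = [t for t in matrix.target_ids if not (medians[t] > cutoff)]
    removed = [t for t in matrix.target_ids if medians[t] > cutoff]
    return FilterResult(
        matrix=matrix.subset_targets(keep),
        removed=removed,
        rule=f"median_cq<={cutoff:g}",
    )


def call_rate_table(
    matrix: CqMatrix,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> CallRateTable:
    """Cumulative call-rate accounting across the standard categories.

    Excludes the negative-control assay.  A target falls in category c
    when its call rate exceeds c - 2 (half-open two-percent bins, so with
    50 samples — call rates in steps of 2 — category c means
    "call rate >= c").  Counts are cumulative: each category includes all
    better ones.  Percentages are taken against the total number of
    targets with at least one reliable call.
    """
    keep = [
        t
        for t in matrix.target_ids
        if matrix.targets.loc[t, "control"] != "negative"
    ]
    sub = matrix.subset_targets(keep) if len(keep) < matrix.n_targets else matrix
    if sub.n_targets == 0:
        table = pd.DataFrame(
            {"category": CALL_RATE_CATEGORIES, "count": 0, "percent": 0.0}
        )
        return CallRateTable(table=table, total=0)
    rates = call_rate_series(sub, amp_score_min, cq_conf_min)
    total = int((rates > 0).sum())
    rows = []
    for cat in CALL_RATE_CATEGORIES:
        count = int((rates > cat - 2).sum())
        percent = 100.0 * count / total if total else 0.0
        rows.append({"category": cat, "count": count, "percent": percent})
    return CallRateTable(table=pd.DataFrame(rows), total=total)
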