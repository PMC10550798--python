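"""Core data containers for microfluidic RT-qPCR post-analysis.

The pipeline moves through three representations: per-well amplification
curves (raw fluorescence against cycle number), per-call quantification
records (Cq plus quality scores), and targets-by-samples Cq matrices that
downstream filtering, stability ranking and relative quantification operate
on.  All containers validate their invariants on construction so that
malformed inputs fail at the boundary, not deep inside an analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplificationCurve",
    "AmpStatus",
    "CqCall",
    "CqMatrix",
    "PipelineConfig",
    "QcScores",
    "ThresholdMethod",
    "NEGATIVE_CONTROL_ASSAY",
    "ENDOGENOUS_CONTROL_ASSAYS",
]

#: Plant miRNA spotted on each card as a no-amplification negative control.
NEGATIVE_CONTROL_ASSAY = "ath-miR-159"

#: Manufacturer endogenous control assays present on each card
#: (U6 is replicated four times per card).
ENDOGENOUS_CONTROL_ASSAYS = (
    "U6 snRNA-001973",
    "RNU44-001094",
    "RNU48-001006",
)


class ThresholdMethod(str, enum.Enum):
    """The three Cq-threshold algorithms compared by the pipeline."""

    FIXED = "fixed"
    AUTOMATIC = "automatic"
    RELATIVE = "relative"


class AmpStatus(str, enum.Enum):
    """Categorical amplification verdict for one well."""

    AMP = "AMP"
    NO_AMP = "NO_AMP"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's fluorescence trajectory over the PCR run.

    Parameters
    ----------
    sample_id, card, well, target_id
        Identity of the reaction: which sample, which 384-well card
        (``"A"`` or ``"B"``), which physical well, which assay.
    cycles
        Strictly increasing integer cycle axis ``1..n`` with no gaps.
    fluorescence
        Normalized reporter signal per cycle, same length as ``cycles``.
    """

    sample_id: str
    card: str
    well: str
    target_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cyc = np.asarray(self.cycles, dtype=int)
        flu = np.asarray(self.fluorescence, dtype=float)
        if cyc.ndim != 1 or flu.ndim != 1 or len(cyc) != len(flu):
            raise ValueError("cycles and fluorescence must be 1-D and equal length")
        if len(cyc) < 2:
            raise ValueError("a curve needs at least two cycles")
        if not np.all(np.diff(cyc) == 1):
            raise ValueError(
                f"cycles must be consecutive integers (sample={self.sample_id}, "
                f"well={self.well})"
            )
        if not np.all(np.isfinite(flu)):
            raise ValueError(
                f"non-finite fluorescence (sample={self.sample_id}, well={self.well})"
            )
        if self.card not in ("A", "B"):
            raise ValueError(f"card must be 'A' or 'B', got {self.card!r}")
        object.__setattr__(self, "cycles", cyc)
        object.__setattr__(self, "fluorescence", flu)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class CqCall:
    """One target/sample quantification under one threshold algorithm."""

    target_id: str
    sample_id: str
    method: ThresholdMethod
    cq: float | None
    threshold_used: float | None
    baseline_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.cq is not None and not (self.cq >= 1.0):
            raise ValueError(f"cq must be >= 1 when present, got {self.cq}")
        if self.method is ThresholdMethod.RELATIVE and self.threshold_used is not None:
            # the relative algorithm is threshold-free by construction
            raise ValueError("relative-threshold calls carry no threshold value")


@dataclass(frozen=True)
class QcScores:
    """Quality scores for one amplification curve.

    ``amp_score`` grades reaction quality on a 0-2 scale (>1 is reliable);
    ``cq_conf`` grades the reliability of the Cq value itself on 0-1
    (>0.8 is good, >0.95 very confident).
    """

    amp_score: float
    cq_conf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.amp_score <= 2.0):
            raise ValueError(f"amp_score out of [0, 2]: {self.amp_score}")
        if not (0.0 <= self.cq_conf <= 1.0):
            raise ValueError(f"cq_conf out of [0, 1]: {self.cq_conf}")

    def passes(self, amp_score_min: float = 1.0, cq_conf_min: float = 0.8) -> bool:
        return self.amp_score > amp_score_min and self.cq_conf > cq_conf_min


class CqMatrix:
    """Targets-by-samples Cq table for one card, with annotations.

    Parameters
    ----------
    values
        DataFrame indexed by target_id with one column per sample_id;
        missing (undetermined) Cq values are NaN, never a sentinel.
    groups
        Series mapping every sample_id to its group label.
    targets
        DataFrame indexed by target_id with columns ``card`` ("A"/"B")
        and ``control`` ("" for ordinary assays, "endogenous" for the
        manufacturer controls, "negative" for the plant-miRNA control).
    qc
        Optional per-cell QC annotation: mapping with keys ``amp_score``,
        ``cq_conf`` (DataFrames aligned with ``values``) and optionally
        ``amp_status``.
    n_cycles
        Number of PCR cycles run; Cq values must not exceed it.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        groups: pd.Series | Mapping[str, str],
        targets: pd.DataFrame | None = None,
        qc: Mapping[str, pd.DataFrame] | None = None,
        n_cycles: int = 40,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicate target ids in Cq matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in Cq matrix")
        groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        missing_meta = [s for s in values.columns if s not in groups.index]
        if missing_meta:
            raise ValueError(f"samples without group metadata: {missing_meta}")
        groups = groups.reindex(values.columns)

        finite = values.to_numpy()[np.isfinite(values.to_numpy())]
        if finite.size and (finite.min() <= 0 or finite.max() > n_cycles):
            raise ValueError(
                f"Cq values must lie in (0, {n_cycles}]; observed range "
                f"[{finite.min():.3g}, {finite.max():.3g}]"
            )

        if targets is None:
            targets = pd.DataFrame(
                {"card": "A", "control": ""}, index=values.index
            )
        else:
            targets = targets.reindex(values.index)
            if targets["card"].isna().any():
                bad = targets.index[targets["card"].isna()].tolist()
                raise ValueError(f"targets without card annotation: {bad}")
            targets = targets.assign(control=targets.get("control", "").fillna(""))

        if qc is not None:
            qc = dict(qc)
            for key in ("amp_score", "cq_conf"):
                if key in qc:
                    frame = qc[key]
                    if not frame.index.equals(values.index) or not frame.columns.equals(
                        values.columns
                    ):
                        raise ValueError(f"qc[{key!r}] not aligned with Cq values")

        self.values = values
        self.groups = groups.astype(str)
        self.targets = targets
        self.qc = qc
        self.n_cycles = int(n_cycles)

    # -- basic geometry -------------------------------------------------
    @property
    def target_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_targets(self, target_ids: Sequence[str]) -> "CqMatrix":
        ids = list(target_ids)
        qc = None
        if self.qc is not None:
            qc = {k: v.loc[ids] for k, v in self.qc.items()}
        return CqMatrix(
            self.values.loc[ids],
            self.groups,
            self.targets.loc[ids],
            qc=qc,
            n_cycles=self.n_cycles,
        )

    def copy(self) -> "CqMatrix":
        qc = None if self.qc is None else {k: v.copy() for k, v in self.qc.items()}
        return CqMatrix(
            self.values.copy(),
            self.groups.copy(),
            self.targets.copy(),
            qc=qc,
            n_cycles=self.n_cycles,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CqMatrix({self.n_targets} targets x {self.n_samples} samples, "
            f"groups={sorted(set(self.groups))}, qc={'yes' if self.qc else 'no'})"
        )


@dataclass
class PipelineConfig:
    """User-tunable settings for the end-to-end pipeline.

    Defaults follow common practice for TaqMan low-density arrays: a
    manual threshold of 0.2 normalized fluorescence units, the amp-score/
    Cq-confidence reliability gate (>1 and >0.8), a 90% call-rate filter
    and exclusion of targets whose median Cq exceeds cycle 32.
    """

    threshold_method: ThresholdMethod = ThresholdMethod.FIXED
    fixed_threshold: float = 0.2
    amp_score_min: float = 1.0
    cq_conf_min: float = 0.8
    call_rate_min: float = 90.0
    median_cq_max: float | str = 32.0  # a cycle number, or "adaptive"
    alpha: float = 0.05
    kw_flag_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.threshold_method = ThresholdMethod(self.threshold_method)
        if self.fixed_threshold <= 0:
            raise ValueError("fixed_threshold must be positive")
        if isinstance(self.median_cq_max, str) and self.median_cq_max != "adaptive":
            raise ValueError("median_cq_max must be a number or 'adaptive'")
        if not (0 <= self.call_rate_min <= 100):
            raise ValueError("call_rate_min is a percentage in [0, 100]")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["threshold_method"] = self.threshold_method.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
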