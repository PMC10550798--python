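"""Reading and writing the tabular formats the pipeline touches.

Canonical interchange formats (all plain text):

* long-format fluorescence CSV with header
  ``sample_id,card,well,target_id,cycle,rn`` — one row per cycle;
* wide Cq-matrix CSV (targets x samples), empty cell = undetermined;
* sample-metadata CSV with header ``sample_id,group``;
* optional target-annotation CSV with header ``target_id,card,control``;
* TSV reports with fixed column order and deterministic row ordering.

Undetermined Cq values stay missing end to end — no sentinel 40 or 0 is
ever introduced, because sentinels corrupt the medians and SDs used
throughout the downstream analysis.  Percentages are carried on the
0-100 scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import AmplificationCurve, CqMatrix, PipelineConfig

__all__ = [
    "read_fluorescence_long",
    "write_fluorescence_long",
    "read_cq_matrix",
    "write_cq_matrix",
    "write_report",
    "read_config",
    "write_config",
]

_FLUOR_COLUMNS = ["sample_id", "card", "well", "target_id", "cycle", "rn"]

#: significant digits for floats written to disk (read∘write identity
#: holds to this precision)
_FLOAT_FMT = "%.12g"


def read_fluorescence_long(path: str | Path) -> list[AmplificationCurve]:
    """Read amplification curves from the long-format fluorescence CSV.

    Groups rows into one curve per (sample_id, card, well) and validates
    cycle completeness: duplicated or missing cycles are integrity
    errors naming the offending sample and well.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FLUOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fluorescence file missing columns: {missing}")
    curves = []
    for (sample, card, well), grp in df.groupby(
        ["sample_id", "card", "well"], sort=True
    ):
        grp = grp.sort_values("cycle")
        cyc = grp["cycle"].to_numpy()
        if len(np.unique(cyc)) != len(cyc):
            raise ValueError(
                f"duplicated cycles for sample={sample!r} well={well!r}"
            )
        if not np.all(np.diff(cyc) == 1) or cyc[0] != 1:
            raise ValueError(
                f"cycles not consecutive from 1 for sample={sample!r} well={well!r}"
            )
        tids = grp["target_id"].unique()
        if len(tids) != 1:
            raise ValueError(
                f"multiple target_ids in one well: sample={sample!r} well={well!r}"
            )
        curves.append(
            AmplificationCurve(
                sample_id=str(sample),
                card=str(card),
                well=str(well),
                target_id=str(tids[0]),
                cycles=cyc,
                fluorescence=grp["rn"].to_numpy(dtype=float),
            )
        )
    return curves


def write_fluorescence_long(curves: Iterable[AmplificationCurve], path: str | Path) -> None:
    """Write curves as the long-format fluorescence CSV (row per cycle)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "card": c.card,
                    "well": c.well,
                    "target_id": c.target_id,
                    "cycle": c.cycles,
                    "rn": c.fluorescence,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cq_matrix(
    path: str | Path,
    metadata_path: str | Path,
    targets_path: str | Path | None = None,
    n_cycles: int = 40,
) -> CqMatrix:
    """Read a wide Cq matrix plus sample metadata (and optional target
    annotation) into a :class:`CqMatrix`.

    Empty cells are undetermined and stay missing.  Samples present in
    the matrix but absent from the metadata, and non-positive Cq values,
    are errors.
    """
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata file missing column {col!r}")
    groups = meta.set_index("sample_id")["group"].astype(str)
    groups.index = groups.index.astype(str)

    targets = None
    if targets_path is not None:
        tinfo = pd.read_csv(targets_path)
        if "target_id" not in tinfo.columns or "card" not in tinfo.columns:
            raise ValueError("target annotation needs target_id and card columns")
        targets = tinfo.set_index("target_id")
        targets.index = targets.index.astype(str)
        if "control" not in targets.columns:
            targets["control"] = ""
        targets["control"] = targets["control"].fillna("")

    finite = values.to_numpy()[np.isfinite(values.to_numpy())]
    if finite.size and finite.min() <= 0:
        raise ValueError("negative or zero Cq values in matrix")
    return CqMatrix(values, groups, targets, n_cycles=n_cycles)


def write_cq_matrix(matrix: CqMatrix, path: str | Path) -> None:
    """Write the Cq values as a wide CSV (empty cell = undetermined)."""
    matrix.values.to_csv(path, index=True, index_label="target_id", float_format=_FLOAT_FMT)


def write_report(results: pd.DataFrame, path: str | Path) -> None:
    """Serialize a result table as TSV with deterministic ordering.

    Rows are ordered by the rank column when one exists (``final_rank``
    or ``rank``), ties and rankless tables by identifier; two runs on
    identical input produce byte-identical files.
    """
    df = results.copy()
    id_col = df.columns[0] if len(df.columns) else None
    sort_cols = []
    for cand in ("final_rank", "rank"):
        if cand in df.columns:
            sort_cols.append(cand)
            break
    # sort by (rank, identifier); identifier alone for rankless tables
    # keyed by a string id; numeric layouts (e.g. the call-rate table)
    # keep their deliberate presentation order
    if id_col is not None and (sort_cols or df[id_col].dtype == object):
        sort_cols.append(id_col)
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_config(path: str | Path) -> PipelineConfig:
    """Load a flat key-value YAML config mirroring PipelineConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat mapping of settings")
    return PipelineConfig.from_dict(raw)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
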