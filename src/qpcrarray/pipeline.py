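"""End-to-end orchestration of the post-analytical pipeline.

Stage order is fixed and mirrors how a card run is analysed in practice:

    Cq calling -> curve QC gating -> call-rate accounting/filter ->
    median-Cq filter -> reference stability + normalization factor ->
    ddCq relative expression

Each stage records what it dropped and why in a run manifest, and the
whole run is a pure function of (config, inputs, seed): identical inputs
produce byte-identical outputs.  The threshold method is a pipeline-level
switch, so comparing methods is a fan-out of runs plus
:func:`qpcrarray.expression.compare_thresholds`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calling import call_cq_automatic, call_cq_fixed, call_cq_relative
from .core import AmplificationCurve, CqMatrix, PipelineConfig, ThresholdMethod
from .expression import differential_expression
from .filtering import call_rate_table, filter_by_call_rate, filter_by_median_cq
from .io import write_cq_matrix, write_report
from .qc import score_curve
from .stability import (
    factor_group_stability,
    geometric_mean_factor,
    reference_vs_factor_agreement,
    stability_report,
)

__all__ = ["PipelineResult", "call_curves", "run_all"]


def call_curves(
    curves: Sequence[AmplificationCurve],
    groups: pd.Series | Mapping[str, str],
    method: ThresholdMethod | str = ThresholdMethod.FIXED,
    fixed_threshold: float = 0.2,
    layout: pd.DataFrame | None = None,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
    n_cycles: int | None = None,
) -> tuple[CqMatrix, pd.DataFrame]:
    """Call Cq for every curve and assemble the annotated Cq matrix.

    Returns the QC-annotated matrix plus a per-call audit table
    (method, threshold_used, baseline window, scores, status).
    """
    method = ThresholdMethod(method)
    if n_cycles is None:
        n_cycles = max(c.n_cycles for c in curves)

    calls = []
    if method is ThresholdMethod.AUTOMATIC:
        by_target: dict[tuple[str, str], list[AmplificationCurve]] = {}
        for c in curves:
            by_target.setdefault((c.card, c.target_id), []).append(c)
        for key in sorted(by_target):
            calls.extend(call_cq_automatic(by_target[key]))
    else:
        caller = (
            (lambda c: call_cq_fixed(c, fixed_threshold))
            if method is ThresholdMethod.FIXED
            else call_cq_relative
        )
        calls = [caller(c) for c in curves]

    if method is ThresholdMethod.AUTOMATIC:
        # re-order calls to match the input curve order
        call_lookup = {(cl.target_id, cl.sample_id): cl for cl in calls}
        calls = [call_lookup[(c.target_id, c.sample_id)] for c in curves]

    rows = []
    values: dict[str, dict[str, float]] = {}
    qc_amp: dict[str, dict[str, float]] = {}
    qc_conf: dict[str, dict[str, float]] = {}
    qc_status: dict[str, dict[str, str]] = {}
    for curve, call in zip(curves, calls):
        key = (curve.target_id, curve.sample_id)
        if curve.sample_id in values.get(curve.target_id, {}):
            raise ValueError(f"duplicate well for target/sample {key}")
        scores, status = score_curve(curve, call.cq, amp_score_min, cq_conf_min)
        cq_val = call.cq if call.cq is not None and call.cq <= n_cycles else None
        values.setdefault(curve.target_id, {})[curve.sample_id] = (
            np.nan if cq_val is None else cq_val
        )
        qc_amp.setdefault(curve.target_id, {})[curve.sample_id] = scores.amp_score
        qc_conf.setdefault(curve.target_id, {})[curve.sample_id] = scores.cq_conf
        qc_status.setdefault(curve.target_id, {})[curve.sample_id] = status.value
        rows.append(
            {
                "target_id": curve.target_id,
                "sample_id": curve.sample_id,
                "card": curve.card,
                "well": curve.well,
                "method": method.value,
                "cq": np.nan if cq_val is None else cq_val,
                "threshold_used": call.threshold_used,
                "baseline_window": (
                    f"{call.baseline_window[0]}-{call.baseline_window[1]}"
                    if call.baseline_window
                    else ""
                ),
                "amp_score": scores.amp_score,
                "cq_conf": scores.cq_conf,
                "amp_status": status.value,
            }
        )

    target_ids = sorted(values)
    sample_ids = sorted({c.sample_id for c in curves})
    vdf = pd.DataFrame(values).T.reindex(index=target_ids, columns=sample_ids)
    if layout is not None:
        tinfo = layout.reindex(target_ids)
    else:
        cards = {c.target_id: c.card for c in curves}
        tinfo = pd.DataFrame(
            {"card": [cards[t] for t in target_ids], "control": ""}, index=target_ids
        )
    qc = {
        "amp_score": pd.DataFrame(qc_amp).T.reindex(index=target_ids, columns=sample_ids),
        "cq_conf": pd.DataFrame(qc_conf).T.reindex(index=target_ids, columns=sample_ids),
        "amp_status": pd.DataFrame(qc_status).T.reindex(index=target_ids, columns=sample_ids),
    }
    matrix = CqMatrix(vdf, groups, tinfo, qc=qc, n_cycles=n_cycles)
    audit = pd.DataFrame(rows).sort_values(["target_id", "sample_id"], kind="mergesort")
    return matrix, audit.reset_index(drop=True)


@dataclass
class PipelineResult:
    """All outputs of one pipeline run plus the run manifest."""

    cq_matrix: CqMatrix
    call_audit: pd.DataFrame | None
    call_rates: pd.DataFrame
    filtered: CqMatrix
    stability: pd.DataFrame | None
    factor: pd.Series | None
    factor_stability: tuple[float, str] | None
    expression: pd.DataFrame | None
    manifest: dict

    def save(self, outdir: str | Path) -> None:
        """Write every table (TSV/CSV) and the manifest (JSON) deterministically."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cq_matrix(self.cq_matrix, outdir / "cq_matrix.csv")
        if self.call_audit is not None:
            write_report(self.call_audit, outdir / "call_audit.tsv")
        write_report(self.call_rates, outdir / "call_rate_table.tsv")
        write_cq_matrix(self.filtered, outdir / "cq_matrix_filtered.csv")
        if self.stability is not None:
            write_report(self.stability, outdir / "stability_report.tsv")
        if self.factor is not None:
            factor_df = self.factor.rename("factor").rename_axis("sample_id").reset_index()
            write_report(factor_df, outdir / "normalization_factor.tsv")
        if self.expression is not None:
            write_report(self.expression, outdir / "expression.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(float_format="%.12g").encode()).hexdigest()


def run_all(
    config: PipelineConfig,
    curves: Sequence[AmplificationCurve] | None = None,
    matrix: CqMatrix | None = None,
    layout: pd.DataFrame | None = None,
    groups: pd.Series | Mapping[str, str] | None = None,
    case: str | None = None,
    control: str | None = None,
    normalization: str = "auto",
) -> PipelineResult:
    """Execute the full post-analytical pipeline.

    Entry points: raw ``curves`` (full path, needs ``groups``) or an
    already-called ``matrix`` (skips calling).  ``normalization`` is
    ``"auto"`` (top-ranked stable reference when a stability report is
    available, else the geometric-mean factor), ``"geomean"``, or
    ``"reference:<target_id>"``.
    """
    if (curves is None) == (matrix is None):
        raise ValueError("provide exactly one of curves or matrix")
    stages: list[dict] = []
    manifest: dict = {
        "tool": "qpcrarray",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": stages,
    }

    audit = None
    if curves is not None:
        if groups is None:
            raise ValueError("groups are required with curve input")
        matrix, audit = call_curves(
            curves,
            groups,
            method=config.threshold_method,
            fixed_threshold=config.fixed_threshold,
            layout=layout,
            amp_score_min=config.amp_score_min,
            cq_conf_min=config.cq_conf_min,
        )
        stages.append(
            {
                "stage": "call",
                "method": config.threshold_method.value,
                "n_curves": len(curves),
                "n_targets": matrix.n_targets,
                "n_samples": matrix.n_samples,
            }
        )
        manifest["input_digest"] = _digest_frame(audit)
    else:
        manifest["input_digest"] = _digest_frame(matrix.values)

    crt = call_rate_table(matrix, config.amp_score_min, config.cq_conf_min)
    stages.append(
        {
            "stage": "qc_call_rate_table",
            "total_targets_with_calls": crt.total,
            "categories": crt.table.to_dict(orient="records"),
        }
    )

    cr = filter_by_call_rate(
        matrix, config.call_rate_min, config.amp_score_min, config.cq_conf_min
    )
    stages.append(
        {
            "stage": "call_rate_filter",
            "rule": cr.rule,
            "n_in": matrix.n_targets,
            "n_out": cr.matrix.n_targets,
            "removed": cr.removed,
        }
    )
    med = filter_by_median_cq(cr.matrix, config.median_cq_max)
    stages.append(
        {
            "stage": "median_cq_filter",
            "rule": med.rule,
            "n_in": cr.matrix.n_targets,
            "n_out": med.matrix.n_targets,
            "removed": med.removed,
        }
    )
    filtered = med.matrix

    # stability: complete, QC-reliable, non-control candidates
    from .filtering import call_rate_series

    rates = call_rate_series(filtered, config.amp_score_min, config.cq_conf_min)
    candidates = [
        t
        for t in filtered.target_ids
        if rates[t] == 100.0
        and not filtered.values.loc[t].isna().any()
        and filtered.targets.loc[t, "control"] != "negative"
    ]
    stab = None
    if len(candidates) >= 3:
        stab = stability_report(filtered, candidates)
        stages.append(
            {
                "stage": "stability",
                "n_candidates": len(candidates),
                "best_reference": str(stab.iloc[0]["target_id"]),
            }
        )
    else:
        stages.append(
            {
                "stage": "stability",
                "n_candidates": len(candidates),
                "warning": "fewer than 3 complete candidates; stability skipped",
            }
        )

    factor = None
    factor_stab = None
    agreement = None
    if candidates:
        nf = geometric_mean_factor(filtered, candidates)
        factor = nf.values
        labels = sorted(set(filtered.groups))
        if len(labels) == 2:
            factor_stab = factor_group_stability(nf, filtered.groups, config.alpha)
        if stab is not None:
            agreement = reference_vs_factor_agreement(
                filtered, str(stab.iloc[0]["target_id"]), nf
            )
        stages.append(
            {
                "stage": "normalization_factor",
                "kind": nf.kind,
                "n_contributing_targets": len(candidates),
                "group_stability": (
                    None
                    if factor_stab is None
                    else {"p_value": factor_stab[0], "verdict": factor_stab[1]}
                ),
                "reference_vs_factor_r": None if agreement is None else agreement[0],
            }
        )

    # relative expression
    expression = None
    labels = sorted(set(filtered.groups))
    if case is None or control is None:
        if len(labels) == 2:
            lowered = [g.lower() for g in labels]
            if control is None:
                control = (
                    labels[lowered.index("control")] if "control" in lowered else labels[1]
                )
            if case is None:
                case = next(g for g in labels if g != control)
    if case is not None and control is not None:
        if normalization == "auto":
            if stab is not None:
                norm = str(stab.iloc[0]["target_id"])
            elif factor is not None:
                norm = factor
            else:
                norm = None
        elif normalization == "geomean":
            norm = factor
        elif normalization.startswith("reference:"):
            norm = normalization.split(":", 1)[1]
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        if norm is not None:
            expression = differential_expression(
                filtered,
                norm,
                case=case,
                control=control,
                method_label=config.threshold_method.value,
            )
            stages.append(
                {
                    "stage": "ddct",
                    "normalization": (
                        norm if isinstance(norm, str) else "geometric_mean"
                    ),
                    "case": case,
                    "control": control,
                    "n_targets": 0 if expression is None else len(expression),
                }
            )

    return PipelineResult(
        cq_matrix=matrix,
        call_audit=audit,
        call_rates=crt.table,
        filtered=filtered,
        stability=stab,
        factor=factor,
        factor_stability=factor_stab,
        expression=expression,
        manifest=manifest,
    )
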