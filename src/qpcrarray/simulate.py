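"""Synthetic amplification curves and Cq matrices with known ground truth.

Real microfluidic-card runs are rarely redistributable, so every stage of
the pipeline is exercised against simulated data whose generating
parameters are retained.  The curve model is a four-parameter logistic on
top of a linear baseline: the minimal shape exhibiting the four canonical
phases of an amplification plot (baseline, exponential, linear and
plateau).  Gaussian i.i.d. noise per cycle models detector noise.

Cq matrices are generated directly on the Cq scale as

    Cq(target, sample) = base(target) + effect(target, group(sample))
                         + shift(sample) + N(0, sd(target))

where ``shift`` is a per-sample global abundance factor (RNA input and
RT efficiency differences move every assay of a sample together) and
designated stable reference targets receive zero group effect and a small
technical SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ENDOGENOUS_CONTROL_ASSAYS,
    NEGATIVE_CONTROL_ASSAY,
    AmplificationCurve,
    CqMatrix,
)

__all__ = [
    "CurveParams",
    "SimulatedCqDataset",
    "SimulatedCurveDataset",
    "analytic_crossing",
    "card_layout",
    "simulate_curve",
    "simulate_cq_dataset",
    "simulate_curve_dataset",
]


@dataclass(frozen=True)
class CurveParams:
    """Generating parameters of one simulated amplification curve.

    ``amplitude`` is the plateau rise above baseline (0 encodes a
    non-amplifying well), ``midpoint_cycle`` the logistic inflection,
    ``steepness`` the logistic scale in cycles (smaller = steeper).
    """

    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0
    amplitude: float = 1.0
    midpoint_cycle: float = 25.0
    steepness: float = 1.5
    noise_sd: float = 0.0
    n_cycles: int = 40

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.amplitude > 0 and self.midpoint_cycle <= 0:
            raise ValueError(f"midpoint_cycle must be > 0, got {self.midpoint_cycle}")
        if self.steepness <= 0:
            raise ValueError(f"steepness must be > 0, got {self.steepness}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_cycles < 10:
            raise ValueError(f"n_cycles must be >= 10, got {self.n_cycles}")

    def model(self, cycles: np.ndarray) -> np.ndarray:
        """Noise-free model value at (possibly fractional) cycles."""
        c = np.asarray(cycles, dtype=float)
        logistic = self.amplitude / (
            1.0 + np.exp(-(c - self.midpoint_cycle) / self.steepness)
        )
        return self.baseline_intercept + self.baseline_slope * c + logistic


def simulate_curve(
    params: CurveParams,
    seed: int,
    *,
    sample_id: str = "S1",
    card: str = "A",
    well: str = "w001",
    target_id: str = "T1",
) -> AmplificationCurve:
    """Draw one amplification curve from the logistic-plus-baseline model.

    Reproducible: the same ``params`` and ``seed`` always return the same
    trace.
    """
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, params.n_cycles + 1)
    signal = params.model(cycles)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=len(cycles))
    return AmplificationCurve(
        sample_id=sample_id,
        card=card,
        well=well,
        target_id=target_id,
        cycles=cycles,
        fluorescence=signal,
    )


def analytic_crossing(params: CurveParams, threshold: float) -> float | None:
    """Exact cycle where the noise-free baseline-subtracted model crosses
    ``threshold``.

    Inverts ``amplitude / (1 + exp(-(c - m)/b)) = threshold`` in closed
    form; returns None when the plateau never reaches the threshold.
    This is the oracle against which Cq-calling accuracy is judged.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if threshold >= params.amplitude:
        return None
    m, b = params.midpoint_cycle, params.steepness
    return m + b * math.log(threshold / (params.amplitude - threshold))


# ---------------------------------------------------------------------------
# Card layout
# ---------------------------------------------------------------------------

def card_layout(card: str = "A", n_mirna: int = 20) -> pd.DataFrame:
    """Assay layout of one simulated 384-well card.

    Mirrors the control complement of a TaqMan MicroRNA array card: four
    U6 snRNA wells, one RNU44, one RNU48 and one non-human negative
    control (ath-miR-159), plus ``n_mirna`` miRNA assays.

    Returns a DataFrame indexed by target_id with columns ``card``,
    ``control`` ("", "endogenous" or "negative") and ``well``.
    """
    if card not in ("A", "B"):
        raise ValueError(f"card must be 'A' or 'B', got {card!r}")
    ids: list[str] = []
    control: list[str] = []
    u6, rnu44, rnu48 = ENDOGENOUS_CONTROL_ASSAYS
    for rep in range(1, 5):
        ids.append(f"{u6}_r{rep}")
        control.append("endogenous")
    for assay in (rnu44, rnu48):
        ids.append(assay)
        control.append("endogenous")
    ids.append(NEGATIVE_CONTROL_ASSAY)
    control.append("negative")
    for i in range(1, n_mirna + 1):
        ids.append(f"sim-miR-{card}-{i:03d}")
        control.append("")
    wells = [f"{card}{i + 1:03d}" for i in range(len(ids))]
    return pd.DataFrame({"card": card, "control": control, "well": wells}, index=pd.Index(ids, name="target_id"))


# ---------------------------------------------------------------------------
# Cq-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCqDataset:
    """A simulated Cq matrix together with its generating ground truth."""

    matrix: CqMatrix
    base_levels: pd.Series
    target_sd: pd.Series
    sample_shifts: pd.Series
    stable_targets: list[str]
    effect_sizes: dict
    missing_rate: float
    seed: int


def _group_labels(groups: Mapping[str, int]) -> tuple[list[str], pd.Series]:
    samples: list[str] = []
    labels: dict[str, str] = {}
    for g, n in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} has {n} samples; at least 2 required")
        for i in range(1, n + 1):
            sid = f"{g}{i:02d}"
            samples.append(sid)
            labels[sid] = g
    return samples, pd.Series(labels)


def simulate_cq_dataset(
    n_targets: int = 20,
    groups: Mapping[str, int] | None = None,
    *,
    stable_targets: Sequence[str] | int = 1,
    effect_sizes: Mapping[str, Mapping[str, float]] | None = None,
    target_sd: float | Mapping[str, float] = 0.5,
    stable_sd: float = 0.05,
    sample_shift_sd: float = 0.25,
    base_range: tuple[float, float] = (18.0, 30.0),
    group_effect_sd: float = 0.8,
    missing_rate: float = 0.0,
    card: str = "A",
    n_cycles: int = 40,
    seed: int = 0,
) -> SimulatedCqDataset:
    """Simulate a targets-by-samples Cq matrix with known stability structure.

    Parameters
    ----------
    n_targets
        Number of (non-control) miRNA targets on the card.
    groups
        Mapping group label -> sample count.  Defaults to the 31-patient /
        19-control two-group design typical of a case-control profiling run.
    stable_targets
        Either explicit target ids or an integer count: that many targets
        are designated stable references (zero group effect, technical SD
        ``stable_sd``); ground-truth labels are retained for rank-recovery
        checks.
    effect_sizes
        Per-target per-group Cq shifts.  Targets not listed (and not
        stable) receive a random group effect drawn with SD
        ``group_effect_sd`` for every non-reference group.
    target_sd
        Biological+technical SD for non-stable targets (scalar or per
        target).
    sample_shift_sd
        SD of the per-sample global abundance factor shared by all targets
        of a sample.
    missing_rate
        Probability that an individual Cq is undetermined (missing at
        random).  Simulated Cq beyond the last cycle is also undetermined.
    """
    if groups is None:
        groups = {"patient": 31, "control": 19}
    rng = np.random.default_rng(seed)
    samples, labels = _group_labels(groups)
    group_names = list(groups)

    targets = [f"sim-miR-{card}-{i:03d}" for i in range(1, n_targets + 1)]
    if isinstance(stable_targets, int):
        if stable_targets > n_targets:
            raise ValueError("more stable targets requested than targets")
        stable = targets[:stable_targets]
    else:
        stable = list(stable_targets)
        unknown = [t for t in stable if t not in targets]
        if unknown:
            raise ValueError(f"stable_targets not among targets: {unknown}")

    base = pd.Series(
        rng.uniform(base_range[0], base_range[1], size=n_targets), index=targets
    )
    if isinstance(target_sd, Mapping):
        sd = pd.Series({t: float(target_sd.get(t, 0.5)) for t in targets})
    else:
        sd = pd.Series(float(target_sd), index=targets)
    sd[stable] = stable_sd

    # group effects: reference group (first label) is the zero level
    effects = pd.DataFrame(0.0, index=targets, columns=group_names)
    for t in targets:
        if t in stable:
            continue
        for g in group_names[1:]:
            effects.loc[t, g] = rng.normal(0.0, group_effect_sd)
    if effect_sizes:
        for t, per_group in effect_sizes.items():
            if t not in effects.index:
                raise ValueError(f"effect for unknown target {t!r}")
            for g, e in per_group.items():
                effects.loc[t, g] = e
    effects.loc[stable, :] = 0.0

    shifts = pd.Series(rng.normal(0.0, sample_shift_sd, size=len(samples)), index=samples)

    noise = rng.normal(0.0, 1.0, size=(n_targets, len(samples)))
    values = (
        base.to_numpy()[:, None]
        + effects.to_numpy()[:, [group_names.index(labels[s]) for s in samples]]
        + shifts.to_numpy()[None, :]
        + noise * sd.to_numpy()[:, None]
    )
    values_df = pd.DataFrame(values, index=targets, columns=samples)

    if missing_rate > 0:
        mask = rng.random(values_df.shape) < missing_rate
        values_df = values_df.mask(mask)
    # late amplification past the final cycle is undetermined, not clipped
    values_df = values_df.mask(values_df > n_cycles)

    target_info = pd.DataFrame({"card": card, "control": ""}, index=values_df.index)
    matrix = CqMatrix(values_df, labels, target_info, n_cycles=n_cycles)
    return SimulatedCqDataset(
        matrix=matrix,
        base_levels=base,
        target_sd=sd,
        sample_shifts=shifts,
        stable_targets=stable,
        effect_sizes=effects.to_dict(orient="index"),
        missing_rate=missing_rate,
        seed=seed,
    )


def simulate_rank_recovery_dataset(
    seed: int,
    n_targets: int = 20,
    groups: Mapping[str, int] | None = None,
    stable_sd: float = 0.05,
    target_sd: float = 0.5,
    shift_magnitude: float = 0.8,
) -> SimulatedCqDataset:
    """The designated-stable-target scenario for rank-recovery checks.

    One stable reference (technical SD ``stable_sd``, zero group effect)
    among ``n_targets`` candidates with SD ``target_sd``, about half of
    which carry explicit group shifts of ``±shift_magnitude`` in a
    balanced design (equally many up- and down-shifted), the rest
    unshifted.  The balance matters: NormFinder identifies group-stable
    candidates relative to the panel average, so a panel whose shifts do
    not cancel on average makes the truly stable target unidentifiable
    for any centering-based method.
    """
    if groups is None:
        groups = {"patient": 25, "control": 25}
    group_names = list(groups)
    targets = [f"sim-miR-A-{i:03d}" for i in range(1, n_targets + 1)]
    shifted = targets[1::2]  # every other non-stable target
    effects = {
        t: {group_names[1]: shift_magnitude * (1 if j % 2 == 0 else -1)}
        for j, t in enumerate(shifted)
    }
    return simulate_cq_dataset(
        n_targets=n_targets,
        groups=groups,
        stable_targets=[targets[0]],
        effect_sizes=effects,
        target_sd=target_sd,
        stable_sd=stable_sd,
        group_effect_sd=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Curve-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCurveDataset:
    """Simulated raw amplification curves with per-curve ground truth.

    ``truth`` has one row per curve (sample_id, well, target_id, the
    generating CurveParams fields and ``true_cq`` — the analytic crossing
    of the noise-free baseline-subtracted model at ``truth_threshold``).
    """

    curves: list[AmplificationCurve]
    truth: pd.DataFrame
    layout: pd.DataFrame
    groups: pd.Series
    truth_threshold: float
    seed: int


def simulate_curve_dataset(
    n_mirna: int = 12,
    groups: Mapping[str, int] | None = None,
    *,
    card: str = "A",
    noise_sd: float = 0.01,
    amplitude_range: tuple[float, float] = (1.5, 4.0),
    midpoint_range: tuple[float, float] = (20.0, 33.0),
    steepness_range: tuple[float, float] = (1.0, 2.0),
    baseline_intercept_range: tuple[float, float] = (0.0, 0.3),
    baseline_slope_range: tuple[float, float] = (-0.002, 0.008),
    dropout_rate: float = 0.05,
    truth_threshold: float = 0.2,
    n_cycles: int = 40,
    seed: int = 0,
) -> SimulatedCurveDataset:
    """Simulate one card's worth of raw amplification curves.

    Every (target, sample) well receives a logistic curve whose midpoint
    is target-specific (shared across samples up to a per-sample shift),
    emulating per-assay abundance.  A ``dropout_rate`` fraction of miRNA
    wells and every negative-control well are non-amplifying
    (amplitude 0).  Parameter ranges follow typical normalized-reporter
    array runs: plateau rises of 1.5-4 units over baselines below 0.3,
    midpoints placing Cq roughly between cycles 15 and 35.
    """
    if groups is None:
        groups = {"patient": 3, "control": 3}
    rng = np.random.default_rng(seed)
    samples, labels = _group_labels(groups)
    layout = card_layout(card, n_mirna)

    # per-target midpoint/steepness shared across samples
    t_mid = {
        t: rng.uniform(*midpoint_range) for t in layout.index
    }
    t_steep = {t: rng.uniform(*steepness_range) for t in layout.index}
    s_shift = {s: rng.normal(0.0, 0.5) for s in samples}

    curves: list[AmplificationCurve] = []
    rows: list[dict] = []
    for t, meta in layout.iterrows():
        for s in samples:
            amp = rng.uniform(*amplitude_range)
            if meta["control"] == "negative" or rng.random() < dropout_rate:
                amp = 0.0
            params = CurveParams(
                baseline_intercept=rng.uniform(*baseline_intercept_range),
                baseline_slope=rng.uniform(*baseline_slope_range),
                amplitude=amp,
                midpoint_cycle=float(np.clip(t_mid[t] + s_shift[s], 12.0, n_cycles - 4)),
                steepness=t_steep[t],
                noise_sd=noise_sd,
                n_cycles=n_cycles,
            )
            curve_seed = int(rng.integers(0, 2**31 - 1))
            curve = simulate_curve(
                params,
                curve_seed,
                sample_id=s,
                card=card,
                well=str(meta["well"]),
                target_id=str(t),
            )
            curves.append(curve)
            tc = analytic_crossing(params, truth_threshold) if amp > 0 else None
            rows.append(
                {
                    "sample_id": s,
                    "well": meta["well"],
                    "target_id": t,
                    "true_cq": np.nan if tc is None else tc,
                    "curve_seed": curve_seed,
                    **{k: getattr(params, k) for k in (
                        "baseline_intercept",
                        "baseline_slope",
                        "amplitude",
                        "midpoint_cycle",
                        "steepness",
                        "noise_sd",
                        "n_cycles",
                    )},
                }
            )
    truth = pd.DataFrame(rows)
    return SimulatedCurveDataset(
        curves=curves,
        truth=truth,
        layout=layout,
        groups=labels,
        truth_threshold=truth_threshold,
        seed=seed,
    )
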