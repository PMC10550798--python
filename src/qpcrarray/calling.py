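"""Cq determination under three threshold algorithms.

Three ways of turning an amplification curve into a quantification cycle
are implemented, mirroring the options users face on real-time PCR
instruments:

* ``fixed`` — a single user-chosen fluorescence threshold (default 0.2)
  applied to every baseline-corrected curve;
* ``automatic`` — a per-target threshold derived from the exponential
  region of that target's amplified curves;
* ``relative`` — a per-curve, threshold-free call computed on a min-max
  rescaled efficiency model, invariant to positive affine transforms of
  the fluorescence axis by construction.

The vendor's automatic and relative-threshold algorithms are proprietary;
the versions here are open analogues honouring the same contracts
(per-target automatic threshold; per-curve, scale- and offset-invariant
relative call).  Bit-compatibility with instrument software is not
claimed.

Baseline handling: a straight line is fitted to the detected
pre-amplification window and then refined by decomposing the whole trace
into linear drift plus a logistic rise.  The refinement matters because a
short pre-amplification window extrapolates poorly for curves that start
amplifying early; the joint fit pins the drift using every cycle.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import AmplificationCurve, CqCall, ThresholdMethod

logger = logging.getLogger(__name__)

__all__ = [
    "call_cq_automatic",
    "call_cq_fixed",
    "call_cq_relative",
    "estimate_noise",
    "subtract_baseline",
]

DEFAULT_FIXED_THRESHOLD = 0.2

#: automatic threshold = this fraction of the signal at the detected
#: exponential-phase midpoint (the logistic inflection, where the curve
#: sits at half its plateau rise) — placing the threshold at ~20% of the
#: plateau, squarely in the exponential region.
AUTO_THRESHOLD_FRACTION = 0.4


# ---------------------------------------------------------------------------
# low-level signal utilities
# ---------------------------------------------------------------------------

def estimate_noise(signal: np.ndarray) -> float:
    """Robust per-cycle noise SD from second differences.

    For i.i.d. noise the second difference has variance 6*sigma^2; the
    median absolute deviation makes the estimate insensitive to the
    amplification rise, which affects only a handful of cycles.
    """
    s = np.asarray(signal, dtype=float)
    d2 = np.diff(s, 2)
    if d2.size == 0:
        return 0.0
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / math.sqrt(6.0))


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication."""
    if len(x) < 3:
        return np.asarray(x, dtype=float)
    padded = np.concatenate([x[:1], x, x[-1:]])
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")


def _detect_onset(signal: np.ndarray) -> int:
    """Exponential-onset cycle: argmax of the smoothed second difference
    of the signal (0-based index into the trace).  Linear drift has zero
    curvature, so the detector responds only to the amplification rise."""
    s = np.asarray(signal, dtype=float)
    d2 = np.diff(_smooth3(s), 2)
    if d2.size == 0:
        return len(s) - 1
    return int(np.argmax(d2)) + 1  # +1: second difference centred on i+1


def _linear_fit(cycles: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(cycles, signal, 1)
    return float(intercept), float(slope)


def _full_model(c, intercept, slope, amplitude, midpoint, steepness):
    return intercept + slope * c + amplitude / (1.0 + np.exp(-(c - midpoint) / steepness))


def _subtract_baseline_arrays(
    cycles: np.ndarray, signal: np.ndarray
) -> tuple[np.ndarray, tuple[int, int]]:
    """Baseline-correct a raw trace; returns (corrected, window).

    The pre-amplification window runs from cycle 3 up to 4 cycles before
    the detected exponential onset, trimmed further to where the trace is
    flat (second differences within noise).  A linear fit over the window
    initializes a joint drift+logistic decomposition; the refined drift
    line is subtracted.  Windows shorter than 3 cycles fall back to
    cycles 3-10 with a logged warning.
    """
    c = np.asarray(cycles, dtype=float)
    s = np.asarray(signal, dtype=float)
    n = len(s)
    if n < 10:
        raise ValueError("baseline subtraction requires at least 10 cycles")
    noise = estimate_noise(s)
    span = float(s.max() - s.min())

    onset = _detect_onset(s)
    lo = 2  # cycle 3 (0-based index)
    hi = min(onset - 4, n - 1)

    # trim the window end to the flat region: |second difference| must
    # stay within noise (or 1e-3 of the span)
    tol = max(10.0 * noise, 1e-3 * span, 1e-12)
    d2 = np.abs(np.diff(s, 2))  # d2[i] is centred on cycle index i+1
    while hi - lo >= 2 and np.any(d2[lo - 1 : hi] > tol):
        hi -= 1

    if hi - lo < 2:
        # routine for flat wells (no onset to anchor the window); only
        # noteworthy when the trace does look amplified
        log = logger.warning if span > 20.0 * noise and span > 0 else logger.debug
        log("pre-amplification window shorter than 3 cycles; falling back to cycles 3-10")
        lo, hi = 2, min(9, n - 1)

    intercept, slope = _linear_fit(c[lo : hi + 1], s[lo : hi + 1])
    corrected0 = s - (intercept + slope * c)

    # joint refinement: decompose into linear drift + logistic rise
    rise0 = float(np.max(_smooth3(corrected0)))
    if rise0 > max(10.0 * noise, 0.02 * span, 1e-12):
        m0 = float(c[np.argmax(np.diff(_smooth3(corrected0)))]) + 0.5
        p0 = [intercept, slope, max(rise0, 1e-9), m0, 1.5]
        bounds = (
            [-np.inf, -np.inf, 0.0, 1.0, 0.2],
            [np.inf, np.inf, 20.0 * max(rise0, 1e-9), float(c[-1]) + 10.0, 10.0],
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _full_model, c, s, p0=p0, bounds=bounds, maxfev=5000
                )
            intercept, slope = float(popt[0]), float(popt[1])
            corrected0 = s - (intercept + slope * c)
        except RuntimeError:
            pass  # keep the window line fit

    window = (int(cycles[lo]), int(cycles[hi]))
    return corrected0, window


def subtract_baseline(curve: AmplificationCurve) -> tuple[np.ndarray, tuple[int, int]]:
    """Baseline-corrected signal and the pre-amplification window used."""
    if curve.n_cycles < 10:
        raise ValueError("curve too short for baseline estimation (need >= 10 cycles)")
    return _subtract_baseline_arrays(curve.cycles, curve.fluorescence)


def _log_linear_crossing(
    cycles: np.ndarray, signal: np.ndarray, threshold: float
) -> float | None:
    """Fractional cycle of the first upward crossing of ``threshold``.

    Interpolation between the flanking cycles is log-linear (the
    exponential-phase signal is log-linear), falling back to linear when
    the lower flank is non-positive.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    s = np.asarray(signal, dtype=float)
    c = np.asarray(cycles, dtype=float)
    if s[0] >= threshold:
        return float(c[0])
    below = s[:-1] < threshold
    above = s[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    s0, s1 = s[i], s[i + 1]
    if s0 > 0:
        frac = (math.log(threshold) - math.log(s0)) / (math.log(s1) - math.log(s0))
    else:
        frac = (threshold - s0) / (s1 - s0)
    return float(c[i] + frac * (c[i + 1] - c[i]))


# ---------------------------------------------------------------------------
# fixed threshold
# ---------------------------------------------------------------------------

def call_cq_fixed(
    curve: AmplificationCurve, threshold: float = DEFAULT_FIXED_THRESHOLD
) -> CqCall:
    """Cq at a fixed fluorescence threshold on the baseline-corrected curve."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    corrected, window = subtract_baseline(curve)
    cq = _log_linear_crossing(curve.cycles, corrected, threshold)
    return CqCall(
        target_id=curve.target_id,
        sample_id=curve.sample_id,
        method=ThresholdMethod.FIXED,
        cq=cq,
        threshold_used=threshold,
        baseline_window=window,
    )


# ---------------------------------------------------------------------------
# automatic (per-target) threshold
# ---------------------------------------------------------------------------

def _exp_midpoint_signal(corrected: np.ndarray) -> float | None:
    """Corrected signal at the detected exponential-phase midpoint
    (cycle of steepest rise), or None when there is no detectable rise."""
    sm = _smooth3(corrected)
    d1 = np.diff(sm)
    if d1.size == 0:
        return None
    i = int(np.argmax(d1))
    level = float((sm[i] + sm[i + 1]) / 2.0)
    return level if level > 0 else None


def call_cq_automatic(curves: Sequence[AmplificationCurve]) -> list[CqCall]:
    """Per-target automatic threshold applied to all curves of one target.

    The threshold is the geometric mean, over the target's amplified
    curves, of the corrected signal at each curve's exponential-phase
    midpoint, scaled by ``AUTO_THRESHOLD_FRACTION`` so that it lands in
    the exponential region (about 20% of the plateau rise).  Curves that
    never reach the shared threshold are called None.
    """
    if len(curves) == 0:
        raise ValueError("call_cq_automatic needs at least one curve")
    corrected_all: list[np.ndarray] = []
    windows: list[tuple[int, int]] = []
    anchors: list[float] = []
    for curve in curves:
        corrected, window = subtract_baseline(curve)
        corrected_all.append(corrected)
        windows.append(window)
        noise = estimate_noise(curve.fluorescence)
        rise = float(np.max(_smooth3(corrected)))
        if rise > max(10.0 * noise, 1e-9):
            level = _exp_midpoint_signal(corrected)
            if level is not None:
                anchors.append(level)

    if not anchors:
        logger.warning(
            "no curve with a detectable exponential phase for target %s; all calls None",
            curves[0].target_id,
        )
        threshold = None
    else:
        threshold = AUTO_THRESHOLD_FRACTION * float(
            np.exp(np.mean(np.log(anchors)))
        )

    calls = []
    for curve, corrected, window in zip(curves, corrected_all, windows):
        cq = (
            _log_linear_crossing(curve.cycles, corrected, threshold)
            if threshold
            else None
        )
        calls.append(
            CqCall(
                target_id=curve.target_id,
                sample_id=curve.sample_id,
                method=ThresholdMethod.AUTOMATIC,
                cq=cq,
                threshold_used=threshold,
                baseline_window=window,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# relative threshold (threshold-free, affine-invariant)
# ---------------------------------------------------------------------------

def call_cq_relative(curve: AmplificationCurve) -> CqCall:
    """Threshold-free relative call on the rescaled efficiency model.

    The trace is min-max normalized (making the whole computation exactly
    invariant to positive affine transforms of fluorescence), baseline
    corrected, and rescaled to [0, 1].  A per-cycle efficiency model
    ``e(c) = s(c+1)/s(c) - 1`` is computed on the reliably positive part
    and smoothed; the reference efficiency level is 50% of its peak.  The
    fractional cycle where the efficiency falls to that level past the
    peak is mapped back to a fluorescence level, whose first crossing is
    returned as the relative Cq.

    Curves whose dynamic range is below five times the estimated noise SD
    are called None (no reliable relative scale).
    """
    raw = curve.fluorescence
    span = float(raw.max() - raw.min())
    if span <= 0:
        return _none_relative(curve, None)
    # affine-proof pre-normalization: downstream arithmetic sees the same
    # numbers (to rounding) for a*F + b as for F
    norm = (raw - raw.min()) / span
    noise = estimate_noise(norm)
    corrected, window = _subtract_baseline_arrays(curve.cycles, norm)

    dyn = float(corrected.max() - corrected.min())
    if dyn < 5.0 * noise or dyn <= 0:
        return _none_relative(curve, window)
    r = (corrected - corrected.min()) / dyn

    floor = max(5.0 * noise / dyn, 0.01)
    valid = (r[:-1] >= floor) & (r[1:] >= floor)
    if valid.sum() < 3:
        return _none_relative(curve, window)
    eff = np.full(len(r) - 1, np.nan)
    eff[valid] = r[1:][valid] / r[:-1][valid] - 1.0

    idx = np.nonzero(valid)[0]
    first, last = idx[0], idx[-1]
    seg = eff[first : last + 1]
    seg = np.where(np.isnan(seg), 0.0, seg)
    seg_s = _smooth3(seg)

    peak_i = int(np.argmax(seg_s))
    peak = float(seg_s[peak_i])
    if peak <= 0:
        return _none_relative(curve, window)
    ref_level = 0.5 * peak

    # fractional position past the peak where smoothed efficiency falls
    # to the reference level; efficiency at segment index j is centred on
    # cycle (first + j) + 0.5
    c_star = None
    for j in range(peak_i, len(seg_s) - 1):
        if seg_s[j] >= ref_level > seg_s[j + 1]:
            frac = (seg_s[j] - ref_level) / (seg_s[j] - seg_s[j + 1])
            c_star = curve.cycles[first + j] + 0.5 + frac
            break
    if c_star is None:
        return _none_relative(curve, window)

    # fluorescence level at c_star by log-linear interpolation of r
    level = _interp_log(curve.cycles, r, c_star)
    if level is None or level <= 0:
        return _none_relative(curve, window)
    cq = _log_linear_crossing(curve.cycles, r, level)
    if cq is not None:
        cq = max(cq, 1.0)
    return CqCall(
        target_id=curve.target_id,
        sample_id=curve.sample_id,
        method=ThresholdMethod.RELATIVE,
        cq=cq,
        threshold_used=None,
        baseline_window=window,
    )


def _none_relative(curve: AmplificationCurve, window) -> CqCall:
    return CqCall(
        target_id=curve.target_id,
        sample_id=curve.sample_id,
        method=ThresholdMethod.RELATIVE,
        cq=None,
        threshold_used=None,
        baseline_window=window,
    )


def _interp_log(cycles: np.ndarray, signal: np.ndarray, at: float) -> float | None:
    """Log-linear interpolation of a positive signal at fractional cycle."""
    c = np.asarray(cycles, dtype=float)
    if at <= c[0]:
        return float(signal[0]) if signal[0] > 0 else None
    if at >= c[-1]:
        return float(signal[-1]) if signal[-1] > 0 else None
    i = int(np.searchsorted(c, at) - 1)
    s0, s1 = signal[i], signal[i + 1]
    t = (at - c[i]) / (c[i + 1] - c[i])
    if s0 > 0 and s1 > 0:
        return float(math.exp((1 - t) * math.log(s0) + t * math.log(s1)))
    return float((1 - t) * s0 + t * s1)
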