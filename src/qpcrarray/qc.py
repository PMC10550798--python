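"""Amplification-curve quality scoring.

Replaces manual inspection of hundreds of curves per card with two
continuous scores and a categorical verdict:

* ``amp_score`` in [0, 2] grades reaction quality from the rise of the
  log-linear region relative to baseline noise and the consistency of the
  exponential phase (R-squared of a log-linear fit).  Values above 1 mark
  reliable amplification.
* ``cq_conf`` in [0, 1] grades the reliability of a computed Cq from the
  local steepness at the crossing relative to noise, again tempered by
  exponential-phase consistency.  Values above 0.8 are good, above 0.95
  very confident.
* ``amp_status`` maps the scores to AMP / NO_AMP / INCONCLUSIVE.

The vendor's score formulas are unpublished; these are open scores that
honour the documented ranges, cutoffs and semantics.  The mapping
constants below were frozen by calibrating on a balanced synthetic
benchmark of amplified (amplitude-to-noise >= 50) versus non-amplified
traces so that the pass rule (amp_score > 1 and cq_conf > 0.8) separates
the two classes; see scripts/calibrate_qc.py.  Scores are deliberately
per-curve: no information is shared across wells, so a well's verdict
cannot change when its neighbours do.
"""

from __future__ import annotations

import math

import numpy as np

from .calling import _smooth3, estimate_noise, subtract_baseline
from .core import AmplificationCurve, AmpStatus, CqCall, QcScores

__all__ = ["amp_score", "cq_confidence", "amp_status", "score_curve"]

# frozen calibration constants (see module docstring)
_AMP_SNR_CAP = 4.0      # log10(SNR) saturates here
_AMP_STEEPNESS = 18.0   # logistic steepness of the 0-2 mapping
_AMP_CENTER = 0.18      # quality level mapped to score 1.0
_CONF_R2_POWER = 0.5    # soften the R^2 penalty in cq_conf
_CONF_STEEP_KAPPA = 0.1  # half-saturation of the squared steepness ratio


def _exp_region_fit(cycles: np.ndarray, corrected: np.ndarray) -> tuple[float, float]:
    """(R-squared, log-slope) of a log-linear fit over the exponential region.

    The region is the set of cycles whose corrected signal lies between
    3% and 50% of the (smoothed) plateau rise; if fewer than three such
    points are positive the fit is undefined and scores (0, 0).
    """
    sm = _smooth3(corrected)
    rise = float(sm.max())
    if rise <= 0:
        return 0.0, 0.0
    mask = (corrected > 0.03 * rise) & (corrected < 0.5 * rise)
    # keep only the contiguous stretch ending at the rise (the last run),
    # so stray baseline noise points do not join the fit
    idx = np.nonzero(mask)[0]
    if idx.size >= 2:
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        if breaks.size:
            idx = idx[breaks[-1] + 1 :]
    if idx.size < 3:
        return 0.0, 0.0
    x = cycles[idx].astype(float)
    y = np.log(corrected[idx])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return 0.0, 0.0
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return 0.0, 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return max(0.0, min(1.0, r2)), float(slope)


def amp_score(curve: AmplificationCurve) -> float:
    """Reaction-quality score in [0, 2]; > 1 means reliable amplification.

    The score is a logistic mapping of the product of the (log) rise-to-
    noise ratio and the exponential-phase fit quality.  It is invariant
    to positive rescaling of the fluorescence axis: both the rise and the
    noise estimate scale together.
    """
    corrected, _ = subtract_baseline(curve)
    return _amp_score_from_corrected(curve, corrected)


def _amp_score_from_corrected(
    curve: AmplificationCurve, corrected: np.ndarray
) -> float:
    rise = float(np.max(_smooth3(corrected)))
    noise = estimate_noise(curve.fluorescence)
    span = float(curve.fluorescence.max() - curve.fluorescence.min())
    # no rise distinguishable from noise (or from the numerical residue
    # of correcting a featureless trace) means no amplification
    if rise <= max(3.0 * noise, 1e-9 * span) or span <= 0:
        return 0.0
    noise_eff = max(noise, 1e-9 * rise)  # relative floor keeps scale invariance
    snr = rise / noise_eff
    r2, _ = _exp_region_fit(curve.cycles, corrected)
    quality = min(math.log10(snr), _AMP_SNR_CAP) / _AMP_SNR_CAP * r2
    score = 2.0 / (1.0 + math.exp(-_AMP_STEEPNESS * (quality - _AMP_CENTER)))
    return max(0.0, min(2.0, score))


def cq_confidence(curve: AmplificationCurve, cq_call: CqCall | float | None) -> float:
    """Reliability of the Cq value in [0, 1]; 0 when no Cq was called.

    Combines the steepness of the crossing segment relative to noise with
    the exponential-phase fit quality through a fixed monotone map, so
    the score is non-increasing in the noise level for a fixed signal.
    """
    cq = cq_call.cq if isinstance(cq_call, CqCall) else cq_call
    if cq is None:
        return 0.0
    corrected, _ = subtract_baseline(curve)
    return _cq_confidence_from_corrected(curve, corrected, cq)


def _cq_confidence_from_corrected(
    curve: AmplificationCurve, corrected: np.ndarray, cq: float | None
) -> float:
    if cq is None:
        return 0.0
    noise = estimate_noise(curve.fluorescence)
    rise = float(np.max(_smooth3(corrected)))
    if rise <= 0:
        return 0.0
    noise_eff = max(noise, 1e-9 * rise)
    r2, log_slope = _exp_region_fit(curve.cycles, corrected)
    # local steepness at the crossing: signal level there times the
    # fitted per-cycle exponential growth, compared against the noise SD
    s_at = float(np.interp(cq, curve.cycles.astype(float), corrected))
    if log_slope > 0 and s_at > 0:
        deriv = s_at * (math.exp(log_slope) - 1.0)
    else:
        i = int(np.clip(math.floor(cq - curve.cycles[0]), 0, len(corrected) - 2))
        deriv = max(float(corrected[i + 1] - corrected[i]), 0.0)
    ratio = deriv / noise_eff
    steep_term = ratio * ratio / (ratio * ratio + _CONF_STEEP_KAPPA)
    conf = (r2**_CONF_R2_POWER) * steep_term
    return max(0.0, min(1.0, conf))


def amp_status(
    scores: QcScores,
    cq_present: bool,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> AmpStatus:
    """Categorical verdict: AMP when both scores pass, NO_AMP when the
    amp score is very low and no crossing was found, INCONCLUSIVE
    otherwise.  INCONCLUSIVE is treated as a failure by the downstream
    gate — it is never promoted automatically."""
    if scores.passes(amp_score_min, cq_conf_min):
        return AmpStatus.AMP
    if scores.amp_score < 0.5 and not cq_present:
        return AmpStatus.NO_AMP
    return AmpStatus.INCONCLUSIVE


def score_curve(
    curve: AmplificationCurve,
    cq: float | None,
    amp_score_min: float = 1.0,
    cq_conf_min: float = 0.8,
) -> tuple[QcScores, AmpStatus]:
    """Score one curve (single baseline subtraction) and classify it."""
    corrected, _ = subtract_baseline(curve)
    scores = QcScores(
        amp_score=_amp_score_from_corrected(curve, corrected),
        cq_conf=_cq_confidence_from_corrected(curve, corrected, cq),
    )
    return scores, amp_status(scores, cq is not None, amp_score_min, cq_conf_min)
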