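# Methods

This note documents the models and procedures implemented in
`qpcrarray`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Amplification-curve model

A well's fluorescence trajectory is modelled as a four-parameter
logistic on a linear baseline:

    F(c) = b0 + b1·c + A / (1 + exp(−(c − m)/s)) + ε_c,   ε_c ~ N(0, σ²) i.i.d.

with cycle number `c = 1..n` (default n = 40), baseline intercept `b0`
and drift `b1` (fluorescence units and units/cycle), plateau rise `A`
(`A = 0` encodes a non-amplifying well), midpoint `m` (cycles) and
logistic scale `s` (cycles; smaller is steeper).  This is the minimal
shape exhibiting the four canonical phases of an amplification plot —
baseline, exponential, linear, plateau.  Richards-type asymmetry is
deliberately omitted: no operation in the package depends on plateau
asymmetry, and the symmetric model admits a closed-form threshold
crossing,

    c*(T) = m + s·ln(T / (A − T)),   0 < T < A,

which serves as the exact oracle for Cq-recovery checks
(`analytic_crossing`).

## Baseline correction

The pre-amplification window starts at cycle 3 and ends 4 cycles before
the detected exponential onset (argmax of the smoothed second difference
of the trace; linear drift has zero curvature, so the detector responds
only to the rise), further trimmed to where second differences stay
within noise.  A straight line fitted over that window initializes a
joint least-squares decomposition of the whole trace into linear drift
plus logistic rise (`scipy.optimize.curve_fit`); the refined drift line
is subtracted.  The refinement is what makes the correction accurate for
curves that start amplifying early: extrapolating a short window line
several cycles forward amplifies the residual exponential contamination
of the window, while the joint fit pins the drift using every cycle.
Windows shorter than 3 cycles fall back to cycles 3–10 (logged; routine
for flat wells, noteworthy for amplified ones).  Degenerate traces
(dynamic range indistinguishable from noise) skip the joint fit.

## Cq calling

All crossings are interpolated log-linearly between the flanking cycles,
because exponential-phase signal is log-linear — the model error of the
interpolation is smallest exactly where Cq lives.

* **Fixed threshold** (default T = 0.2): first upward crossing of the
  baseline-corrected signal.  Deliberately not scale-invariant — that is
  the documented weakness of manual thresholds on heterogeneous cards.
* **Automatic threshold**: one threshold per target, the geometric mean
  over the target's amplified curves of the corrected signal at each
  curve's exponential-phase midpoint (cycle of steepest rise, where a
  logistic sits at A/2), scaled by 0.4 — i.e. ≈ 20% of the plateau
  rise, squarely inside the exponential region.  The 0.4 factor places
  the automatic threshold at the conventional manual level (0.2) for a
  unit-amplitude curve, which is the contract the package tests.
* **Relative threshold (C_RT analogue)**: per curve and threshold-free.
  The trace is min-max normalized *first* (making every downstream step
  structurally invariant to positive affine transforms of fluorescence),
  baseline-corrected, rescaled to [0, 1]; a per-cycle efficiency model
  e(c) = s(c+1)/s(c) − 1 is computed on the reliably positive part
  (floor: max(5·noise/range, 0.01)) and smoothed with a 3-cycle moving
  average; the reference efficiency level is 50% of the smoothed peak;
  the fractional cycle where the efficiency decays to that level past
  the peak is mapped to a fluorescence level whose first crossing is the
  C_RT.  For a noise-free logistic the 50% rule lands exactly one cycle
  before the midpoint, i.e. at ≈ 1/(1+e^(1/s)) of the plateau — a
  well-sampled region.  The vendor's reference-efficiency constant is
  unpublished; the 50%-of-peak rule is this package's openly specified
  stand-in, not a claim about the proprietary algorithm.  Curves with
  dynamic range below 5 estimated noise SDs are called None.

Noise is estimated robustly as 1.4826·MAD(second differences)/√6.

## Curve QC

Two scores gate every call (vendor formulas are unpublished; these are
open scores honouring the documented ranges and cutoffs):

* `amp_score ∈ [0, 2]`: a logistic mapping of
  min(log10(rise/noise), 4)/4 · R², where `rise` is the smoothed plateau
  rise of the corrected trace and R² is a log-linear fit over the
  exponential region (3–50% of the rise).  Scale-invariant by
  construction (rise and noise scale together).  >1 means reliable.
* `cq_conf ∈ [0, 1]`: (R²)^0.5 · ρ²/(ρ² + 0.1), where
  ρ = (signal at the crossing × fitted per-cycle growth)/noise — the
  inverse of the noise-induced Cq jitter in cycles.  0 when no Cq was
  called; non-increasing in noise for fixed signal.  >0.8 good, >0.95
  very confident.

The mapping constants were frozen by calibrating on a balanced benchmark
of 500 amplified (amplitude/noise ≥ 50) and 500 non-amplified synthetic
curves (`scripts/calibrate_qc.py` regenerates it); the pass rule
(amp_score > 1 ∧ cq_conf > 0.8) must separate the classes at ≥ 99%
accuracy, which the acceptance suite re-verifies.  `amp_status` maps the
scores to AMP / NO_AMP / INCONCLUSIVE; INCONCLUSIVE is always treated as
a failure downstream, never auto-promoted.  The scores are deliberately
per-curve — no information is shared across wells — so a well's verdict
cannot change when its neighbours do (a documented deviation from
instrument software, whose status call is sensitive to the number of
curves analysed together).

## Filtering

Gate order is fixed: QC → call rate → median Cq.  A cell counts toward
call rate only when a Cq is present *and* its scores pass the gate.
Defaults: call rate ≥ 90%; drop targets with median observed Cq > 32
(`"adaptive"` replaces 32 by the median of per-target medians, which
avoids discarding low-but-consistent expressors).  Medians use observed
values only; undetermined Cq is never imputed (a sentinel 40 or 0 would
corrupt every median and SD downstream, which is why the I/O layer
refuses to create one).  The call-rate table uses cumulative two-percent
bins (category c counts targets with call rate > c−2; with 50 samples
call rates step by 2, so this reads as "≥ c"), percentages against the
number of targets with at least one reliable call.  The non-human
negative-control assay is excluded from call-rate accounting;
endogenous-control assays are retained and flagged.

## Reference stability

All stability inputs must be complete (call rate 100%); passing an
incomplete candidate is an error, not a silent drop.  Cq is already a
log2-scale quantity, so pairwise "expression ratios" are plain Cq
differences.

* **BestKeeper**: sample SD (n−1) and CV of the candidate's Cq.  This is
  the descriptive SD/CV variant, not the original Excel tool's
  geometric-mean/MAD construction.
* **geNorm**: V_jk = SD over samples of (Cq_j − Cq_k); M_j = mean over
  partners.  The stepwise-exclusion ranking (iteratively removing the
  highest-M candidate; the final pair ties at rank 1.5) is available,
  but the raw-M ranking is the default input to the consensus.
* **Comparative ΔCt**: the same pairwise SDs averaged per candidate,
  without exclusion.
* **NormFinder**: model-based decomposition on sample-centered data.
  Per group: candidate means a_ig and variances s²_ig of the centered
  values; intragroup variances are bias-corrected for the centering
  (σ̂²_ig = (s²_ig − Σs²/(k(k−1)))/(1 − 2/k), floored at 0, k ≥ 3
  candidates); intergroup deviations d_ig = a_ig − mean_g(a_ig) are
  shrunken by an empirical-Bayes factor γ/(γ + σ̂²_ig/n_g) with γ the
  method-of-moments variance of the d's; stability =
  mean_g(|d̃_ig| + √(σ̂²_ig/n_g)).  With a single group it reduces to
  √σ̂²_i.  All four statistics are invariant to adding a constant to
  every cell.
* **Comprehensive rank**: the geometric mean of the four 1-based ranks
  (ties get average ranks); the final order is computed on the exact
  rank product (monotone in the geometric mean but float-exact), ties
  broken lexicographically by target id.

Cards are ranked separately — each card is an independent experiment
(own reverse transcription, pre-amplification and run), so no cross-card
information is shared.

The global alternative is the per-sample geometric mean of Cq over the
card's complete targets, undefined (rejected) for zero or negative
contributions.  Its group-stability check (Wilcoxon rank-sum between
the two groups) answers whether global normalization would bias fold
changes; `reference_vs_factor_agreement` reports the Pearson r between
the chosen reference's raw Cq and the factor.

## Relative expression

ΔCq(sample) = Cq_target − normalization value; samples with missing
target Cq are excluded listwise.  ΔΔCq uses group *means* of ΔCq (the
conventional estimator — medians are reported alongside but do not drive
the fold change); FC = 2^−ΔΔCq, reported as −1/FC when below 1, so
|FC| ≥ 1 and the sign encodes direction.  Group tests are two-sided
Wilcoxon rank-sum: exact by full enumeration of the rank-sum null (with
midranks under ties) whenever C(n, n1) ≤ 20 000, normal approximation
with tie correction otherwise.  Cross-threshold comparison:
Kruskal–Wallis per target across the methods' Cq values (p = 1 for
all-identical values, where the statistic is undefined), Dunn's post hoc
z tests with tie-corrected pooled-rank SD, Holm-adjusted (the adjustment
is configurable; Holm is the default because it controls FWER without
independence assumptions), flagging targets at KW p < 0.01.

## Synthetic data: what it emulates, and what it does not

Curve-level simulation emulates: sigmoidal amplification with baseline
drift and Gaussian detector noise; per-target abundance (shared
midpoints, per-sample shifts); non-amplifying wells; and the control
complement of a real card (four U6 wells, RNU44, RNU48, one non-human
negative control).  Default parameter ranges — plateau rise 1.5–4
normalized units, baselines below 0.3 with drift −0.002–0.008 per cycle,
midpoints 20–33 (Cq roughly 15–35), logistic scale 1–2 cycles, noise SD
0.01 — describe a clean normalized-reporter run; they are engineering
choices, not estimates from any particular instrument or tissue.

Cq-level simulation generates
Cq(t, s) = base_t + effect_{t,g(s)} + shift_s + N(0, σ_t) with a default
two-group design of 31 + 19 samples, base levels uniform on 18–30,
per-sample global shifts (SD 0.25) and target SD 0.5 (0.05 for
designated stable references, which also have zero group effect).
Simulated Cq past the final cycle becomes undetermined rather than being
clipped.

Not modelled: probe chemistry, passive-reference dye behaviour,
inhibitor kinetics, plateau asymmetry, heteroscedastic or correlated
noise, and structured (non-random) missingness.  Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
performance on any particular instrument's exports.

The designated-stable-target scenario used for rank-recovery checks
(`simulate_rank_recovery_dataset`) gives half the non-stable targets
explicit group shifts of ±0.8 Cq in a *balanced* design (equally many up
and down, mean zero).  The balance is load-bearing: NormFinder measures
group stability relative to the panel average (its sample-centering step
removes the global abundance factor), so a panel whose shifts do not
cancel on average transfers the net shift onto every unshifted
candidate, including the truly stable one.  With i.i.d. random shifts on
all 19 competitors the stable target is no longer identifiable as
group-stable by any centering-based method — a property of the problem,
not of this implementation — and NormFinder's first-place rate drops
accordingly.  Users ranking references on panels with strongly
one-directional regulation should prefer the variance-based statistics
(BestKeeper, geNorm, ΔCt) or pre-select a plausibly balanced candidate
panel.

## Numerical choices

* Crossing interpolation is log-linear; linear fallback when the lower
  flank is non-positive.  First-crossing-from-below semantics make Cq
  monotone in the threshold.
* Noise estimation by MAD of second differences (robust to the rise).
* The joint baseline fit is skipped when the corrected rise is below
  max(10·noise, 2% of span, 1e-12) — degenerate traces keep the window
  line fit; `curve_fit` failures fall back likewise.
* Exact Wilcoxon enumeration uses midranks and the two-sided rule
  p = min(1, 2·min(P(W ≤ w), P(W ≥ w))) with a 1e-9 tie tolerance on
  rank sums.
* Reports are written with 12-significant-digit floats; read∘write is
  the identity at that precision, and identical runs produce
  byte-identical files (manifests contain no timestamps).
* Seeds are explicit arguments everywhere; no global random state.

## Known limitations

* The automatic and relative algorithms are open analogues with the same
  contracts as the instrument options they mirror, not re-implementations
  of the proprietary algorithms; numeric agreement with vendor software
  is out of scope.
* QC scores honour the documented ranges and cutoffs but the score
  *values* are this package's own calibration; only the pass/fail gate
  semantics are transferable.
* Efficiency-corrected quantification (Pfaffl-type) is not implemented;
  fold changes assume doubling per cycle.
* The call-rate denominator is all samples loaded on the card; per-run
  success accounting would need sample-level run metadata the interchange
  format does not carry.
* Stability ranking requires complete (100% call-rate) candidates by
  design; imputation is deliberately unsupported.
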