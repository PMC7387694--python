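# Methods

`hefpipe` implements the analysis chain used to study heartbeat-evoked
magnetic fields (HEFs): cortical responses averaged time-locked to the ECG
R peak, and their spectral and connectivity signatures. This note records
the models, the parameters that matter, and the numerical choices, so that
results computed with the package can be interpreted and reproduced.

## The analysis model

**Trigger stream.** Everything downstream is locked to ECG R peaks. The
detector is a Pan–Tompkins-style envelope detector: 4th-order zero-phase
Butterworth band-pass (5–35 Hz default), squared derivative smoothed with a
120 ms moving average, adaptive threshold at 25% of the 99th envelope
percentile, a 300 ms refractory period, and refinement of each candidate to
the extremum of the absolute median-centered raw trace within ±50 ms.
Squaring makes detection polarity-invariant. A flat trace yields an empty
peak series with a warning rather than an error.

**HRV.** Time-domain measures on the normal-to-normal (NN) intervals:
SDNN is the sample standard deviation (n−1 denominator, the convention of
the HRV standards; the source material does not state one) and RMSSD the
root mean square of successive differences, both in ms. NN intervals are
formed within condition blocks only, never across block boundaries. No
ectopic-beat correction is applied.

**Epoching.** Windows of −200 to +600 ms around each R peak, closed at
both ends — 801 samples at 1 kHz. The stated window span is 800 ms; we
keep both endpoint samples and document the fencepost choice. Peaks whose
window would clip a recording edge, or which fall outside blocks of the
requested condition, are excluded and counted, so that
`retained + rejected + edge_excluded + outside_blocks` always equals the
peak count. Artifact rejection is peak-to-peak per channel type —
reject iff max−min **strictly exceeds** 400 fT on any magnetometer or
4000 fT/cm on any gradiometer ("exceeded" read literally; a value exactly
at threshold is retained). Source-type (ROI) channels never trigger
rejection. Thresholds apply in the channel's stated physical units; unit
conversion is the caller's responsibility. Overlapping epochs (RR < 800 ms)
are permitted. Evoked averaging baseline-corrects against the −200..0 ms
window by default; the flag exists because baseline handling is a
convention, not a necessity.

**Time-frequency and ITC.** Complex Morlet wavelets (Gaussian-windowed
complex exponentials), default 8–24 Hz in 1 Hz steps at a fixed
`n_cycles = 7`. The inter-trial coherence is

    ITC(f, t) = | (1/n) Σ_k F_k(f, t) / |F_k(f, t)| |,

the modulus of the across-trial mean unit phasor, bounded in [0, 1]. (A
published form of this expression omits the outer modulus while stating the
[0, 1] range; the modulus is the standard definition and the one
implemented.) For uniform phases E[ITC] ≈ √π/(2√n) — the Rayleigh mean
resultant — which the tests verify by resampling. Maps are z-normalized
against the mean and sample SD of the ITC over a reference region; the
default reference is the insular seed channel in the control condition over
200–600 ms × 8–24 Hz. A 200–400 ms post-R "baseline" window appears as an
alternative convention in the HEF literature; both windows are accepted via
configuration, and the 200–600 ms statistics window is the default because
the headline between-condition comparisons use it.

**PLI connectivity.** Instantaneous phase per band (alpha 8–13 Hz, beta
14–24 Hz) from a zero-phase band-pass FIR plus the analytic signal; the
phase lag index between a seed ROI and each target is

    PLI = | mean sign( wrap(φ_a − φ_b) ) |,

pooled over all valid (trial, time) samples in the 200–500 ms window, with
sign(0) contributing 0 — which is what makes the PLI blind to zero-lag
(volume-conduction-like) coupling. Pooling over samples rather than
averaging per-trial PLIs maximizes the effective sample count; the
per-trial variant is available behind a flag for sensitivity analyses.
Group tables report Fisher-z (atanh) transformed PLIs, with the argument
clipped to 1 − 1e−12 so perfect coupling stays finite. Alpha-band results
are computed and reported even where the scientific focus is beta, to keep
the full band specification exercised.

**Statistics.** Between-condition comparisons use equal-variance
independent two-sample t-tests (df = n₁ + n₂ − 2) by default — with equal
group sizes this coincides with the Welch form, which is what lets the
summary-statistics entry point reproduce published worked examples
regardless of which form was used. The design is within-subject, so a
paired variant is provided; "independent" remains the default to match the
reporting convention of the results this package reproduces. The ITC map
comparison is pointwise across subjects at p < 0.01 with **no**
multiple-comparison correction (a Benjamini–Hochberg option exists but is
off by default); contiguous significant regions ("distributions of
significance") are enumerated with 4-connectivity on the (frequency, time)
grid — free-form contours have no defined adjacency, so the conservative
grid notion is used. PLI group comparisons use two-sided Mann–Whitney U
tests (exact enumeration when n₁+n₂ ≤ 20 and tie-free, otherwise the
normal approximation with tie and continuity corrections; the reported U
is the smaller of the pair), masked at p < 0.05 and converted to signed
z-values via z = sign·Φ⁻¹(1 − p/2).

## The synthetic-data generator

The generator produces the study conditions end to end so every stage can
be tested against known ground truth.

* **RR intervals**: a stationary AR(1) Gaussian process with marginal mean
  `mean_rr`, marginal SD `rr_sd`, and lag-1 correlation `rr_ar1`. This is
  the minimal model in which SDNN and RMSSD are separately controllable,
  with the closed form RMSSD = SDNN·√(2(1−ρ)). Defaults `mean_rr = 900 ms`,
  `rr_sd = 43 ms`, `rr_ar1 = 0.67` reproduce the study regime of ~66.7 bpm,
  SDNN ≈ 43 ms, RMSSD ≈ 35 ms. Intervals are floored at 1 ms.
* **ECG**: a sharp biphasic QRS-like template (dominant Gaussian R wave,
  σ = 5 ms, ~20 ms wide, with a smaller trailing S dip) at each cumulative
  RR position; the ground-truth peak index is the template maximum. Any
  sharp template would do for detector testing; the R/S asymmetry ensures
  the raw-trace extremum is unambiguous.
* **Block design**: alternating condition blocks (default two 3-min blocks
  per condition, 12 min total). At ~66.7 bpm a 6-min condition yields
  roughly 400 beats, the order of magnitude of per-condition trial counts
  in the target studies.
* **ROI signals** per beat: (i) a Gaussian evoked bump (default amplitude
  1, latency 265 ms, σ 40 ms — within the 250–300 ms peak window reported
  for heartbeat-evoked responses); (ii) oscillatory bursts with Gaussian
  envelopes whose phase *at the lock latency* is von Mises distributed per
  beat (κ = 0 uniform, κ = None deterministic) and advances linearly at
  2πf elsewhere — this makes the ITC analytically predictable at exactly
  the (frequency, lock-latency) point; (iii) lagged copies of a source
  burst for coupled ROIs (constant phase lag, the PLI ground truth); and
  (iv) white plus 1/f-power Gaussian noise.
* **Default planted effects** (the bundled study conditions): in
  "disgust", κ = 2 locked bursts at 19 and 23 Hz (lock 420 ms, envelope
  σ 100 ms) on the insular seed plus a random-phase 20 Hz burst shared
  with L_VMPFC at a constant 0.5 rad lag; in "control", a κ = 2 locked
  burst at 14 Hz (lock 300 ms). The lock latencies sit inside the
  edge-valid region of the corresponding wavelet rows. Noise defaults
  (white SD 2.0, pink SD 1.0 per sample at 1 kHz against unit-amplitude
  bursts) put the single-trial narrowband SNR near one — locking is
  invisible in single trials but recoverable across ~400, the regime the
  method is designed for; with much weaker noise, spectral leakage from
  any locked burst dominates whole-map coherence and no condition
  contrast survives normalization.
* **Per-subject variation**: cohort runs jitter mean RR as N(900, 120) ms
  clipped to [650, 1250] — heart rates of ~48–92 bpm and 6-min beat counts
  of ~290–550, matching the between-subject spread of the target regime.

What the generator does **not** emulate: sensor-space field topographies
and forward/inverse modeling (the pipeline starts at labeled ROI or sensor
time series), cardiac dipole artifact leakage into MEG channels,
respiratory or gastric rhythms, non-stationary noise, and T-wave-locked
components. Passing tests therefore demonstrate correctness of the
computations and recoverability under the stated signal model, not
robustness to every artifact of real recordings.

## Numerical choices

* **Wavelet truncation**: the Gaussian envelope is truncated at ±2.5
  temporal SDs. A 7-cycle wavelet at 8 Hz spans ~0.70 s under this
  truncation and fits the 801-sample epoch; longer truncations would not.
  The wavelet is forced exactly zero-mean after truncation (DC rejection),
  and normalized so a unit-amplitude sinusoid at the wavelet frequency
  yields |F| = 0.5. Samples closer than the half-support to an epoch edge
  are flagged invalid and masked from all statistics — never zeroed.
  A wavelet whose truncated support exceeds the epoch raises an error
  naming the frequency.
* **Zero-modulus coefficients**: where |F_k| = 0 the phase is undefined;
  such trials contribute 0 to the ITC sum and the point is flagged.
* **Decimation**: cohort-scale runs decimate epochs by 4 (to 250 Hz)
  before the TF and PLI stages, after a zero-phase FIR low-pass at 0.8×
  the new Nyquist (100 Hz). All analysis frequencies are ≤ 24 Hz, so this
  is lossless for the quantities computed; it exists purely to bound
  compute. `tf_decim = 1` disables it.
* **Streaming ITC**: `itc_from_epochs` computes the same quantity as
  `itc(morlet_transform(...))` frequency-by-frequency in single precision;
  the two paths agree to ~1e−6 and the equivalence is a test.
* **FIR phase extraction**: odd-length symmetric band-pass taps
  (~1.5·fs/f_lo), applied as a centered convolution — symmetric FIR plus
  centering is exactly zero-phase, no forward-backward pass needed. The
  filter half-length at each epoch edge is flagged invalid; samples with
  numerically zero analytic amplitude (phase undefined) are invalidated
  too. A Morlet-phase variant (`method="wavelet"`) exists as a
  cross-check; the two agree on narrowband signals to within 0.05 PLI.
* **Ties and boundaries**: sign(0) → 0 in the PLI; PLI = 1 maps to
  atanh(1 − 1e−12) ≈ 14.2; rejection thresholds are strict inequalities;
  reference windows are closed intervals; sample indices are 0-based and
  epoch time axes are in ms with t = 0 at the R peak.

## Problem sizes

Recovery checks simulate 39-subject cohorts with two 3-min blocks per
condition per subject (≈290–550 beats/condition). The test suite evaluates
20 independent cohort seeds and requires the planted 19/23 Hz increases,
the 14 Hz decrease, and the top-ranked coupled ROI in ≥ 90% of them;
`scripts/acceptance.py` reports the same rates over 10 seeds derived from
its `--seed`. ITC null calibration uses 2000 resamples at n ∈ {50, 200};
type-I calibration uses 10,000 null t-tests at n = 39 per group; cardiac
recovery uses 5,000-beat RR series and 400-beat noisy ECGs. These sizes
are the package's chosen operating points: large enough for the stated
tolerances, small enough to run routinely.

## Known limitations

* The pipeline starts at ROI time series; nothing here validates source
  reconstruction choices upstream of it.
* The printed Mann–Whitney U of some published worked examples cannot be
  reconciled with standard conventions at the stated group sizes; the
  package reports the smaller-U convention and makes no attempt to match
  such values numerically.
* The generator's AR(1) RR model has no respiratory sinus arrhythmia
  structure; SDNN/RMSSD are matched, spectral HRV is not (and no
  frequency-domain HRV is computed).
* Where a published analysis is ambiguous (baseline subtraction of evoked
  responses, normalization window, paired vs independent tests for
  within-subject HRV), the package exposes both behaviors and documents
  its default; it does not assert which the original analysis used.
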