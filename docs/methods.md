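# Methods

## Detection model

The detector assumes that a mechanically active (perfusing) heart transmits
a small transient to the chest surface at each beat, delayed by the
electromechanical coupling time, and that this transient is the only
component of the pause-time acceleration signal that is phase-locked to the
ECG.  Under that assumption the normalized cross-correlation between the
filtered ECG and acceleration concentrates into a peak at the (negative of
the) mechanical delay, and its height CCp is a scale-free measure of
coupling strength: bounded in [−1, 1] by Cauchy–Schwarz, invariant to
channel gains, and insensitive to uncorrelated noise in either channel.

Two normalizations are implemented.  The default, `energy_sqrt`, divides
the lag sums by `sqrt(Σx²·Σy²)`; it is the form whose values are bounded in
[−1, 1] and match the magnitudes the method is known to produce (group
means near 0.44 for PR).  The alternative `energy_product` divides by the
plain product `Σx²·Σy²`; it is dimensionally inconsistent for signals of
arbitrary scale and is retained only so the two conventions can be compared
directly.  CCp is the *signed* maximum by default; an absolute-value mode
exists but is off, since an anti-phase coupling has no physiological
interpretation here.

Lag convention: with `r(l) = Σ x(n)·y(n−l)`, an acceleration delayed by δ
relative to the ECG peaks at `l = −δ·fs`.  `DetectionResult.peak_lag`
stores the lag in this convention; `delay_estimate_s = −peak_lag/fs` is the
mechanical-delay estimate.

## Filters

ECG: 0.2–45 Hz; ACC: 0.5–7.5 Hz; both 4th-order Butterworth.  The ACC
order is not externally fixed anywhere, so it defaults to the ECG's order 4
and is configurable.  Filters are applied zero-phase (forward–backward,
`sosfiltfilt` with its reflective edge padding) because any phase
distortion would corrupt the ECG–ACC lag structure that CCp depends on; a
causal single-pass mode (`zero_phase: false`) exists for real-time
emulation.  Zero-phase application squares the magnitude response, which
the closed-form Butterworth oracle in `preprocess.butterworth_gain`
accounts for.

## Segmentation

Compression episodes and pauses are separated by thresholding the moving
RMS envelope (0.5 s centred window) of the mean-removed acceleration at
10 m/s² — between the ~46 m/s² compression regime and the ~1.8 m/s² pulse
regime, giving a wide indifference margin in both directions.  Pauses must
last at least 3 s; analysis segments are 3 s (900 samples) anchored at the
pause start, with an optional guard offset (default 0) for residual motion
after the last compression.  All intervals are half-open sample-index
ranges.

## Annotation

Organized rhythm is defined as ≥ 1 QRS complex in the window; PR requires
additionally SAP > 60 mmHg and pulse pressure > 10 mmHg (strict
inequalities); organized non-PR segments are PEA; disorganized segments get
`not_applicable`.  SAP/DAP are the window extrema of the raw ABP slice,
pulse pressure their difference, MAP the window mean (a DAP + PP/3
estimator is provided as an alternative).  Heart rate is 60 over the
*median* RR interval — robust to one missed or spurious detection in a 3-s
window — and undefined with fewer than two complexes.

The QRS detector is a Pan–Tompkins-style rectified-derivative detector:
squared derivative, 150 ms moving-window integration, peaks above 30 % of
the window maximum with a 0.2 s refractory period, fiducial on the local
ECG extremum.  Two guards adapt it to arrest rhythms: window edges are
cosine-tapered over 100 ms (complexes cut by the window boundary otherwise
dominate the adaptive threshold), and a spectral gate requires ≥ 2 % of the
ECG energy above 10 Hz, which separates discrete complexes from
fibrillation-like 3–8 Hz activity.  This automatic path is a stand-in for
expert annotation; manual QRS marks can be injected per segment
(`annotate --manual-qrs`), and exclusion flags (rhythm transition,
defibrillation shock) are caller-supplied metadata, not detected.

## Threshold training and evaluation

The decision threshold maximizes accuracy over the candidate set of
midpoints between consecutive distinct sorted feature values (plus one
candidate beyond each extreme) — a resolution-free grid.  Accuracy ties
break toward higher sensitivity, then the smaller threshold.  Decisions use
strict `value > threshold`.

AUC is computed by midrank (Mann–Whitney) pair counting with ties counted
½, which equals the trapezoidal ROC area exactly.  Student's t is
pooled-variance (Welch via flag), the χ² test is the 2×2 Pearson statistic
without continuity correction (correction via flag), and Pearson's r gets
its p-value through the exact t transform.  Correlated AUCs on the same
segments are compared with a Z-test using DeLong's covariance estimate
(Hanley–McNeil with an average-correlation correction as an alternative
mode).  These formulas are implemented directly; scipy supplies only the
reference distributions, so the independent scipy/sklearn implementations
can serve as oracles in the test suite.

## Synthetic generator

Each organized segment draws a beat template: a sharp biphasic QRS spike
(width 70–130 ms) plus a co-centred Gaussian hump (amplitude 0.2–0.6 mV,
width 120–220 ms) standing in for the fused low-frequency repolarisation of
wide peri-arrest complexes.  Beats repeat at a clipped-normal heart rate
(PR 159 ± 51, PEA 86 ± 45 bpm, clipped to 30–300) with ±5 % RR jitter, plus
0.3 Hz baseline wander (0.05 mV) and white noise (0.05 mV).  Disorganized
traces are 3–8 Hz band-limited Gaussian processes.

The ABP is a per-beat pressure pulse (fast upstroke, exponential diastolic
decay, non-stacking) delayed 100–200 ms after each QRS and scaled so the
window mean hits a target MAP drawn from 115.3 ± 36.3 mmHg (PR, clipped to
≥ 75 so the SAP criterion is met) or 15.2 ± 9.5 mmHg (PEA, pulse pressure
2–8 mmHg).

The pause-time ACC is Gaussian noise (default SD 0.4 m/s²) plus, for PR
only, a per-beat transient with the beat's own time course at a fixed
per-segment electromechanical delay (50–200 ms) and amplitude drawn from
1.83 ± 0.96 m/s² with 25 % beat-to-beat jitter.  Giving the transient the
beat's time course makes its 0.5–7.5 Hz component a damped low-frequency
oscillation whose band-limited shape matches the ECG's in-band content —
the coupling structure the detector assumes.  Compression episodes add a
~1.8 Hz oscillation (plus second harmonic) at 46.35 ± 15.95 m/s².

### What the generator reproduces, and what it cannot

With the defaults, the synthetic PR group mean CCp is ≈ 0.44–0.47 with SD
≈ 0.13 — matching the reported PR statistics — and the CCp AUC at study
scale (63/153) is ≈ 0.95.  The synthetic **PEA** mean, however, is ≈ 0.2
rather than the ≈ 0.07 seen in animal data.  This is a structural property,
not a tuning failure: the maximum over ±899 lags of the normalized
cross-correlation between *any* band-limited Gaussian-like processes of
this length floors near 0.15–0.25.  Animal PEA recordings reach 0.07 only
because real narrow-QRS ECG is spectrally sparse in a way that
simultaneously caps the achievable PR CCp near `sqrt(in-band energy
fraction)` ≈ 0.4–0.5; the generator's morphology distribution balances the
two regimes.  Consequences: the trained synthetic threshold sits near 0.4
instead of 0.22, and synthetic sensitivity at that threshold is lower than
the animal study's.  Passing tests therefore demonstrate correctness of
the *machinery* (filters, correlation, peak logic, labelling, statistics)
and qualitative PR/PEA separability, not a quantitative reproduction of
animal-data operating points.

### Delay-recovery protocol

A 3-s window that cuts complexes at *both* edges can alias the correlation
peak to a neighbouring beat (±1 RR): with K beats, the true alignment and
the off-by-one alignment then match almost the same number of complete
beat pairs.  This is an identifiability limit of cross-correlation on
short windows, not an implementation artifact, so the delay-recovery
characterization uses windows containing complete cardiac cycles
(`full_beats=True`, 60–160 bpm, where δ < RR) and defines SNR in-band
(0.5–7.5 Hz RMS of pulse component over noise), since the analysis discards
out-of-band power.  Under that protocol, recovery of δ ∈ [50, 200] ms
within 20 ms succeeds in ≈ 100 % of trials at in-band SNR 2.

## Numerical choices

* Cross-correlation is FFT-accelerated (`scipy.signal.correlate`) and
  verified against the O(N²) defining sums to 1e-10.
* Peak ties break toward the smallest |lag|, then the negative lag.
* All-zero inputs raise rather than return NaN; zero-variance t-tests
  return t = 0, p = 1 when means agree and flag an infinite statistic
  otherwise.
* Waveform CSVs round-trip at ≥ 15 significant digits (≤ 1e-9 error); the
  sample rate is re-inferred from the median time step and must be uniform
  within a relative 1e-6.
* Random draws come from `numpy.random.default_rng(seed)` only; identical
  (params, seed) reproduce identical arrays bit for bit.

## Problem sizes used by the test suite

Unit tests run on single segments and small batches; the deeper checks use
200 delay-recovery trials, 1000 noise-free segments for label determinism,
1000 permutation replicates for the DeLong type-I calibration, and 20
study-scale replicates (63/153 segments) for end-to-end discrimination.
The whole suite completes in well under a minute on one CPU.

## Known limitations

* Pulse detection during ongoing compressions is out of scope (the method
  operates only in compression pauses).
* The QRS detector is a stand-in for expert annotation; its
  fibrillation gate is tuned to the generator's disorganized process and is
  not a validated arrhythmia classifier.
* Exclusion conditions (rhythm transitions, shocks) are metadata, not
  detected from the waveforms.
* The generator's noise is Gaussian and stationary; real sensor artifacts
  (motion, contact changes) are not modelled, with the consequences for the
  PEA correlation floor described above.
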