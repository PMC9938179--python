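# Methods

This note documents the analysis model implemented by `somnoscope`, the
synthetic-data generator used to validate it, the numerical choices made,
and their limitations. Every empirical number quoted here was computed
with the code in this repository (see `tests/` and
`scripts/acceptance.py`).

## 1. Signal model and event detection

### Band-pass + z-score front end

All detectors operate on a band-passed, z-scored copy of one LFP channel.
The band-pass is a linear-phase Hamming-window FIR (`scipy.signal.firwin`)
whose transition width is the smaller of half the low cut-off, half the
distance to Nyquist, and 10 Hz; the filter is applied forward and backward
so the net phase response is zero and event times are not displaced. For
speed the double application is implemented as two FFT convolutions with
reflection padding, which is mathematically identical to
forward–backward filtering of a symmetric FIR but O(N log N) — at 2 kHz a
0.5 Hz edge needs a ~26,000-tap kernel, where direct convolution is
prohibitive. After filtering, the trace is z-scored with the mean and SD
of the whole trace, making every threshold scale-free.

### Slow-waves (0.5–4 Hz)

Candidate waves are positive-then-negative half-wave pairs delimited by
zero crossings of the filtered trace. A wave is kept when

- either extremum exceeds 3.5 SD in magnitude,
- the trough is more negative than −50 µV (an absolute physiological
  floor, checked in µV, not SD),
- the total duration lies in 0.25–2 s.

The event's time is its trough (the DOWN state); its amplitude is the
peak-to-trough difference in µV; its intrinsic frequency is the reciprocal
of its duration.

### Spindles (8–16 Hz) and ripples (125–220 Hz)

The amplitude envelope is a cubic spline through the local maxima of the
rectified z-scored trace (an envelope that touches the oscillation peaks
exactly, unlike a low-passed rectified signal). Candidate intervals are
runs where the envelope exceeds an edge threshold (1.5 SD spindles, 2 SD
ripples) that contain at least one sample above the 3.5 SD detection
threshold. Intervals closer than the merge gap (0.5 s spindles, 50 ms
ripples) are merged *before* duration bounds (0.35–4 s, 50–500 ms) are
applied — the order matters and is covered by a brute-force oracle test.
Intrinsic frequency is the within-event cycle rate (number of envelope-band
peaks − 1, divided by duration).

### State attribution

Each event is tagged with the vigilance state of the 4 s epoch containing
its reference time; events outside the scored span are `unscored`, never
silently dropped.

## 2. Spectra and phase-amplitude coupling

Power spectra are mean periodograms over non-overlapping 4 s Hamming
segments (0.25 Hz resolution). Segments intersecting artifact epochs — or,
under a state restriction, any other state — are excluded; a window with
no eligible segment is an error or NaN, never zero. SWA time courses
average the 0.5–4 Hz segment power in 5 min bins.

Coupling uses the Kullback–Leibler modulation index
MI = (log N − H(P)) / log N with N = 18 phase bins, where P is the
normalized mean amplitude (Hilbert envelope of the amplitude band) per
phase bin (Hilbert phase of the phase band). MI is 0 for a uniform
phase-amplitude profile and 1 when all amplitude concentrates in one bin;
both closed forms, and agreement with an independent binning oracle to
1e-10, are tested.

Comodulograms scan phase bands 0.5 Hz wide in 0.5 Hz steps over 0.5–4 Hz
against amplitude bands 2 Hz wide in 1 Hz steps over 8–20 Hz, restricted
to NREM segments of at least 8 s. One cycle of the phase band's low edge
is trimmed from every segment end so that concatenation boundaries do not
contaminate the analytic signal. The input is internally decimated
(anti-aliased) to ≥ 10× the top amplitude frequency, which cuts the cost
~10× at 2 kHz without touching the 8–20 Hz content. The headline coupling
statistic is the maximal MI in the 0.5–1.5 Hz × 10–16 Hz window, and
`pac_change` is its post-minus-baseline difference.

## 3. Single-unit analytics

Putative pyramidal cells have spike width > 200 µs and mean rate < 5 Hz.
Rate analyses include units firing above 0.15 Hz over the recording;
correlation analyses require > 200 spikes in each analysis window. The
bursting index is the fraction of inter-spike intervals < 20 ms.

PETHs pool spike counts across anchors (slow-wave troughs: ±500 ms, 5 ms
bins; ripple times: ±250 ms, 2 ms bins), convert to Hz, and z-score each
unit across its own bins; the summary statistic is the mean z in ±250 ms
(slow-waves) or ±40 ms (ripples). Cross-correlograms count spike-time
differences in 2 ms bins over ±500 ms, z-scored across lag bins, excluding
zero-lag self-pairs for autocorrelograms; the peak statistic is the mean z
in ±100 ms (within-region) or 0–200 ms (cortex→hippocampus).

## 4. Vigilance scoring

Per 4 s epoch the scorer computes the theta (5–10 Hz) to SWA (0.5–4 Hz)
power ratio of the LFP and the EMG RMS. SWA-dominated epochs
(log ratio ≤ 0) are NREM; theta-dominated epochs are REM when the EMG is
below half the median EMG of the NREM epochs and wake otherwise. Epochs
containing clipped samples (|x| ≥ 5 mV) or flagged movement are artifacts.

The SWA/theta boundary is a fixed power-dominance criterion rather than a
data-driven split: quantile splits hard-code state proportions, and a
minimum-within-class-variance (Otsu) split — tried first — fails when one
state vastly outnumbers the rest, cutting the majority cluster in half
(57% agreement on a 121-NREM/29-other synthetic session). Being a power
ratio from a single channel, the fixed criterion is scale-free and needs
no per-recording fitting; it agrees with generator ground truth on
96–100% of epochs across seeds (acceptance bound: ≥ 85%).

## 5. Synthetic session generator

The generator is first-class, tested code: it is the ground truth against
which every detector and estimator in the package is validated.

- **Background**: Gaussian 1/f^α noise (α = 1 by default) shaped in the
  frequency domain and normalized to a target RMS (30 µV).
- **State schedule**: alternating exponential bouts (NREM 90 s, wake 45 s,
  REM 30 s means; REM follows NREM with probability 0.35; sessions start
  awake), rounded to 4 s epochs.
- **Slow-waves**: biphasic zero-integral wavelets — positive lobe over 40%
  of the duration carrying 60% of the peak-to-peak amplitude, trough over
  60% at 40%. Equal lobe areas keep the template inside the 0.5–4 Hz
  band: a non-zero-mean draft lost up to ~47% of trough depth to the
  0.5 Hz high-pass edge for long waves, corrupting recall measurements.
- **Spindles/ripples**: Tukey(0.5)-windowed sinusoid bursts at 12 /
  160 Hz. Event counts are Poisson per NREM minute; a configurable leak
  fraction (5 / 15 / 30%) places events outside NREM, mimicking the
  NREM-preference observed in vivo. Placement is rejection-sampled to
  avoid overlap; impossible densities raise an error rather than
  degrading silently.
- **Coupling**: a configurable fraction of spindle onsets is locked to a
  host slow-wave phase (0.4π on the linear 0–2π wave phase) with von
  Mises concentration κ = 10c/(1−c), exact at c = 1.
- **Theta and EMG**: 7 Hz theta gated into wake/REM epochs; EMG is white
  noise with state-dependent RMS (wake 40 > NREM 15 > REM 5 µV), giving
  the scorer realistic inputs.
- **Spikes**: inhomogeneous Poisson trains by thinning a ceiling-rate
  process; rate is multiplied by (1 − suppression) within ±125 ms of
  slow-wave troughs and by (1 + gain) inside ripples (CA1); pairwise
  correlation comes from a shared per-region mother process; a configured
  fraction of spikes receives a short-ISI doublet, setting the bursting
  index.
- **Drug effects**: dictionaries of dotted parameter paths with `mul`/
  `add` transforms (fractions clipped to [0, 1]), applied to a deep copy
  with provenance recorded. `generate_drug_session` splices two same-seed
  sessions at the injection time so pre/post share background phase and
  state schedule. The shipped presets change slow-wave amplitude/duration,
  ripple size/rate/frequency and coupling in the directions reported for
  zolpidem, diazepam and THIP in the rodent literature.

## 6. Group statistics

The decision tree for condition comparisons is deterministic in the data:
if every group passes Shapiro–Wilk and the set passes Bartlett (α = 0.05),
one-way ANOVA with Bonferroni-corrected pairwise t-tests against control;
otherwise Kruskal–Wallis with Dunn's rank post-hoc under Šidák adjustment
(tie-corrected rank z; p_adj = 1 − (1 − p)^m). Dunn–Šidák is implemented
in-package because no installed library provides it. PAC changes are
tested separately with a one-sample t against zero and Welch t against
control, since their variances are typically unequal. Per-frequency-bin
spectral comparisons apply the full tree per 0.25 Hz bin, with an optional
Bonferroni correction across bins.

Calibration: on 1,000 simulated null datasets (4 groups × n = 4) the
omnibus rejection rate at α = 0.05 is 0.056 for Gaussian data (ANOVA path
chosen 78% of the time) and 0.040 for Cauchy data (Kruskal–Wallis path
79%), within the accepted 0.05 ± 0.02 band.

## 7. Validation summary (defaults, 20 seeded sessions)

- Detector fidelity with ±0.25 s matching (trough for slow-waves,
  interval midpoint for spindles/ripples): recall/precision ≈ 0.96/1.00
  (slow-waves), 0.99/1.00 (spindles), 0.99/1.00 (ripples).
- Injected slow-wave amplitude changes of +10/+25/+50% are recovered as
  +9.1/+23.8/+48.1% (20 seeds, NREM-rich sessions, tight amplitude
  distribution); recovery is monotone in the injected effect.
- Coupling depth 0 → 0.8 produces a positive modulation-index change in
  20/20 seeds, with the comodulogram maximum in the 0.5–1.5 × 10–16 Hz
  window.
- With down-state suppression 0.8, 10/10 cortical units show negative
  event-locked z; common-input pairs beat independent pairs on the
  cross-correlogram statistic in 98/100 pairs; the bursting index
  converges to the configured fraction within 0.01 at > 10,000 spikes.

## 8. Numerical choices and limitations

- Detection thresholds are in SD units of the whole analysis trace, so
  pre/post windows are detected independently (`detect_windowed`); a drug
  that changes background variance changes the µV meaning of 3.5 SD, which
  is the standard convention but a real interpretive caveat.
- Amplitude recovery has a small negative bias (≈1–2 pp at +50%) because
  the detection threshold truncates the amplitude distribution at slightly
  different relative points pre and post; with wide amplitude
  distributions (SD 80 µV at mean 400 µV) this bias grows to ≈5 pp.
- The generator's waves are stereotyped templates in stationary 1/f noise:
  no waveform asymmetry across the night, no inter-regional propagation
  delays, no REM theta–gamma coupling. Detector fidelity numbers on it are
  upper bounds for real data.
- The sinusoidal-coupling MI has no analytic closed form under Hilbert
  estimation; the 1e-10 oracle agreement is on the binning stage, with the
  Hilbert stage validated separately on constructed signals.
- Kruskal–Wallis p-values at n = 4 per group rely on the χ² approximation;
  the measured type-I error (0.040) is slightly conservative, as expected.
- EDF files are read (via `mne`) but not written; CSV with a `# fs=`
  header is the canonical continuous format.
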