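# somnoscope

Detection and quantification of NREM-sleep oscillations — cortical
slow-waves, sleep spindles and hippocampal ripples — in rodent
electrophysiology, with the downstream statistics used in pre/post drug
studies.

## Scientific problem

GABAergic hypnotics (zolpidem, diazepam, THIP) all promote sleep, but they
reshape the oscillations of NREM sleep differently: a drug can deepen
slow-waves while suppressing spindles, or shrink hippocampal ripples while
leaving cortical events untouched. Because these oscillations — and the
precise phase coupling between them — are the substrate of sleep-dependent
memory consolidation, quantifying how a compound changes them matters as
much as whether it induces sleep.

Answering that question takes a chain of analyses: score vigilance states
from LFP/EMG, detect the three event classes with amplitude- and
duration-based rules, measure spectra and slow-wave/spindle phase-amplitude
coupling, relate spike trains of single units to the detected events, and
compare drug groups against vehicle with assumption-aware statistics.
`somnoscope` implements that chain end to end, plus a fully parameterized
synthetic-session generator so every stage can be validated against known
ground truth.

## What is in the package

| module | contents |
|---|---|
| `somnoscope.dataio` | signals, hypnograms, events, spike trains; CSV/EDF/YAML I/O |
| `somnoscope.synthgen` | synthetic session generator (LFP, EMG, spikes, ground truth) |
| `somnoscope.events` | zero-phase band-pass + z-score detectors for slow-waves, spindles, ripples |
| `somnoscope.spectral` | 4 s-window power spectra, SWA time courses, modulation index, comodulograms |
| `somnoscope.units` | unit classification, bursting index, PETHs, cross-correlograms |
| `somnoscope.grouping` | vigilance scoring, pre/post change records, ANOVA/Kruskal–Wallis decision tree |
| `somnoscope.pipeline` | per-session orchestration (`analyze_session`) |
| `somnoscope.cli` | `somnoscope simulate|detect|pac|units|pipeline` |

Detection conventions: events are found on band-passed
(slow-waves 0.5–4 Hz, spindles 8–16 Hz, ripples 125–220 Hz), z-scored
traces at a 3.5 SD threshold; slow-waves additionally need > 50 µV trough
negativity; spindle/ripple intervals are cut at 1.5 / 2 SD envelope edges,
merged across < 0.5 s / < 50 ms gaps and bounded to 0.35–4 s / 50–500 ms.
All thresholds live in `DetectionConfig` and can be loaded from YAML.

## Worked example

Simulate a session whose generating parameters change at a (virtual)
zolpidem injection, then recover the drug effect with the analysis
pipeline:

```python
from somnoscope import GenParams, SessionManifest, analyze_session
from somnoscope.synthgen import DRUG_EFFECTS, generate_drug_session

params = GenParams(duration=840.0, fs=500.0, nrem_bout_mean=150.0,
                   wake_bout_mean=30.0, rem_prob=0.1)
session = generate_drug_session(params, DRUG_EFFECTS["zolpidem"],
                                injection_time=420.0, seed=42)

manifest = SessionManifest(subject="example", condition="zolpidem",
                           injection_time=420.0,
                           baseline_window=(60.0, 420.0),
                           post_window=(480.0, 840.0))
res = analyze_session(session.prl_signal, session.ca1_signal,
                      session.hypnogram, manifest)
for c in res["changes"]:
    if c.metric in ("slow_wave_amplitude", "slow_wave_intrinsic_freq",
                    "ripple_density_per_min"):
        print(f"{c.metric}: {c.change:+.1f}%")
```

Output:

```
slow_wave_amplitude: +24.2%
slow_wave_intrinsic_freq: -1.8%
ripple_density_per_min: +37.0%
```

The `zolpidem` preset multiplies the generator's slow-wave amplitude by
1.237, lengthens slow-waves by 6.4% and adds 30% more ripples; the
pipeline recovers +24.2% amplitude, −1.8% intrinsic frequency and more
ripples from the raw traces alone. `res` also carries the detected events,
per-window power spectra (0.25 Hz bins, % of baseline) and vigilance-state
amounts; `compute_pac=True` adds pre/post comodulograms and the
slow-wave→spindle modulation-index change.

Group-level comparisons take one change value per subject and condition:

```python
from somnoscope import compare_groups
result = compare_groups({"saline": [...], "zolpidem": [...], ...})
# result.test_used is "anova_bonferroni" or "kruskal_dunn",
# chosen from Shapiro-Wilk + Bartlett checks; result.posthoc holds
# the pairwise table against the control group
```

## Reproduction

`scripts/acceptance.py` runs the package's main computations on seeded
synthetic data — detector recall/precision, rule conformance against a
brute-force oracle, modulation-index closed forms, drug-effect parameter
recovery, coupling recovery, spike-train analytics, type-I error
calibration of the statistics tree, and scorer agreement — and writes the
headline numbers as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; the same seed reproduces the file
bit for bit. The test suite (`tests/test_acceptance.py`) asserts the
corresponding guarantees, e.g. recall/precision ≥ 0.9 for all three
detectors, recovered amplitude changes within ±5 percentage points of the
injected ones, and omnibus type-I error within 0.05 ± 0.02.

See `docs/methods.md` for the underlying model, numerical choices and
limitations.
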