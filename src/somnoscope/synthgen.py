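"""Synthetic polysomnography sessions with known ground truth.

The generator builds paired prefrontal (PrL) and hippocampal (CA1) LFP
channels as 1/f background noise plus injected oscillatory transients —
slow-waves (0.5–4 Hz biphasic waves), spindles (8–16 Hz bursts, optionally
phase-locked to slow-waves) and CA1 ripples (125–220 Hz bursts) — together
with an EMG channel, a 4 s-epoch hypnogram, and inhomogeneous-Poisson spike
trains showing down-state suppression, ripple gain, burstiness and pairwise
common-input correlation.  Every draw is a function of (params, seed), so a
session is exactly reproducible.

Event densities are expressed per minute of NREM sleep.  A configurable
"leak" fraction of each event kind is deliberately placed outside NREM,
emulating the imperfect state specificity of real detections (in vivo,
roughly 95% of slow-waves, 85% of spindles and ~70% of ripples fall inside
NREM).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dataio import (
    ContinuousSignal,
    EventKind,
    Hypnogram,
    OscillationEvent,
    Region,
    SpikeTrain,
    VigilanceState,
)

__all__ = [
    "EventGenParams",
    "SpikeGenParams",
    "GenParams",
    "SyntheticSession",
    "make_background",
    "make_hypnogram",
    "inject_events",
    "generate_spike_trains",
    "apply_drug_effect",
    "generate_session",
    "DRUG_EFFECTS",
]


@dataclass
class EventGenParams:
    """Generation settings for one event kind (densities per NREM minute)."""

    density: float  # events / NREM min
    amplitude_mean: float  # µV (peak-to-peak for slow-waves, envelope peak otherwise)
    amplitude_sd: float
    duration_mean: float  # s
    duration_sd: float
    carrier: float  # Hz (spindles/ripples); ignored for slow-waves
    leak_fraction: float = 0.0  # fraction of events placed outside NREM


@dataclass
class SpikeGenParams:
    n_units_per_region: int = 8
    base_fr: float = 1.2  # Hz
    burst_fraction: float = 0.1  # target bursting index (ISI < 20 ms fraction)
    down_suppression: float = 0.7  # rate multiplier inside down states is (1 - this)
    ripple_gain: float = 1.5  # rate multiplier inside ripples is (1 + this)
    common_input_fraction: float = 0.2  # shared mother-process fraction
    pyramidal_fraction: float = 0.85


@dataclass
class GenParams:
    """All knobs of the synthetic session generator."""

    duration: float = 600.0  # s
    fs: float = 2000.0  # Hz
    epoch_len: float = 4.0  # s
    # state schedule: alternating exponential bouts
    nrem_bout_mean: float = 90.0
    wake_bout_mean: float = 45.0
    rem_bout_mean: float = 30.0
    rem_prob: float = 0.35  # probability a NREM bout is followed by REM rather than wake
    # background
    background_exponent: float = 1.0
    background_rms: float = 30.0  # µV
    # theta (5–10 Hz) added during wake and REM so a theta/SWA scorer can work
    theta_freq: float = 7.0
    wake_theta_amp: float = 40.0  # µV
    rem_theta_amp: float = 50.0
    # EMG: white noise with state-dependent RMS, wake > NREM > REM
    emg_rms: dict = field(default_factory=lambda: {"wake": 40.0, "NREM": 15.0, "REM": 5.0})
    # events
    slow_wave: EventGenParams = field(default_factory=lambda: EventGenParams(
        density=10.0, amplitude_mean=400.0, amplitude_sd=80.0,
        duration_mean=0.8, duration_sd=0.15, carrier=0.0, leak_fraction=0.05))
    spindle: EventGenParams = field(default_factory=lambda: EventGenParams(
        density=4.0, amplitude_mean=60.0, amplitude_sd=10.0,
        duration_mean=1.0, duration_sd=0.2, carrier=12.0, leak_fraction=0.15))
    ripple: EventGenParams = field(default_factory=lambda: EventGenParams(
        density=12.0, amplitude_mean=50.0, amplitude_sd=10.0,
        duration_mean=0.10, duration_sd=0.015, carrier=160.0, leak_fraction=0.30))
    # slow-wave → spindle coupling
    coupling_prob: float = 0.0  # P(a spindle is locked to a slow-wave)
    coupling_depth: float = 0.0  # 0 = no phase concentration, 1 = exact lock
    coupling_phase: float = 0.4 * np.pi  # target onset phase (2π spans one wave)
    spikes: SpikeGenParams = field(default_factory=SpikeGenParams)
    provenance: list = field(default_factory=list)

    def event_params(self, kind: EventKind) -> EventGenParams:
        return {EventKind.SLOW_WAVE: self.slow_wave,
                EventKind.SPINDLE: self.spindle,
                EventKind.RIPPLE: self.ripple}[kind]


@dataclass
class SyntheticSession:
    prl_signal: ContinuousSignal
    ca1_signal: ContinuousSignal
    emg: ContinuousSignal
    hypnogram: Hypnogram
    truth_events: list
    spike_trains: list
    params: GenParams

    def truth(self, kind: EventKind | str) -> list:
        kind = EventKind(kind)
        return [e for e in self.truth_events if e.kind == kind]


# ---------------------------------------------------------------------------
# background + hypnogram


def make_background(duration: float, fs: float, exponent: float = 1.0,
                    rms: float = 30.0, seed: int | np.random.Generator = 0) -> ContinuousSignal:
    """1/f^exponent Gaussian noise with the requested RMS (µV).

    Built by shaping the spectrum of white noise: Fourier amplitudes are
    multiplied by f^(-exponent/2) so power falls as f^-exponent.
    """
    if not 0 <= exponent <= 2:
        raise ValueError("exponent must be in [0, 2]")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short for requested fs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return ContinuousSignal(x, fs, region=Region.OTHER, label="background")


def make_hypnogram(params: GenParams, rng: np.random.Generator) -> Hypnogram:
    """Alternating exponential-length bouts, rounded to whole epochs.

    The schedule starts with a wake bout (so sleep-onset latency is defined),
    then alternates NREM with wake or REM (REM with probability rem_prob).
    """
    n_epochs = int(np.floor(params.duration / params.epoch_len))
    if n_epochs < 1:
        raise ValueError("duration shorter than one epoch")
    labels: list[VigilanceState] = []

    def push(state: VigilanceState, mean: float) -> None:
        bout = max(rng.exponential(mean), params.epoch_len)
        k = max(1, int(round(bout / params.epoch_len)))
        labels.extend([state] * k)

    push(VigilanceState.WAKE, params.wake_bout_mean)
    while len(labels) < n_epochs:
        push(VigilanceState.NREM, params.nrem_bout_mean)
        if len(labels) >= n_epochs:
            break
        if rng.random() < params.rem_prob:
            push(VigilanceState.REM, params.rem_bout_mean)
        else:
            push(VigilanceState.WAKE, params.wake_bout_mean)
    return Hypnogram(labels[:n_epochs], params.epoch_len)


def _state_mask(hyp: Hypnogram, state: VigilanceState, n: int, fs: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in hyp.intervals_of(state):
        mask[int(s * fs):int(e * fs)] = True
    return mask


def _smooth_edges(mask: np.ndarray, fs: float, ramp: float = 0.25) -> np.ndarray:
    """Boolean mask -> float gate with cosine ramps (avoids spectral splatter)."""
    k = max(int(ramp * fs), 1)
    win = np.hanning(2 * k + 1)
    win /= win.sum()
    return np.convolve(mask.astype(float), win, mode="same")


# ---------------------------------------------------------------------------
# event injection


def _slow_wave_shape(duration: float, amplitude: float, fs: float) -> tuple[np.ndarray, float]:
    """One biphasic slow-wave: raised-sine positive lobe (40% of the period)
    followed by a longer negative trough (60%).  `amplitude` is peak-to-peak,
    split 0.6/0.4 between the lobes so the wave integrates to zero — LFP
    recordings are AC-coupled, and a net-DC transient would be mangled by the
    0.5 Hz edge of the detection band-pass.  Returns the waveform and the
    trough offset (s) from wave start."""
    n = max(int(round(duration * fs)), 8)
    n_pos = max(int(round(0.4 * n)), 2)
    n_neg = n - n_pos
    a_neg = amplitude * 0.4
    a_pos = amplitude * 0.6
    pos = a_pos * np.sin(np.pi * np.arange(n_pos) / n_pos)
    neg = -a_neg * np.sin(np.pi * np.arange(n_neg) / n_neg)
    wave = np.concatenate([pos, neg])
    trough_offset = (n_pos + n_neg / 2.0) / fs
    return wave, trough_offset


def _burst_shape(duration: float, amplitude: float, carrier: float, fs: float,
                 phase: float) -> np.ndarray:
    """Tukey-windowed sinusoid: flat-topped so the envelope holds its peak for
    half the event and the detected edges sit close to the true support."""
    n = max(int(round(duration * fs)), 8)
    t = np.arange(n) / fs
    win = sps.windows.tukey(n, alpha=0.5)
    return amplitude * win * np.sin(2 * np.pi * carrier * t + phase)


def _draw_positions(rng: np.random.Generator, intervals: list, count: int,
                    dur: np.ndarray, occupied: list, max_tries: int = 200) -> list:
    """Place `count` events of durations `dur` wholly inside `intervals`,
    rejecting overlap with previously `occupied` same-kind spans."""
    total = sum(e - s for s, e in intervals)
    placed = []
    for i in range(count):
        d = dur[i]
        ok = False
        for _ in range(max_tries):
            u = rng.uniform(0, total)
            acc = 0.0
            for s, e in intervals:
                if u < acc + (e - s):
                    start = s + (u - acc)
                    break
                acc += e - s
            if start + d > e:  # must fit inside its interval
                continue
            if any(start < oe and start + d > os for os, oe in occupied):
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError("rejection sampling failed: event density too high for available time")
        occupied.append((start, start + d))
        placed.append(start)
    return placed


def inject_events(signal: ContinuousSignal, hypnogram: Hypnogram, params: GenParams,
                  seed: int | np.random.Generator, kinds: tuple = (EventKind.SLOW_WAVE, EventKind.SPINDLE),
                  ) -> tuple[ContinuousSignal, list]:
    """Add transient oscillatory events to a copy of `signal`.

    Returns the modified signal and the ground-truth event list.  Slow-wave
    truth records peak-to-peak amplitude and trough time; spindle/ripple truth
    records envelope-peak amplitude, centre time and carrier frequency.  When
    coupling is on, a fraction of spindle onsets is drawn at a von Mises
    concentration around `coupling_phase` of a host slow-wave (2π spanning the
    wave's full period).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = signal.fs
    x = signal.samples.copy()
    nrem = hypnogram.intervals_of(VigilanceState.NREM)
    non_nrem = (hypnogram.intervals_of(VigilanceState.WAKE)
                + hypnogram.intervals_of(VigilanceState.REM))
    nrem_minutes = sum(e - s for s, e in nrem) / 60.0
    truth: list[OscillationEvent] = []
    slow_waves: list[tuple[float, float]] = []  # (start, duration) for coupling hosts

    for kind in kinds:
        ep = params.event_params(kind)
        if ep.density <= 0 or nrem_minutes <= 0:
            continue
        n_total = rng.poisson(ep.density * nrem_minutes)
        n_leak = rng.binomial(n_total, ep.leak_fraction) if ep.leak_fraction > 0 else 0
        n_nrem = n_total - n_leak
        durs = np.clip(rng.normal(ep.duration_mean, ep.duration_sd, n_total),
                       0.5 * ep.duration_mean, 2.0 * ep.duration_mean)
        amps = np.clip(rng.normal(ep.amplitude_mean, ep.amplitude_sd, n_total),
                       0.3 * ep.amplitude_mean, None)
        occupied: list[tuple[float, float]] = []
        starts = _draw_positions(rng, nrem, n_nrem, durs[:n_nrem], occupied)
        if n_leak and non_nrem:
            starts += _draw_positions(rng, non_nrem, n_leak, durs[n_nrem:], occupied)
        order = np.argsort(starts)
        starts = [starts[i] for i in order]
        durs = durs[:len(order)][order]
        amps = amps[:len(order)][order]

        if kind == EventKind.SPINDLE and params.coupling_prob > 0 and slow_waves:
            starts = _couple_spindle_onsets(rng, params, starts, durs, slow_waves, nrem)

        for st, d, a in zip(starts, durs, amps):
            i0 = int(round(st * fs))
            if kind == EventKind.SLOW_WAVE:
                wave, troff = _slow_wave_shape(d, a, fs)
                if i0 + wave.size > x.size:
                    continue
                x[i0:i0 + wave.size] += wave
                end = st + wave.size / fs
                truth.append(OscillationEvent(kind, st, end, st + troff, a, 1.0 / (end - st)))
                slow_waves.append((st, end - st))
            else:
                phase = rng.uniform(0, 2 * np.pi)
                burst = _burst_shape(d, a, ep.carrier, fs, phase)
                if i0 + burst.size > x.size:
                    continue
                x[i0:i0 + burst.size] += burst
                end = st + burst.size / fs
                truth.append(OscillationEvent(kind, st, end, (st + end) / 2.0, a, ep.carrier))

    truth.sort(key=lambda e: e.start)
    out = ContinuousSignal(x, fs, signal.region, signal.label, signal.t0)
    return out, truth


def _couple_spindle_onsets(rng, params: GenParams, starts, durs, slow_waves, nrem):
    """Re-draw a fraction of spindle onsets at a target slow-wave phase."""
    c = float(np.clip(params.coupling_depth, 0.0, 1.0))
    new = list(starts)
    sw_arr = np.array(slow_waves)  # (start, duration)
    for i in range(len(new)):
        if rng.random() >= params.coupling_prob:
            continue
        sw_start, sw_dur = sw_arr[rng.integers(len(sw_arr))]
        if c >= 1.0:
            phi = params.coupling_phase
        elif c <= 0.0:
            phi = rng.uniform(0, 2 * np.pi)
        else:
            kappa = 10.0 * c / (1.0 - c)
            phi = rng.vonmises(params.coupling_phase, kappa) % (2 * np.pi)
        new[i] = sw_start + sw_dur * phi / (2 * np.pi)
    return new


# ---------------------------------------------------------------------------
# spike trains


def _modulation_intervals(truth_events, params: GenParams):
    """(start, end, factor) windows where the firing rate is scaled."""
    out = []
    s = params.spikes
    for e in truth_events:
        if e.kind == EventKind.SLOW_WAVE and s.down_suppression > 0:
            out.append((e.peak_time - 0.125, e.peak_time + 0.125, 1.0 - s.down_suppression))
        elif e.kind == EventKind.RIPPLE and s.ripple_gain != 0:
            out.append((e.start, e.end, 1.0 + s.ripple_gain))
    return out


def _rate_factor(times: np.ndarray, windows) -> np.ndarray:
    f = np.ones_like(times)
    for s, e, fac in windows:
        f[(times >= s) & (times < e)] = fac
    return f


def generate_spike_trains(hypnogram: Hypnogram, truth_events, params: GenParams,
                          seed: int | np.random.Generator) -> list:
    """Inhomogeneous-Poisson spike trains for both regions.

    Rate = base_fr, multiplied by (1 - down_suppression) within ±125 ms of
    slow-wave troughs and by (1 + ripple_gain) inside ripples (CA1 units only
    for ripples; slow-wave suppression applies to both regions, hippocampal
    firing being entrained by cortical slow oscillations).  Pairwise
    correlation comes from a per-region shared mother process thinned into
    each unit; burstiness from doublets appended to a fraction of spikes.
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sp = params.spikes
    if sp.base_fr <= 0:
        raise ValueError("base_fr must be > 0")
    T = hypnogram.duration
    trains: list[SpikeTrain] = []
    for region in (Region.PRL, Region.CA1):
        windows = [w for w in _modulation_intervals(truth_events, params)
                   if not (region == Region.PRL and w[2] > 1.0)]  # ripple gain only in CA1
        lam_max = sp.base_fr * (1.0 + max(sp.ripple_gain, 0.0))
        # shared mother process at the ceiling rate
        n_mother = rng.poisson(lam_max * T)
        mother = np.sort(rng.uniform(0, T, n_mother))
        n_pyr = int(round(sp.pyramidal_fraction * sp.n_units_per_region))
        for u in range(sp.n_units_per_region):
            shared = mother[rng.random(mother.size) < sp.common_input_fraction]
            n_own = rng.poisson(lam_max * (1.0 - sp.common_input_fraction) * T)
            own = rng.uniform(0, T, n_own)
            t = np.sort(np.concatenate([shared, own]))
            keep_p = sp.base_fr * _rate_factor(t, windows) / lam_max
            t = t[rng.random(t.size) < keep_p]
            # burstiness: append a doublet to fraction p so that the ISI<20 ms
            # proportion converges to burst_fraction: p/(1+p) = b.
            b = float(np.clip(sp.burst_fraction, 0.0, 0.95))
            if b > 0 and t.size:
                p = b / (1.0 - b)
                sel = rng.random(t.size) < p
                doublets = t[sel] + rng.uniform(0.002, 0.015, int(sel.sum()))
                t = np.concatenate([t, doublets])
            t = np.unique(t)
            t = t[(t >= 0) & (t < T)]
            if t.size < 2:
                t = np.sort(rng.uniform(0, T, 2))  # degenerate guard
            pyramidal = u < n_pyr
            width = (rng.normal(300.0, 30.0) if pyramidal else rng.normal(150.0, 20.0))
            width = float(np.clip(width, 210.0, None) if pyramidal else np.clip(width, 60.0, 195.0))
            trains.append(SpikeTrain(
                unit_id=f"{region.value}_{u:02d}", region=region, times=t, spike_width=width))
    return trains


# ---------------------------------------------------------------------------
# drug-effect transforms


DRUG_EFFECTS = {
    # directions follow the in-vivo findings: zolpidem boosts slow-wave
    # amplitude and slow-wave/spindle coupling, slows slow-waves slightly and
    # adds ripples; diazepam shrinks slow-waves and ripples and speeds
    # ripples up; THIP gives a modest slow-wave amplitude boost.
    "saline": {},
    "zolpidem": {
        "slow_wave.amplitude_mean": {"mul": 1.237},
        "slow_wave.duration_mean": {"mul": 1.064},
        "ripple.density": {"mul": 1.3},
        "coupling_prob": {"add": 0.5},
        "coupling_depth": {"add": 0.6},
    },
    "diazepam": {
        "slow_wave.amplitude_mean": {"mul": 0.72},
        "ripple.amplitude_mean": {"mul": 0.433},
        "ripple.carrier": {"mul": 1.05},
    },
    "THIP": {
        "slow_wave.amplitude_mean": {"mul": 1.146},
    },
}

_CLIP01 = {"coupling_prob", "coupling_depth", "slow_wave.leak_fraction",
           "spindle.leak_fraction", "ripple.leak_fraction",
           "spikes.burst_fraction", "spikes.down_suppression",
           "spikes.common_input_fraction", "spikes.pyramidal_fraction"}


def apply_drug_effect(params: GenParams, effect: dict) -> GenParams:
    """Return a new GenParams with named fields transformed.

    `effect` maps dotted parameter paths (e.g. "slow_wave.amplitude_mean") to
    {"mul": x} and/or {"add": y}.  Fractional parameters are clipped to
    [0, 1].  The applied transform is appended to the new params' provenance.
    """
    new = copy.deepcopy(params)
    for path, tr in effect.items():
        obj = new
        parts = path.split(".")
        for p in parts[:-1]:
            if not hasattr(obj, p):
                raise KeyError(f"unknown parameter path {path!r}")
            obj = getattr(obj, p)
        leaf = parts[-1]
        if not hasattr(obj, leaf):
            raise KeyError(f"unknown parameter path {path!r}")
        val = getattr(obj, leaf)
        if not isinstance(val, (int, float)):
            raise KeyError(f"parameter {path!r} is not numeric")
        if "mul" in tr:
            val = val * tr["mul"]
        if "add" in tr:
            val = val + tr["add"]
        if path in _CLIP01:
            val = float(np.clip(val, 0.0, 1.0))
        setattr(obj, leaf, val)
    new.provenance = list(params.provenance) + [dict(effect)]
    return new


# ---------------------------------------------------------------------------
# full session


def generate_session(params: GenParams | None = None, seed: int = 0) -> SyntheticSession:
    """Build a complete synthetic session from a single seed."""
    params = params if params is not None else GenParams()
    if params.fs <= 2 * max(params.ripple.carrier, params.spindle.carrier, params.theta_freq):
        raise ValueError("fs must exceed twice the highest carrier frequency")
    rng = np.random.default_rng(seed)
    hyp = make_hypnogram(params, rng)
    T = hyp.duration
    n = int(round(T * params.fs))

    prl = make_background(T, params.fs, params.background_exponent, params.background_rms, rng)
    prl.region, prl.label = Region.PRL, "PrL"
    ca1 = make_background(T, params.fs, params.background_exponent, params.background_rms, rng)
    ca1.region, ca1.label = Region.CA1, "CA1"

    # theta during wake and REM on both channels
    t = np.arange(n) / params.fs
    theta = np.sin(2 * np.pi * params.theta_freq * t + rng.uniform(0, 2 * np.pi))
    for sig in (prl, ca1):
        gate_w = _smooth_edges(_state_mask(hyp, VigilanceState.WAKE, n, params.fs), params.fs)
        gate_r = _smooth_edges(_state_mask(hyp, VigilanceState.REM, n, params.fs), params.fs)
        sig.samples += theta * (params.wake_theta_amp * gate_w + params.rem_theta_amp * gate_r)

    prl, truth_prl = inject_events(prl, hyp, params, rng,
                                   kinds=(EventKind.SLOW_WAVE, EventKind.SPINDLE))
    ca1, truth_ca1 = inject_events(ca1, hyp, params, rng, kinds=(EventKind.RIPPLE,))
    truth = sorted(truth_prl + truth_ca1, key=lambda e: e.start)

    emg_noise = rng.standard_normal(n)
    emg_amp = np.zeros(n)
    for state, key in ((VigilanceState.WAKE, "wake"), (VigilanceState.NREM, "NREM"),
                       (VigilanceState.REM, "REM")):
        emg_amp += params.emg_rms[key] * _state_mask(hyp, state, n, params.fs)
    emg = ContinuousSignal(emg_noise * emg_amp, params.fs, Region.EMG, "EMG")

    spikes = generate_spike_trains(hyp, truth, params, rng)
    return SyntheticSession(prl, ca1, emg, hyp, truth, spikes, params)


def generate_drug_session(params: GenParams, effect: dict, injection_time: float,
                          seed: int = 0) -> SyntheticSession:
    """Session whose generating parameters change at `injection_time`.

    Two full sessions are generated from the same seed — one with `params`,
    one with the drug effect applied — and spliced at the injection sample:
    signals, truth events and spike trains before the injection come from the
    untreated session, after it from the treated one.  State-schedule
    parameters must not be part of the effect (the hypnogram is shared).
    """
    base = generate_session(params, seed=seed)
    treated = generate_session(apply_drug_effect(params, effect), seed=seed)
    fs = params.fs
    i_inj = int(round(injection_time * fs))

    def splice(a: ContinuousSignal, b: ContinuousSignal) -> ContinuousSignal:
        x = a.samples.copy()
        x[i_inj:] = b.samples[i_inj:]
        return ContinuousSignal(x, fs, a.region, a.label, a.t0)

    truth = ([e for e in base.truth_events if e.end <= injection_time]
             + [e for e in treated.truth_events if e.start >= injection_time])
    truth.sort(key=lambda e: e.start)
    spikes = []
    for ta, tb in zip(base.spike_trains, treated.spike_trains):
        t = np.concatenate([ta.times[ta.times < injection_time],
                            tb.times[tb.times >= injection_time]])
        spikes.append(SpikeTrain(ta.unit_id, ta.region, np.unique(t), ta.spike_width))
    return SyntheticSession(
        splice(base.prl_signal, treated.prl_signal),
        splice(base.ca1_signal, treated.ca1_signal),
        splice(base.emg, treated.emg),
        base.hypnogram, truth, spikes, treated.params)
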