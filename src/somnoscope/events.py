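"""Detection of slow-waves, spindles and ripples from LFP.

The detection chain is: zero-phase band-pass filter → z-score over the whole
submitted trace → (slow-waves) zero-crossing delimited waves with a ±3.5 SD
extremum and a > 50 µV trough negativity, or (spindles/ripples) a cubic-spline
envelope of the rectified z-score with a 3.5 SD detection threshold, lower
edge thresholds for start/end times, gap merging and duration bounds.

Detection is deliberately not restricted to NREM sleep; events are tagged
with their vigilance state afterwards (:func:`attribute_state`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .dataio import (
    BandConfig,
    ContinuousSignal,
    DetectionConfig,
    EventKind,
    Hypnogram,
    OscillationEvent,
    VigilanceState,
)

__all__ = [
    "ZScoredBandSignal",
    "Envelope",
    "bandpass_zscore",
    "spline_envelope",
    "detect_slow_waves",
    "detect_band_events",
    "detect_events",
    "attribute_state",
    "state_fractions",
    "apply_interval_rules",
]


@dataclass
class ZScoredBandSignal:
    """Band-pass filtered trace in SD units, with the µV scaling retained."""

    z: np.ndarray
    band: tuple[float, float]
    fs: float
    mean: float  # µV, of the filtered trace
    sd: float  # µV

    def to_uv(self) -> np.ndarray:
        return self.z * self.sd + self.mean


@dataclass
class Envelope:
    """Spline envelope of a rectified z-scored trace (SD units)."""

    values: np.ndarray
    fs: float


def _design_fir(band: tuple[float, float], fs: float) -> np.ndarray:
    """Linear-phase Hamming-window band-pass FIR.

    The transition width scales with the band edges (a quarter of the lower
    edge, capped by the headroom to Nyquist), which keeps the kernel short for
    ripple-band work while still resolving a 0.5 Hz edge.
    """
    lo, hi = band
    nyq = fs / 2.0
    trans = min(lo / 2.0, (nyq - hi) / 2.0, 10.0)
    trans = max(trans, 0.05)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps |= 1  # odd length -> integer group delay, exact zero phase
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def _zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of a symmetric FIR via FFT convolution.

    For a linear-phase kernel this equals filtfilt (magnitude response
    squared, zero phase) but runs in O(N log N).  Edges are reflection-padded
    by one kernel length.
    """
    pad = taps.size
    if x.size <= pad:
        pad = x.size - 1
    xp = np.pad(x, pad, mode="reflect") if pad > 0 else x
    y = sps.fftconvolve(xp, taps, mode="same")
    y = sps.fftconvolve(y, taps, mode="same")
    return y[pad:pad + x.size] if pad > 0 else y


def bandpass_zscore(signal: ContinuousSignal, band: tuple[float, float]) -> ZScoredBandSignal:
    """Zero-phase band-pass then z-score over the whole trace.

    The mean and SD used for scaling are stored so detected amplitudes can be
    reported back in µV.  A constant (zero-variance) trace yields all-zero z.
    """
    lo, hi = band
    if not 0 < lo < hi < signal.fs / 2:
        raise ValueError(f"band {band} must lie inside (0, fs/2 = {signal.fs / 2})")
    taps = _design_fir(band, signal.fs)
    filt = _zero_phase_filter(signal.samples, taps)
    mean = float(np.mean(filt))
    sd = float(np.std(filt))
    if sd < 1e-12:
        z = np.zeros_like(filt)
        sd = 0.0
    else:
        z = (filt - mean) / sd
    return ZScoredBandSignal(z=z, band=(lo, hi), fs=signal.fs, mean=mean, sd=sd)


def spline_envelope(zsignal: ZScoredBandSignal | np.ndarray, fs: float | None = None) -> Envelope:
    """Cubic-spline envelope through the local maxima of the rectified trace.

    The spline interpolates |z| at its local maxima and is evaluated at every
    sample; beyond the first/last maximum the envelope holds that maximum's
    value.
    """
    if isinstance(zsignal, ZScoredBandSignal):
        z, fs = zsignal.z, zsignal.fs
    else:
        z = np.asarray(zsignal, float)
        if fs is None:
            raise ValueError("fs required for raw-array input")
    r = np.abs(z)
    peaks, _ = sps.find_peaks(r)
    if peaks.size < 4:
        raise ValueError(
            f"only {peaks.size} local maxima in rectified trace; need ≥ 4 "
            "(submit a longer input)")
    spline = CubicSpline(peaks, r[peaks])
    env = np.empty_like(r)
    inner = slice(peaks[0], peaks[-1] + 1)
    env[inner] = spline(np.arange(peaks[0], peaks[-1] + 1))
    env[:peaks[0]] = r[peaks[0]]
    env[peaks[-1] + 1:] = r[peaks[-1]]
    return Envelope(values=env, fs=fs)


# ---------------------------------------------------------------------------
# interval rules (shared by the detectors and testable against brute force)


def apply_interval_rules(intervals: list, merge_gap: float, min_dur: float,
                         max_dur: float) -> list:
    """Merge, then duration-filter, a sorted list of (start, end) intervals.

    Two intervals separated by a gap strictly smaller than `merge_gap` are
    merged; merging is applied transitively before any duration bound, then
    intervals shorter than `min_dur` or longer than `max_dur` are dropped.
    """
    if not intervals:
        return []
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if min_dur <= e - s <= max_dur]


# ---------------------------------------------------------------------------
# slow-waves


def detect_slow_waves(signal: ContinuousSignal, cfg: BandConfig | None = None) -> list:
    """Slow-waves from the 0.5–4 Hz z-scored trace.

    A candidate wave is one positive-then-negative pair of half-waves
    delimited by zero crossings.  It qualifies if either extremum exceeds
    ``detect_thresh`` SD; its amplitude is the initial positive peak minus the
    maximal negative trough (µV of the filtered trace) and waves whose trough
    negativity does not exceed ``min_negativity`` (50 µV) are rejected.
    peak_time is the trough time; intrinsic frequency is 1/duration.
    """
    cfg = cfg if cfg is not None else DetectionConfig()[EventKind.SLOW_WAVE]
    zs = bandpass_zscore(signal, cfg.band)
    z, fs, sd = zs.z, zs.fs, zs.sd
    if sd == 0.0:
        return []
    sign = np.sign(z)
    sign[sign == 0] = 1
    crossings = np.flatnonzero(np.diff(sign) != 0) + 1  # index of first sample after crossing
    if crossings.size < 3:
        return []
    events: list[OscillationEvent] = []
    segs = list(zip(np.r_[0, crossings], np.r_[crossings, z.size]))
    for k in range(len(segs) - 1):
        s0, e0 = segs[k]
        s1, e1 = segs[k + 1]
        if z[s0] <= 0 or z[s1] >= 0:
            continue  # want positive half-wave followed by negative half-wave
        pos_peak = float(np.max(z[s0:e0]))
        trough_i = s1 + int(np.argmin(z[s1:e1]))
        trough = float(z[trough_i])
        if pos_peak < cfg.detect_thresh and trough > -cfg.detect_thresh:
            continue
        trough_uv = trough * sd
        if cfg.min_negativity is not None and -trough_uv <= cfg.min_negativity:
            continue
        start, end = s0 / fs, e1 / fs
        dur = end - start
        if not (cfg.min_dur <= dur <= cfg.max_dur):
            continue
        amplitude = (pos_peak - trough) * sd
        events.append(OscillationEvent(
            kind=EventKind.SLOW_WAVE,
            start=signal.t0 + start, end=signal.t0 + end,
            peak_time=signal.t0 + trough_i / fs,
            amplitude=amplitude, intrinsic_freq=1.0 / dur))
    return events


# ---------------------------------------------------------------------------
# spindles / ripples


def detect_band_events(signal: ContinuousSignal, kind: EventKind | str,
                       cfg: BandConfig | None = None) -> list:
    """Spindles or ripples from the spline envelope of the band-passed trace.

    An event exists wherever the envelope exceeds ``detect_thresh`` SD; its
    start and end are where the envelope falls back through ``edge_thresh``.
    Events separated by less than ``merge_gap`` are merged first, then
    duration bounds are applied.  Amplitude is the envelope peak rescaled to
    µV; intrinsic frequency is the within-event cycle rate (positive peaks of
    the filtered trace minus one, over the duration).
    """
    kind = EventKind(kind)
    if kind == EventKind.SLOW_WAVE:
        raise ValueError("use detect_slow_waves for slow-waves")
    cfg = cfg if cfg is not None else DetectionConfig()[kind]
    zs = bandpass_zscore(signal, cfg.band)
    if zs.sd == 0.0:
        return []
    env = spline_envelope(zs).values
    fs = zs.fs
    above_edge = env >= cfg.edge_thresh
    # contiguous runs above the edge threshold that contain a detection crossing
    d = np.diff(above_edge.astype(int))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1) + 1
    if above_edge[0]:
        run_starts = np.r_[0, run_starts]
    if above_edge[-1]:
        run_ends = np.r_[run_ends, above_edge.size]
    candidates = []
    for s, e in zip(run_starts, run_ends):
        if np.max(env[s:e]) >= cfg.detect_thresh:
            candidates.append((s / fs, e / fs))
    intervals = apply_interval_rules(candidates, cfg.merge_gap, cfg.min_dur, cfg.max_dur)
    pos_peaks, _ = sps.find_peaks(zs.z)
    events: list[OscillationEvent] = []
    for s, e in intervals:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        peak_i = i0 + int(np.argmax(env[i0:i1]))
        n_peaks = int(np.sum((pos_peaks >= i0) & (pos_peaks < i1)))
        dur = e - s
        freq = max(n_peaks - 1, 0) / dur
        events.append(OscillationEvent(
            kind=kind, start=signal.t0 + s, end=signal.t0 + e,
            peak_time=signal.t0 + peak_i / fs,
            amplitude=float(np.max(env[i0:i1])) * zs.sd,
            intrinsic_freq=freq if freq > 0 else 1.0 / dur))
    return events


def detect_events(signal: ContinuousSignal, kind: EventKind | str,
                  cfg: DetectionConfig | None = None) -> list:
    """Dispatch to the appropriate detector for `kind`."""
    kind = EventKind(kind)
    cfg = cfg if cfg is not None else DetectionConfig()
    if kind == EventKind.SLOW_WAVE:
        return detect_slow_waves(signal, cfg[kind])
    return detect_band_events(signal, kind, cfg[kind])


# ---------------------------------------------------------------------------
# state attribution


def attribute_state(events: list, hypnogram: Hypnogram) -> list:
    """Tag each event with the vigilance state of the epoch holding its peak.

    Events whose peak falls outside the hypnogram are tagged "unscored".
    Returns the same event objects, mutated in place, for chaining.
    """
    for e in events:
        e.state = hypnogram.state_at(e.peak_time)
    return events


def state_fractions(events: list) -> dict:
    """Fraction of events per vigilance state (over state-tagged events)."""
    if not events:
        return {}
    out: dict[str, float] = {}
    for e in events:
        key = e.state.value if e.state is not None else "unscored"
        out[key] = out.get(key, 0) + 1
    return {k: v / len(events) for k, v in out.items()}
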