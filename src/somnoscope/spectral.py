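"""Power spectra, slow-wave-activity time courses and phase-amplitude coupling.

Spectra follow the classic sleep-EEG convention: mean periodogram over
non-overlapping 4 s Hamming-windowed segments, giving 0.25 Hz bins.  SWA is
the 0.5–4 Hz mean power per 4 s segment averaged into 5-min bins.  Coupling
is quantified with the Kullback–Leibler modulation index: the amplitude
envelope of the fast signal is binned by the instantaneous phase of the slow
signal and the normalized divergence of that profile from uniform is
MI = (log N − H(P)) / log N ∈ [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dataio import ContinuousSignal, Hypnogram, SessionManifest, VigilanceState
from .events import bandpass_zscore

__all__ = [
    "PowerSpectrum",
    "Comodulogram",
    "welch_power",
    "swa_timecourse",
    "modulation_index",
    "comodulogram",
    "pac_change",
    "pac_session",
    "state_segments",
]

SWA_BAND = (0.5, 4.0)
SEGMENT_LEN = 4.0  # s -> 0.25 Hz bins


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, 0.25 Hz spacing
    power: np.ndarray  # µV²/Hz
    window_len: float = SEGMENT_LEN
    n_segments: int = 0

    def band_power(self, band: tuple[float, float]) -> float:
        """Mean power density (µV²/Hz) over the closed frequency band."""
        m = (self.freqs >= band[0]) & (self.freqs <= band[1])
        return float(np.mean(self.power[m]))


@dataclass
class Comodulogram:
    phase_bands: list  # [(lo, hi), ...] Hz
    amp_bands: list
    mi: np.ndarray  # shape (n_phase, n_amp)

    @property
    def phase_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.phase_bands])

    @property
    def amp_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.amp_bands])

    def max_in_window(self, phase_win: tuple[float, float],
                      amp_win: tuple[float, float]) -> float:
        """Maximal MI over cells whose band centres fall in the closed windows."""
        pm = (self.phase_centers >= phase_win[0]) & (self.phase_centers <= phase_win[1])
        am = (self.amp_centers >= amp_win[0]) & (self.amp_centers <= amp_win[1])
        if not pm.any() or not am.any():
            raise ValueError(f"window phase={phase_win}, amp={amp_win} selects no grid cells")
        return float(np.max(self.mi[np.ix_(pm, am)]))

    def argmax(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(phase_band, amp_band) of the matrix maximum."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return self.phase_bands[i], self.amp_bands[j]


# ---------------------------------------------------------------------------
# spectra


def _eligible_segments(n_samples: int, fs: float, t0: float,
                       hypnogram: Hypnogram | None,
                       restrict: VigilanceState | None) -> list:
    """Start indices of whole 4 s segments passing the state restriction.

    A segment is dropped if any part of it falls in an artifact epoch or — when
    a restriction is given — outside the requested state.
    """
    seg = int(round(SEGMENT_LEN * fs))
    starts = []
    for i0 in range(0, n_samples - seg + 1, seg):
        if hypnogram is not None:
            t_lo = t0 + i0 / fs
            t_hi = t0 + (i0 + seg) / fs
            states = {hypnogram.state_at(t) for t in
                      np.arange(t_lo, t_hi - 1e-9, hypnogram.epoch_len)}
            states.add(hypnogram.state_at(t_hi - 1e-9))
            if VigilanceState.ARTIFACT in states:
                continue
            if restrict is not None and states != {restrict}:
                continue
        starts.append(i0)
    return starts


def welch_power(signal: ContinuousSignal, hypnogram: Hypnogram | None = None,
                restrict: VigilanceState | str | None = None) -> PowerSpectrum:
    """Mean periodogram over non-overlapping 4 s Hamming segments (0.25 Hz bins)."""
    if restrict is not None:
        restrict = VigilanceState(restrict)
        if hypnogram is None:
            raise ValueError("state restriction requires a hypnogram")
    fs = signal.fs
    seg = int(round(SEGMENT_LEN * fs))
    if signal.samples.size < seg:
        raise ValueError(f"signal shorter than one {SEGMENT_LEN} s segment")
    starts = _eligible_segments(signal.samples.size, fs, signal.t0, hypnogram, restrict)
    if not starts:
        raise ValueError("no eligible 4 s segments under the given restriction")
    acc = None
    for i0 in starts:
        f, p = sps.periodogram(signal.samples[i0:i0 + seg], fs=fs,
                               window="hamming", detrend=False)
        acc = p if acc is None else acc + p
    return PowerSpectrum(freqs=f, power=acc / len(starts), n_segments=len(starts))


def swa_timecourse(signal: ContinuousSignal, hypnogram: Hypnogram | None = None,
                   bin_len: float = 300.0, restrict: VigilanceState | str | None = None):
    """SWA (0.5–4 Hz mean power per 4 s segment) averaged in `bin_len` bins.

    Returns (bin_start_times, swa) arrays; bins with no eligible segment are
    NaN, never zero.
    """
    import pandas as pd

    if restrict is not None:
        restrict = VigilanceState(restrict)
    fs = signal.fs
    seg = int(round(SEGMENT_LEN * fs))
    starts = _eligible_segments(signal.samples.size, fs, signal.t0, hypnogram, restrict)
    if not starts:
        raise ValueError("no eligible 4 s segments")
    times, swa = [], []
    for i0 in starts:
        f, p = sps.periodogram(signal.samples[i0:i0 + seg], fs=fs,
                               window="hamming", detrend=False)
        m = (f >= SWA_BAND[0]) & (f <= SWA_BAND[1])
        times.append(signal.t0 + i0 / fs)
        swa.append(float(np.mean(p[m])))
    df = pd.DataFrame({"t": times, "swa": swa})
    total = signal.t0 + signal.samples.size / fs
    edges = np.arange(signal.t0, total + bin_len, bin_len)
    bins = pd.cut(df["t"], edges, right=False)
    out = df.groupby(bins, observed=False)["swa"].mean()
    return edges[:-1][: len(out)], out.to_numpy()


# ---------------------------------------------------------------------------
# modulation index


def modulation_index(phase_sig: np.ndarray, amp_sig: np.ndarray, n_bins: int = 18,
                     *, phase: np.ndarray | None = None,
                     amplitude: np.ndarray | None = None) -> float:
    """KL modulation index between two band-filtered traces.

    Instantaneous phase comes from the analytic signal of `phase_sig`,
    amplitude from the analytic-signal magnitude of `amp_sig`; the mean
    amplitude per 2π/n_bins phase bin, normalized to a distribution P, gives
    MI = (log N − H(P)) / log N.  Pre-computed phase/amplitude arrays may be
    passed instead (used by the surrogate machinery).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    if phase is None:
        phase = np.angle(sps.hilbert(np.asarray(phase_sig, float)))
    if amplitude is None:
        amplitude = np.abs(sps.hilbert(np.asarray(amp_sig, float)))
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude inputs must have equal length")
    total = float(np.sum(amplitude))
    if total <= 0:
        raise ValueError("amplitude signal sums to zero; MI undefined")
    bins = np.minimum(((phase + np.pi) / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    mean_amp = np.bincount(bins, weights=amplitude, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    nz = counts > 0
    mean_amp[nz] = mean_amp[nz] / counts[nz]
    s = mean_amp.sum()
    if s <= 0:
        raise ValueError("all phase bins have zero amplitude")
    p = mean_amp / s
    pp = p[p > 0]
    entropy = float(-np.sum(pp * np.log(pp)))
    return (np.log(n_bins) - entropy) / np.log(n_bins)


def state_segments(signal: ContinuousSignal, hypnogram: Hypnogram,
                   state: VigilanceState | str = VigilanceState.NREM,
                   min_len: float = 8.0) -> list:
    """Contiguous sub-signals of the given state, at least `min_len` s long."""
    state = VigilanceState(state)
    out = []
    for s, e in hypnogram.intervals_of(state):
        s, e = max(s, signal.t0), min(e, signal.t0 + signal.duration)
        if e - s >= min_len:
            out.append(signal.slice(s, e))
    return out


def _default_bands(rng: tuple[float, float], width: float, step: float) -> list:
    lo, hi = rng
    out = []
    b = lo
    while b + width <= hi + 1e-9:
        out.append((round(b, 6), round(b + width, 6)))
        b += step
    return out


def _decimate_for_pac(seg: ContinuousSignal, amp_hi: float) -> ContinuousSignal:
    """Downsample so pac filtering is cheap; keeps ≥ 10× the top amp frequency."""
    target = max(10.0 * amp_hi, 50.0)
    q = int(seg.fs // target)
    if q <= 1:
        return seg
    y = sps.decimate(seg.samples, q, ftype="fir", zero_phase=True)
    return ContinuousSignal(y, seg.fs / q, seg.region, seg.label, seg.t0)


def comodulogram(signal: ContinuousSignal, hypnogram: Hypnogram | None = None,
                 phase_range: tuple[float, float] = (0.5, 4.0),
                 amp_range: tuple[float, float] = (8.0, 20.0),
                 phase_width: float = 0.5, phase_step: float = 0.5,
                 amp_width: float = 2.0, amp_step: float = 1.0,
                 n_bins: int = 18, state: VigilanceState | str = VigilanceState.NREM,
                 ) -> Comodulogram:
    """MI over a grid of (phase band, amplitude band) cells.

    When a hypnogram is given the computation is restricted to concatenated
    segments (≥ 8 s) of the requested state; one cycle of the phase band's low
    edge is trimmed from each segment end so concatenation boundaries do not
    contaminate the analytic-signal estimates.  The signal is internally
    downsampled (anti-aliased) to ≥ 10× the top amplitude frequency.
    """
    phase_bands = _default_bands(phase_range, phase_width, phase_step)
    amp_bands = _default_bands(amp_range, amp_width, amp_step)
    if not phase_bands or not amp_bands:
        raise ValueError("empty band grid")
    if hypnogram is not None:
        segs = state_segments(signal, hypnogram, state)
        if not segs:
            raise ValueError(f"no {VigilanceState(state).value} segments ≥ 8 s")
    else:
        segs = [signal]
    segs = [_decimate_for_pac(s, amp_range[1]) for s in segs]

    # amplitude envelopes depend only on the amp band: compute once per segment
    amp_env = [[np.abs(sps.hilbert(bandpass_zscore(seg, ab).z)) for ab in amp_bands]
               for seg in segs]
    mi = np.zeros((len(phase_bands), len(amp_bands)))
    for i, pb in enumerate(phase_bands):
        trim = 1.0 / pb[0]
        phases, amps_by_band = [], {j: [] for j in range(len(amp_bands))}
        for si, seg in enumerate(segs):
            k = int(trim * seg.fs)
            if seg.samples.size <= 2 * k + 8:
                continue
            zp = bandpass_zscore(seg, pb)
            phases.append(np.angle(sps.hilbert(zp.z))[k:-k])
            for j in range(len(amp_bands)):
                amps_by_band[j].append(amp_env[si][j][k:-k])
        if not phases:
            raise ValueError(f"segments too short for phase band {pb}")
        ph_all = np.concatenate(phases)
        for j in range(len(amp_bands)):
            am_all = np.concatenate(amps_by_band[j])
            mi[i, j] = modulation_index(None, None, n_bins, phase=ph_all, amplitude=am_all)
    return Comodulogram(phase_bands=phase_bands, amp_bands=amp_bands, mi=mi)


def pac_change(pre: Comodulogram, post: Comodulogram,
               phase_win: tuple[float, float] = (0.5, 1.5),
               amp_win: tuple[float, float] = (10.0, 16.0)) -> float:
    """Max-over-window MI(post) − max-over-window MI(pre)."""
    if pre.phase_bands != post.phase_bands or pre.amp_bands != post.amp_bands:
        raise ValueError("pre and post comodulograms must share the same grid")
    return post.max_in_window(phase_win, amp_win) - pre.max_in_window(phase_win, amp_win)


def pac_session(signal: ContinuousSignal, hypnogram: Hypnogram,
                manifest: SessionManifest, **kwargs) -> dict:
    """Pre/post comodulograms on the manifest windows and their MI change."""
    pre_sig = signal.slice(*manifest.baseline_window)
    post_sig = signal.slice(*manifest.post_window)
    pre = comodulogram(pre_sig, hypnogram, **kwargs)
    post = comodulogram(post_sig, hypnogram, **kwargs)
    return {
        "pre": pre, "post": post,
        "mi_pre": pre.max_in_window((0.5, 1.5), (10.0, 16.0)),
        "mi_post": post.max_in_window((0.5, 1.5), (10.0, 16.0)),
        "change": pac_change(pre, post),
    }
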