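"""Single-unit firing metrics, event-locked modulation and pairwise correlation.

Conventions follow common practice in rodent sleep electrophysiology:
putative pyramidal cells have broad waveforms (spike width > 200 µs) and low
mean rates (< 5 Hz); the bursting index is the fraction of inter-spike
intervals below 20 ms; peri-event time histograms (PETHs) are z-scored
across their own bins; cross-correlograms use 2 ms bins over ±500 ms and are
likewise z-scored across lag bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dataio import Hypnogram, Region, SpikeTrain, VigilanceState

__all__ = [
    "UnitClass",
    "AnalysisPurpose",
    "PETH",
    "CrossCorrelogram",
    "classify_unit",
    "include_unit",
    "bursting_index",
    "peth",
    "peth_stat",
    "cross_correlogram",
    "xcorr_stat",
]


class UnitClass(str, Enum):
    PYRAMIDAL = "pyramidal"
    OTHER = "other"


class AnalysisPurpose(str, Enum):
    RATE_ANALYSIS = "rate_analysis"
    XCORR = "xcorr"


@dataclass
class PETH:
    """Event-aligned firing, one z-scored row per unit."""

    bin_centers: np.ndarray  # s relative to anchor
    z_rates: np.ndarray  # (n_units, n_bins), NaN rows for zero-variance units
    rates: np.ndarray  # raw Hz, same shape
    n_events: int
    window: tuple[float, float]
    bin_len: float
    unit_ids: list


@dataclass
class CrossCorrelogram:
    lags: np.ndarray  # bin centers, s; symmetric about 0
    z_counts: np.ndarray
    counts: np.ndarray
    bin_len: float
    pair: tuple[str, str]
    regions: tuple[Region, Region]


def classify_unit(spike_width: float, mean_fr: float) -> UnitClass:
    """Pyramidal iff spike width > 200 µs and mean firing rate < 5 Hz."""
    if spike_width <= 0 or mean_fr < 0:
        raise ValueError("spike_width must be > 0 and mean_fr ≥ 0")
    if spike_width > 200.0 and mean_fr < 5.0:
        return UnitClass.PYRAMIDAL
    return UnitClass.OTHER


def include_unit(train: SpikeTrain, purpose: AnalysisPurpose | str,
                 recording_duration: float | None = None,
                 windows: tuple | None = None,
                 min_rate: float = 0.15, min_spikes: int = 200) -> bool:
    """Inclusion rules for rate and correlation analyses.

    rate_analysis: mean rate over the whole recording must exceed `min_rate`
    Hz.  xcorr: the unit must fire more than `min_spikes` spikes in *each* of
    the given analysis windows (baseline and post).
    """
    purpose = AnalysisPurpose(purpose)
    if purpose == AnalysisPurpose.RATE_ANALYSIS:
        if recording_duration is None or recording_duration <= 0:
            raise ValueError("rate_analysis inclusion needs a positive recording_duration")
        return train.mean_fr(recording_duration) > min_rate
    if windows is None:
        raise ValueError("xcorr inclusion needs the analysis windows")
    return all(train.in_window(w).size > min_spikes for w in windows)


def bursting_index(train: SpikeTrain | np.ndarray) -> float:
    """Fraction of inter-spike intervals strictly below 20 ms.

    Undefined (NaN) for trains with fewer than two spikes.
    """
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size < 2:
        return float("nan")
    isi = np.diff(times)
    return float(np.mean(isi < 0.020))


# ---------------------------------------------------------------------------
# PETH


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.full_like(x, np.nan, dtype=float)
    ok = sd[:, 0] > 0
    out[ok] = (x[ok] - mu[ok]) / sd[ok]
    return out


def peth(trains, anchors, window: tuple[float, float] = (-0.5, 0.5),
         bin_len: float = 0.005) -> PETH:
    """Peri-event time histogram around anchor times.

    Per-bin rate = spike count pooled across anchors / (n_anchors × bin_len),
    then z-scored per unit across that unit's own bins.  Anchors are slow-wave
    troughs (±500 ms, 5 ms bins) or ripple envelope maxima (±250 ms, 2 ms
    bins) in the standard analyses.  Units with zero rate variance get a NaN
    z row (flagged, not dropped).
    """
    anchors = np.asarray(anchors, float)
    if anchors.size == 0:
        raise ValueError("at least one anchor is required")
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_len))
    edges = lo + np.arange(n_bins + 1) * bin_len
    rates = np.zeros((len(trains), n_bins))
    for i, tr in enumerate(trains):
        counts = np.zeros(n_bins)
        for a in anchors:
            rel = tr.times[(tr.times >= a + lo) & (tr.times < a + hi)] - a
            counts += np.histogram(rel, bins=edges)[0]
        rates[i] = counts / (anchors.size * bin_len)
    centers = (edges[:-1] + edges[1:]) / 2
    return PETH(bin_centers=centers, z_rates=_zscore_rows(rates), rates=rates,
                n_events=anchors.size, window=(lo, hi), bin_len=bin_len,
                unit_ids=[tr.unit_id for tr in trains])


def peth_stat(p: PETH, stat_window: tuple[float, float]) -> np.ndarray:
    """Per-unit mean z over the bins whose centers fall in the closed window."""
    lo, hi = stat_window
    if lo < p.window[0] - 1e-9 or hi > p.window[1] + 1e-9:
        raise ValueError("stat_window must lie inside the PETH window")
    m = (p.bin_centers >= lo) & (p.bin_centers <= hi)
    if not m.any():
        raise ValueError("stat_window selects no bins")
    return p.z_rates[:, m].mean(axis=1)


# ---------------------------------------------------------------------------
# cross-correlograms


def _restrict_to_state(times: np.ndarray, hypnogram: Hypnogram,
                       state: VigilanceState) -> np.ndarray:
    keep = np.array([hypnogram.state_at(t) == state for t in times])
    return times[keep]


def cross_correlogram(train_a: SpikeTrain, train_b: SpikeTrain,
                      window: float = 0.5, bin_len: float = 0.002,
                      hypnogram: Hypnogram | None = None,
                      restrict: VigilanceState | str | None = None) -> CrossCorrelogram:
    """Counts of (b − a) spike-time differences per lag bin, z-scored.

    With a state restriction, a spike-time difference contributes only if
    both spikes fall in epochs of the chosen state.  The lag grid is symmetric
    about zero; for identical trains the zero-lag self-pairs are excluded.
    """
    ta, tb = train_a.times, train_b.times
    if restrict is not None:
        restrict = VigilanceState(restrict)
        if hypnogram is None:
            raise ValueError("state restriction requires a hypnogram")
        ta = _restrict_to_state(ta, hypnogram, restrict)
        tb = _restrict_to_state(tb, hypnogram, restrict)
    if ta.size == 0 or tb.size == 0:
        raise ValueError(
            f"pair ({train_a.unit_id}, {train_b.unit_id}): empty train after restriction")
    n_bins = 2 * int(round(window / bin_len))
    edges = -window + np.arange(n_bins + 1) * bin_len
    counts = np.zeros(n_bins)
    auto = train_a.unit_id == train_b.unit_id
    lo_idx = np.searchsorted(tb, ta - window, side="left")
    hi_idx = np.searchsorted(tb, ta + window, side="right")
    for t, i0, i1 in zip(ta, lo_idx, hi_idx):
        d = tb[i0:i1] - t
        if auto:
            d = d[d != 0.0]
        counts += np.histogram(d, bins=edges)[0]
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts)
    centers = (edges[:-1] + edges[1:]) / 2
    return CrossCorrelogram(lags=centers, z_counts=z, counts=counts, bin_len=bin_len,
                            pair=(train_a.unit_id, train_b.unit_id),
                            regions=(train_a.region, train_b.region))


def xcorr_stat(xc: CrossCorrelogram, pair_kind: str | None = None) -> float:
    """Mean z around the correlogram peak window.

    within_region: ±100 ms; prl_to_ca1: 0 to +200 ms.  If `pair_kind` is not
    given it is inferred from the stored region pair.
    """
    if pair_kind is None:
        pair_kind = ("within_region" if xc.regions[0] == xc.regions[1] else "prl_to_ca1")
    if pair_kind == "within_region":
        lo, hi = -0.1, 0.1
    elif pair_kind == "prl_to_ca1":
        lo, hi = 0.0, 0.2
    else:
        raise ValueError(f"unknown pair_kind {pair_kind!r}")
    m = (xc.lags >= lo) & (xc.lags <= hi)
    if not m.any():
        raise ValueError("lag grid does not cover the stat window")
    return float(xc.z_counts[m].mean())
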