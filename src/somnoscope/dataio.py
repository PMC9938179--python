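"""Core data model and file I/O.

Time convention used throughout the package: seconds, zero-based from the
start of the recording, with half-open intervals ``[start, end)``.  Signals
are stored in microvolts.  Event tables, hypnograms and spike lists travel
as plain CSV with fixed schemas so every number is auditable with a text
editor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Region",
    "VigilanceState",
    "EventKind",
    "ContinuousSignal",
    "Hypnogram",
    "SpikeTrain",
    "OscillationEvent",
    "SessionManifest",
    "BandConfig",
    "DetectionConfig",
    "read_continuous",
    "write_continuous",
    "read_hypnogram",
    "write_hypnogram",
    "read_events",
    "write_events",
    "read_spike_trains",
    "write_spike_trains",
    "load_detection_config",
    "save_detection_config",
    "EVENT_COLUMNS",
]


class Region(str, Enum):
    """Recording site."""

    PRL = "PrL"
    CA1 = "CA1"
    EMG = "EMG"
    OTHER = "other"


class VigilanceState(str, Enum):
    WAKE = "wake"
    NREM = "NREM"
    REM = "REM"
    ARTIFACT = "artifact"
    UNSCORED = "unscored"


class EventKind(str, Enum):
    SLOW_WAVE = "slow_wave"
    SPINDLE = "spindle"
    RIPPLE = "ripple"


@dataclass
class ContinuousSignal:
    """A uniformly sampled continuous signal in microvolts.

    Parameters
    ----------
    samples : ndarray
        Signal values in µV.  Non-finite samples mark flagged gaps.
    fs : float
        Sampling rate in Hz, > 0.
    region : Region
        Recording site tag.
    label : str
        Free-text channel label.
    t0 : float
        Offset of the first sample from recording start, in seconds.
    """

    samples: np.ndarray
    fs: float
    region: Region = Region.OTHER
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        self.region = Region(self.region)

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, start: float, end: float) -> "ContinuousSignal":
        """Return the sub-signal covering the half-open window [start, end) s."""
        i0 = int(np.ceil((start - self.t0) * self.fs))
        i1 = int(np.ceil((end - self.t0) * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.samples.size)
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end}) for signal of duration {self.duration}")
        return ContinuousSignal(
            self.samples[i0:i1], self.fs, self.region, self.label, self.t0 + i0 / self.fs
        )


@dataclass
class Hypnogram:
    """Epoch-wise vigilance-state labels (default 4 s epochs)."""

    labels: list
    epoch_len: float = 4.0

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be > 0")
        if len(self.labels) == 0:
            raise ValueError("hypnogram must have at least one epoch")
        self.labels = [VigilanceState(l) for l in self.labels]

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    def state_at(self, t: float) -> VigilanceState:
        """State of the epoch containing time t (s); 'unscored' outside coverage."""
        if t < 0 or t >= self.duration:
            return VigilanceState.UNSCORED
        return self.labels[int(t // self.epoch_len)]

    def epochs_of(self, state: VigilanceState) -> np.ndarray:
        """Indices of epochs with the given label."""
        return np.flatnonzero(np.array([l == state for l in self.labels]))

    def intervals_of(self, state: VigilanceState) -> list[tuple[float, float]]:
        """Merged half-open [start, end) intervals (s) of the given state."""
        idx = self.epochs_of(state)
        out: list[tuple[float, float]] = []
        for i in idx:
            s, e = i * self.epoch_len, (i + 1) * self.epoch_len
            if out and abs(out[-1][1] - s) < 1e-9:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
        return out

    def fraction(self, state: VigilanceState) -> float:
        return len(self.epochs_of(state)) / self.n_epochs

    def restrict(self, window: tuple[float, float]) -> "Hypnogram":
        """Epochs wholly inside the half-open window [start, end) s."""
        i0 = int(np.ceil(window[0] / self.epoch_len - 1e-9))
        i1 = int(np.floor(window[1] / self.epoch_len + 1e-9))
        if i1 <= i0:
            raise ValueError("window contains no whole epoch")
        return Hypnogram(self.labels[i0:i1], self.epoch_len)


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit.

    isolation_distance is carried as metadata only (spike sorting itself is
    out of scope here).
    """

    unit_id: str
    region: Region
    times: np.ndarray
    spike_width: float  # µs
    isolation_distance: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.region = Region(self.region)
        if self.spike_width <= 0:
            raise ValueError("spike_width must be > 0 µs")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"spike times of unit {self.unit_id} are not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def mean_fr(self, duration: float) -> float:
        """Mean firing rate (Hz) over a recording of the given duration (s)."""
        if duration <= 0:
            raise ValueError("duration must be > 0")
        return self.n_spikes / duration

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        """Spike times within the half-open window [start, end)."""
        lo, hi = window
        return self.times[(self.times >= lo) & (self.times < hi)]


@dataclass
class OscillationEvent:
    """One detected (or injected ground-truth) oscillatory event.

    peak_time is the negative trough for slow-waves and the envelope maximum
    for spindles/ripples.  intrinsic_freq is 1/duration for slow-waves and the
    within-event cycle rate for spindles/ripples.
    """

    kind: EventKind
    start: float
    end: float
    peak_time: float
    amplitude: float
    intrinsic_freq: float
    state: VigilanceState | None = None
    flags: str = ""

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        if self.state is not None:
            self.state = VigilanceState(self.state)
        if not self.start < self.end:
            raise ValueError(f"event start {self.start} must be < end {self.end}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SessionManifest:
    """Condition and timing metadata for one recording session."""

    subject: str
    condition: str = "saline"
    injection_time: float = 1800.0
    baseline_window: tuple[float, float] | None = None
    post_window: tuple[float, float] | None = None

    CONDITIONS = ("saline", "zolpidem", "diazepam", "THIP", "custom")

    def __post_init__(self) -> None:
        if self.condition not in self.CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; allowed: {self.CONDITIONS}")
        if self.baseline_window is None:
            # 5–25 min pre-injection
            self.baseline_window = (self.injection_time - 1500.0, self.injection_time - 300.0)
        if self.post_window is None:
            # 40–60 min post-injection
            self.post_window = (self.injection_time + 2400.0, self.injection_time + 3600.0)
        self.baseline_window = (float(self.baseline_window[0]), float(self.baseline_window[1]))
        self.post_window = (float(self.post_window[0]), float(self.post_window[1]))
        b, p = self.baseline_window, self.post_window
        if not (b[0] < b[1] and p[0] < p[1]):
            raise ValueError("analysis windows must have positive length")
        if b[1] > p[0]:
            raise ValueError("baseline and post windows must not overlap")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            subject=str(d["subject"]),
            condition=d.get("condition", "saline"),
            injection_time=float(d.get("injection_time", 1800.0)),
            baseline_window=tuple(d["baseline_window"]) if "baseline_window" in d else None,
            post_window=tuple(d["post_window"]) if "post_window" in d else None,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "subject": self.subject,
            "condition": self.condition,
            "injection_time": self.injection_time,
            "baseline_window": list(self.baseline_window),
            "post_window": list(self.post_window),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class BandConfig:
    """Detection settings for one event kind."""

    band: tuple[float, float]
    detect_thresh: float  # SD units
    edge_thresh: float  # SD units
    min_dur: float  # s
    max_dur: float  # s
    merge_gap: float  # s
    min_negativity: float | None = None  # µV, slow-waves only

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.edge_thresh > self.detect_thresh:
            raise ValueError("edge_thresh must be ≤ detect_thresh")
        if not self.min_dur < self.max_dur:
            raise ValueError("min_dur must be < max_dur")


def _default_bands() -> dict:
    return {
        # Slow-waves: delimited by zero-crossings of the 0.5–4 Hz trace, not by
        # envelope crossings, so edge_thresh/merge_gap are unused; the 50 µV
        # negativity floor is the distinctive rule.
        EventKind.SLOW_WAVE: BandConfig(
            band=(0.5, 4.0), detect_thresh=3.5, edge_thresh=3.5,
            min_dur=0.25, max_dur=2.0, merge_gap=0.0, min_negativity=50.0,
        ),
        EventKind.SPINDLE: BandConfig(
            band=(8.0, 16.0), detect_thresh=3.5, edge_thresh=1.5,
            min_dur=0.35, max_dur=4.0, merge_gap=0.5,
        ),
        EventKind.RIPPLE: BandConfig(
            band=(125.0, 220.0), detect_thresh=3.5, edge_thresh=2.0,
            min_dur=0.05, max_dur=0.5, merge_gap=0.05,
        ),
    }


@dataclass
class DetectionConfig:
    """Per-kind detection settings; defaults carry the standard thresholds."""

    bands: dict = field(default_factory=_default_bands)

    def __getitem__(self, kind: EventKind | str) -> BandConfig:
        return self.bands[EventKind(kind)]


def load_detection_config(path: str | Path) -> DetectionConfig:
    """Load a YAML detection config; keys absent from the file keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = DetectionConfig()
    for kind_name, d in raw.items():
        kind = EventKind(kind_name)
        base = dataclasses.asdict(cfg.bands[kind])
        base.update(d)
        base["band"] = tuple(base["band"])
        cfg.bands[kind] = BandConfig(**base)
    return cfg


def save_detection_config(cfg: DetectionConfig, path: str | Path) -> None:
    out = {}
    for kind, bc in cfg.bands.items():
        d = dataclasses.asdict(bc)
        d["band"] = list(d["band"])
        if d["min_negativity"] is None:
            del d["min_negativity"]
        out[kind.value] = d
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh)


# ---------------------------------------------------------------------------
# Continuous-signal I/O


def read_continuous(path: str | Path, format: str | None = None, *,
                    fs: float | None = None, region: str = "other",
                    unit: str | None = None) -> ContinuousSignal:
    """Read a continuous signal from EDF, CSV or .npy.

    CSV files must either carry a ``# fs=<Hz>`` header comment or be given an
    explicit ``fs``.  Samples are returned in µV: a declared unit of "mV" is
    scaled by 1000, "uV"/"µV" passes through, anything else is a hard error.

    EDF reading delegates to :mod:`mne` (optional dependency); the channel
    units declared in the EDF header are honoured.
    """
    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".csv": "csv", ".npy": "npy"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")

    scale = _unit_scale(unit) if unit is not None else 1.0

    if format == "edf":
        return _read_edf(path, region)
    if format == "npy":
        if fs is None:
            raise ValueError("fs is required for npy input (no header to carry it)")
        return ContinuousSignal(np.load(path) * scale, fs, region=region, label=path.stem)
    if format == "csv":
        header_fs, header_unit = _csv_sidecar(path)
        fs = fs if fs is not None else header_fs
        if fs is None:
            raise ValueError(f"{path}: sampling rate missing (no '# fs=' header and no fs argument)")
        if unit is None and header_unit is not None:
            scale = _unit_scale(header_unit)
        samples = pd.read_csv(path, comment="#", header=None).iloc[:, 0].to_numpy(float)
        return ContinuousSignal(samples * scale, fs, region=region, label=path.stem)
    raise ValueError(f"unknown format {format!r}")


def _unit_scale(unit: str) -> float:
    u = unit.strip().lower().replace("µ", "u")
    if u in ("uv", "microvolt", "microvolts"):
        return 1.0
    if u in ("mv", "millivolt", "millivolts"):
        return 1000.0
    raise ValueError(f"unsupported physical unit {unit!r}: supply µV or mV")


def _csv_sidecar(path: Path) -> tuple[float | None, str | None]:
    fs = unit = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("unit="):
                unit = body[5:]
    return fs, unit


def _read_edf(path: Path, region: str) -> ContinuousSignal:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne; install somnoscope[edf]") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # mne returns volts
    return ContinuousSignal(data, raw.info["sfreq"], region=region, label=raw.ch_names[0])


def write_continuous(signal: ContinuousSignal, path: str | Path) -> None:
    """Write a signal as CSV with a ``# fs=`` / ``# unit=uV`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={signal.fs}\n# unit=uV\n# region={signal.region.value}\n")
        np.savetxt(fh, signal.samples, fmt="%.6f")


# ---------------------------------------------------------------------------
# Hypnogram / event / spike-train tables

EVENT_COLUMNS = ["kind", "start", "end", "peak_time", "amplitude",
                 "intrinsic_freq", "duration", "state"]


def read_hypnogram(path: str | Path, epoch_len: float = 4.0) -> Hypnogram:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: hypnogram CSV needs a 'label' column")
    labels = []
    for i, lab in enumerate(df["label"].astype(str)):
        try:
            labels.append(VigilanceState(lab))
        except ValueError:
            raise ValueError(f"{path}: unknown vigilance label {lab!r} at epoch {i}") from None
    if "epoch_len" in df.columns:
        epoch_len = float(df["epoch_len"].iloc[0])
    return Hypnogram(labels, epoch_len)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "label": [l.value for l in hyp.labels],
        "epoch_len": hyp.epoch_len,
    }).to_csv(path, index=False)


def events_to_frame(events: Iterable[OscillationEvent]) -> pd.DataFrame:
    rows = [{
        "kind": e.kind.value,
        "start": e.start, "end": e.end, "peak_time": e.peak_time,
        "amplitude": e.amplitude, "intrinsic_freq": e.intrinsic_freq,
        "duration": e.duration,
        "state": e.state.value if e.state is not None else "",
    } for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: Iterable[OscillationEvent], path: str | Path) -> None:
    """Write events as CSV with the fixed schema; times with 6 decimals."""
    df = events_to_frame(events)
    df.to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> list[OscillationEvent]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(OscillationEvent(
            kind=EventKind(r["kind"]), start=float(r["start"]), end=float(r["end"]),
            peak_time=float(r["peak_time"]), amplitude=float(r["amplitude"]),
            intrinsic_freq=float(r["intrinsic_freq"]),
            state=VigilanceState(r["state"]) if r["state"] else None,
        ))
    return out


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append((tr.unit_id, tr.region.value, tr.spike_width, t))
    pd.DataFrame(rows, columns=["unit_id", "region", "spike_width_us", "time_s"]) \
        .to_csv(path, index=False, float_format="%.6f")


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    out = []
    for uid, g in df.groupby("unit_id", sort=False):
        out.append(SpikeTrain(
            unit_id=str(uid), region=Region(g["region"].iloc[0]),
            times=np.sort(g["time_s"].to_numpy(float)),
            spike_width=float(g["spike_width_us"].iloc[0]),
        ))
    return out
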