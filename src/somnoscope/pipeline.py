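"""Session-level orchestration: detect → window → quantify → compare.

Detection is run independently on the baseline and post analysis windows so
that the z-score scaling of each window reflects only that window — the
convention that makes pre/post amplitude changes meaningful when a drug also
changes the background variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import (
    ContinuousSignal,
    DetectionConfig,
    EventKind,
    Hypnogram,
    SessionManifest,
)
from .events import attribute_state, detect_events
from .grouping import change_records, window_state_amounts, windowed_event_metrics
from .spectral import pac_session, welch_power

__all__ = ["detect_windowed", "analyze_session"]

# which channel carries which event kind
KIND_CHANNEL = {EventKind.SLOW_WAVE: "prl", EventKind.SPINDLE: "prl",
                EventKind.RIPPLE: "ca1"}


def detect_windowed(prl: ContinuousSignal, ca1: ContinuousSignal,
                    manifest: SessionManifest, cfg: DetectionConfig | None = None,
                    hypnogram: Hypnogram | None = None) -> list:
    """Detect all three event kinds separately on each analysis window.

    Slow-waves and spindles come from the PrL channel, ripples from CA1.
    Events are state-tagged when a hypnogram is given.
    """
    cfg = cfg if cfg is not None else DetectionConfig()
    chans = {"prl": prl, "ca1": ca1}
    events = []
    for win in (manifest.baseline_window, manifest.post_window):
        for kind, chan in KIND_CHANNEL.items():
            sig = chans[chan].slice(*win)
            events.extend(detect_events(sig, kind, cfg))
    events.sort(key=lambda e: e.start)
    if hypnogram is not None:
        attribute_state(events, hypnogram)
    return events


def analyze_session(prl: ContinuousSignal, ca1: ContinuousSignal,
                    hypnogram: Hypnogram, manifest: SessionManifest,
                    cfg: DetectionConfig | None = None,
                    compute_pac: bool = False,
                    change_mode: str = "percent") -> dict:
    """Full per-session LFP analysis.

    Returns a dict with the detected ``events``, per-window event ``metrics``,
    ``changes`` (post vs baseline ChangeRecords), ``state_amounts``, per-window
    power ``spectra`` (% of baseline), and — when `compute_pac` — the PAC
    summary of the PrL channel.
    """
    events = detect_windowed(prl, ca1, manifest, cfg, hypnogram)
    metrics = windowed_event_metrics(events, manifest)
    changes = change_records(metrics, manifest.subject, manifest.condition,
                             mode=change_mode)
    out = {
        "events": events,
        "metrics": metrics,
        "changes": changes,
        "state_amounts": window_state_amounts(hypnogram, manifest),
    }
    spectra = {}
    for name, win in (("baseline", manifest.baseline_window),
                      ("post", manifest.post_window)):
        spectra[name] = {ch: welch_power(sig.slice(*win))
                         for ch, sig in (("prl", prl), ("ca1", ca1))}
    pct = {}
    for ch in ("prl", "ca1"):
        base, post = spectra["baseline"][ch], spectra["post"][ch]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct[ch] = pd.DataFrame({
                "freq": base.freqs,
                "percent_of_baseline": np.where(base.power > 0,
                                                post.power / base.power * 100.0, np.nan),
            })
    out["spectra"] = spectra
    out["spectra_percent"] = pct
    if compute_pac:
        out["pac"] = pac_session(prl, hypnogram, manifest)
    return out


def percent_change(changes: list, metric: str) -> float:
    """Convenience: the change value of a named metric from a ChangeRecord list."""
    for c in changes:
        if c.metric == metric:
            return c.change
    raise KeyError(f"metric {metric!r} not found")
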