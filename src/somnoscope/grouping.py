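"""Vigilance scoring, baseline/post windowing, change metrics and group statistics.

The statistical decision tree mirrors standard practice for small-n
pharmacology designs: every group is checked for normality (Shapiro–Wilk)
and the set for homogeneity of variance (Bartlett); if both pass, a one-way
ANOVA with Bonferroni-corrected pairwise comparisons against the control
group is used, otherwise a Kruskal–Wallis omnibus with Dunn's rank post-hoc
under Šidák adjustment.  Phase-amplitude-coupling changes are handled
separately with one-sample t-tests against zero and Welch two-sample
t-tests against control, because their variances are typically unequal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .dataio import (
    ContinuousSignal,
    EventKind,
    Hypnogram,
    OscillationEvent,
    SessionManifest,
    VigilanceState,
)

__all__ = [
    "ChangeRecord",
    "GroupComparison",
    "score_vigilance",
    "sleep_onset_latency",
    "windowed_event_metrics",
    "window_state_amounts",
    "change_records",
    "compare_groups",
    "pac_compare",
    "per_bin_spectral_comparison",
    "dunn_sidak",
]

THETA_BAND = (5.0, 10.0)
SWA_BAND = (0.5, 4.0)


# ---------------------------------------------------------------------------
# rule-based vigilance scoring


def score_vigilance(lfp: ContinuousSignal, emg: ContinuousSignal,
                    epoch_len: float = 4.0, clip_uv: float = 5000.0,
                    movement: np.ndarray | None = None) -> Hypnogram:
    """Rule-based 4 s-epoch scoring from LFP and EMG.

    Per epoch, the theta (5–10 Hz) to SWA (0.5–4 Hz) power ratio and the EMG
    RMS are computed.  Epochs where SWA dominates theta (log ratio ≤ 0) are
    NREM; theta-dominated epochs are wake when the EMG is high and REM when
    it is low.  The SWA/theta boundary is a fixed power-dominance criterion —
    being a ratio of powers from the same channel it is scale-free and needs
    no per-recording fitting (data-driven splits such as Otsu's rule fail
    when one state vastly outnumbers the others, splitting the majority
    cluster instead of the states).  The wake/REM EMG boundary sits at half
    the median EMG of the NREM epochs (EMG is intermediate in NREM, high in
    wake, very low in REM).  Epochs containing clipped samples
    (|x| ≥ `clip_uv`) are artifacts.  An optional per-epoch movement trace
    marks additional artifact epochs where it is non-zero.
    """
    if abs(lfp.duration - emg.duration) > epoch_len:
        raise ValueError("LFP and EMG must cover the same span")
    fs = lfp.fs
    n_ep = int(lfp.duration // epoch_len)
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    seg = int(round(epoch_len * fs))
    seg_e = int(round(epoch_len * emg.fs))
    ratio = np.empty(n_ep)
    emg_rms = np.empty(n_ep)
    artifact = np.zeros(n_ep, dtype=bool)
    for i in range(n_ep):
        x = lfp.samples[i * seg:(i + 1) * seg]
        if np.any(np.abs(x) >= clip_uv) or not np.all(np.isfinite(x)):
            artifact[i] = True
            ratio[i] = np.nan
        else:
            f, p = sps.periodogram(x, fs=fs, window="hamming", detrend=False)
            th = np.mean(p[(f >= THETA_BAND[0]) & (f <= THETA_BAND[1])])
            sw = np.mean(p[(f >= SWA_BAND[0]) & (f <= SWA_BAND[1])])
            ratio[i] = th / max(sw, 1e-12)
        e = emg.samples[i * seg_e:(i + 1) * seg_e]
        emg_rms[i] = np.sqrt(np.mean(e**2)) if e.size else 0.0
    if movement is not None:
        artifact |= np.asarray(movement, float)[:n_ep] > 0

    ok = ~artifact
    logr = np.log(np.maximum(ratio[ok], 1e-12))
    labels = np.array([VigilanceState.ARTIFACT] * n_ep, dtype=object)
    if logr.size == 0:
        return Hypnogram(list(labels), epoch_len)
    lo_m = logr <= 0.0  # SWA-dominated epochs are NREM
    idx_ok = np.flatnonzero(ok)
    nrem_idx = idx_ok[lo_m]
    high_idx = idx_ok[~lo_m]
    labels[nrem_idx] = VigilanceState.NREM
    if high_idx.size:
        ref = np.median(emg_rms[nrem_idx]) if nrem_idx.size else np.median(emg_rms[ok])
        rem = emg_rms[high_idx] < 0.5 * ref
        labels[high_idx[rem]] = VigilanceState.REM
        labels[high_idx[~rem]] = VigilanceState.WAKE
    return Hypnogram(list(labels), epoch_len)


def sleep_onset_latency(hypnogram: Hypnogram) -> float | None:
    """Start time (s) of the first NREM epoch; None if no NREM was scored."""
    idx = hypnogram.epochs_of(VigilanceState.NREM)
    if idx.size == 0:
        return None
    return float(idx[0] * hypnogram.epoch_len)


# ---------------------------------------------------------------------------
# windowed metrics and change records


def windowed_event_metrics(events: list, manifest: SessionManifest) -> pd.DataFrame:
    """Per-window event density and mean features, separately per event kind.

    Density is events/min of window; a window with zero events of a kind gets
    density 0 with NaN feature means (flagged missing, never zero).
    """
    rows = []
    for win_name, win in (("baseline", manifest.baseline_window),
                          ("post", manifest.post_window)):
        minutes = (win[1] - win[0]) / 60.0
        for kind in EventKind:
            sel = [e for e in events
                   if e.kind == kind and win[0] <= e.peak_time < win[1]]
            row = {"window": win_name, "kind": kind.value,
                   "n": len(sel), "density_per_min": len(sel) / minutes}
            for feat in ("amplitude", "intrinsic_freq", "duration"):
                row[feat] = (float(np.mean([getattr(e, feat) for e in sel]))
                             if sel else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def window_state_amounts(hypnogram: Hypnogram, manifest: SessionManifest) -> pd.DataFrame:
    """Minutes of each vigilance state within the baseline and post windows."""
    rows = []
    for win_name, win in (("baseline", manifest.baseline_window),
                          ("post", manifest.post_window)):
        h = hypnogram.restrict(win)
        for st in (VigilanceState.WAKE, VigilanceState.NREM, VigilanceState.REM):
            rows.append({"window": win_name, "state": st.value,
                         "minutes": h.fraction(st) * h.duration / 60.0})
    return pd.DataFrame(rows)


@dataclass
class ChangeRecord:
    """Post-vs-baseline change of one metric for one subject."""

    subject: str
    condition: str
    metric: str
    baseline: float
    post: float
    mode: str = "difference"  # or "percent"

    @property
    def change(self) -> float:
        if self.mode == "difference":
            return self.post - self.baseline
        if self.mode == "percent":
            if self.baseline == 0:
                return float("nan")
            return (self.post - self.baseline) / self.baseline * 100.0
        raise ValueError(f"unknown change mode {self.mode!r}")


def change_records(metrics: pd.DataFrame, subject: str, condition: str,
                   mode: str = "percent") -> list:
    """ChangeRecords for every (kind, feature) pair in a windowed-metrics table."""
    out = []
    base = metrics[metrics["window"] == "baseline"].set_index("kind")
    post = metrics[metrics["window"] == "post"].set_index("kind")
    for kind in base.index:
        for feat in ("density_per_min", "amplitude", "intrinsic_freq", "duration"):
            out.append(ChangeRecord(
                subject=subject, condition=condition, metric=f"{kind}_{feat}",
                baseline=float(base.loc[kind, feat]), post=float(post.loc[kind, feat]),
                mode=mode))
    return out


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class GroupComparison:
    test_used: str  # anova_bonferroni | kruskal_dunn | welch_t | one_sample_t
    statistic: float
    df: float
    p: float
    posthoc: pd.DataFrame | None = None
    notes: str = ""


def _normal_and_homoscedastic(groups: dict, alpha: float = 0.05) -> bool:
    try:
        for vals in groups.values():
            if stats.shapiro(vals).pvalue <= alpha:
                return False
        if stats.bartlett(*groups.values()).pvalue <= alpha:
            return False
    except ValueError:
        return False  # constant groups etc. -> rank-based path
    return True


def dunn_sidak(groups: dict, control: str) -> pd.DataFrame:
    """Dunn's rank post-hoc of each group against `control`, Šidák-adjusted.

    z = (mean rank difference) / sqrt([N(N+1)/12 − ΣT/(12(N−1))](1/ni + 1/nj))
    with T = t³ − t over tie groups; two-sided normal p, family adjustment
    p_adj = 1 − (1 − p)^m for m comparisons.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    ranks = stats.rankdata(pooled)
    n_tot = pooled.size
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[i:i + k].mean()
        sizes[g] = k
        i += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    others = [g for g in names if g != control]
    m = len(others)
    rows = []
    for g in others:
        se = np.sqrt(var_base * (1.0 / sizes[g] + 1.0 / sizes[control]))
        z = (mean_ranks[g] - mean_ranks[control]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = 1.0 - (1.0 - p) ** m
        rows.append({"condition": g, "vs": control, "statistic": z,
                     "p": p, "p_adj": p_adj, "significant": p_adj < 0.05})
    return pd.DataFrame(rows)


def _bonferroni_pairwise(groups: dict, control: str) -> pd.DataFrame:
    others = [g for g in groups if g != control]
    m = len(others)
    rows = []
    for g in others:
        t, p = stats.ttest_ind(groups[g], groups[control], equal_var=True)
        p_adj = min(p * m, 1.0)
        rows.append({"condition": g, "vs": control, "statistic": float(t),
                     "p": float(p), "p_adj": p_adj, "significant": p_adj < 0.05})
    return pd.DataFrame(rows)


def compare_groups(groups: dict, control: str = "saline", alpha: float = 0.05,
                   posthoc_if_ns: bool = False) -> GroupComparison:
    """Omnibus + post-hoc comparison across conditions.

    If every group passes Shapiro–Wilk and the set passes Bartlett (α = 0.05),
    a one-way ANOVA with Bonferroni pairwise tests against `control` is run;
    otherwise Kruskal–Wallis with Dunn–Šidák.  The choice is a deterministic
    function of the data.
    """
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    for g, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"condition {g!r} has fewer than 3 values")
    if control not in groups:
        raise ValueError(f"control condition {control!r} absent from groups")
    groups = {g: np.asarray(v, float) for g, v in groups.items()}

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return GroupComparison(test_used="anova_bonferroni", statistic=0.0,
                               df=len(groups) - 1, p=1.0, posthoc=None,
                               notes="all values identical; omnibus trivially non-significant")

    if _normal_and_homoscedastic(groups, alpha):
        stat, p = stats.f_oneway(*groups.values())
        test = "anova_bonferroni"
        df = len(groups) - 1
        post = (_bonferroni_pairwise(groups, control)
                if (p < alpha or posthoc_if_ns) else None)
    else:
        stat, p = stats.kruskal(*groups.values())
        test = "kruskal_dunn"
        df = len(groups) - 1
        post = (dunn_sidak(groups, control)
                if (p < alpha or posthoc_if_ns) else None)
    return GroupComparison(test_used=test, statistic=float(stat), df=df,
                           p=float(p), posthoc=post)


def pac_compare(changes: dict, control: str = "saline") -> pd.DataFrame:
    """PAC-change statistics: one-sample t vs 0 and Welch t vs control.

    PAC changes use t-tests directly (not the omnibus tree) because their
    variances are typically unequal across conditions.
    """
    rows = []
    ctrl = np.asarray(changes[control], float)
    for cond, vals in changes.items():
        vals = np.asarray(vals, float)
        t1, p1 = stats.ttest_1samp(vals, 0.0)
        row = {"condition": cond, "mean_change": vals.mean(),
               "sem": vals.std(ddof=1) / np.sqrt(len(vals)),
               "t_vs_baseline": float(t1), "p_vs_baseline": float(p1)}
        if cond != control:
            t2, p2 = stats.ttest_ind(vals, ctrl, equal_var=False)
            row["t_vs_control"], row["p_vs_control"] = float(t2), float(p2)
        else:
            row["t_vs_control"], row["p_vs_control"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def per_bin_spectral_comparison(spectra: dict, freqs: np.ndarray,
                                control: str = "saline", alpha: float = 0.05,
                                bonferroni_bins: bool = True) -> pd.DataFrame:
    """Per-frequency-bin group comparison of %-of-baseline spectra.

    `spectra` maps condition → array (n_subjects, n_bins); the full decision
    tree is applied independently per bin.  Returns one row per (bin,
    condition-vs-control) with raw and across-bin Bonferroni-corrected
    significance; contiguous significant runs can be read off the table.
    """
    freqs = np.asarray(freqs, float)
    n_bins = freqs.size
    for cond, arr in spectra.items():
        if np.asarray(arr).shape[1] != n_bins:
            raise ValueError(f"condition {cond!r} spectra do not match the frequency grid")
    rows = []
    for b in range(n_bins):
        groups = {c: np.asarray(a, float)[:, b] for c, a in spectra.items()}
        cmp_res = compare_groups(groups, control=control, alpha=alpha, posthoc_if_ns=True)
        post = cmp_res.posthoc
        for cond in spectra:
            if cond == control:
                continue
            if post is not None:
                r = post[post["condition"] == cond].iloc[0]
                p_adj, sig = float(r["p_adj"]), bool(r["significant"]) and cmp_res.p < alpha
            else:
                p_adj, sig = 1.0, False
            rows.append({"freq": freqs[b], "condition": cond, "test": cmp_res.test_used,
                         "p_omnibus": cmp_res.p, "p_posthoc": p_adj,
                         "significant": sig,
                         "significant_bonf": sig and p_adj < alpha / n_bins})
    return pd.DataFrame(rows)
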