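import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somnoscope import (
    ContinuousSignal,
    EventKind,
    Hypnogram,
    OscillationEvent,
    SessionManifest,
    VigilanceState,
    change_records,
    compare_groups,
    dunn_sidak,
    pac_compare,
    per_bin_spectral_comparison,
    score_vigilance,
    sleep_onset_latency,
    windowed_event_metrics,
    window_state_amounts,
)
from somnoscope.grouping import ChangeRecord

FS = 250.0


def _piecewise_session(epoch_states, seed=0):
    """LFP/EMG built epoch by epoch with state-typical content."""
    rng = np.random.default_rng(seed)
    seg = int(4 * FS)
    t = np.arange(seg) / FS
    lfp, emg = [], []
    for st in epoch_states:
        if st == "NREM":
            lfp.append(100 * np.sin(2 * np.pi * 2.0 * t) + rng.normal(0, 10, seg))
            emg.append(rng.normal(0, 15, seg))
        elif st == "wake":
            lfp.append(50 * np.sin(2 * np.pi * 7.0 * t) + rng.normal(0, 10, seg))
            emg.append(rng.normal(0, 40, seg))
        elif st == "REM":
            lfp.append(50 * np.sin(2 * np.pi * 7.0 * t) + rng.normal(0, 10, seg))
            emg.append(rng.normal(0, 5, seg))
        else:  # artifact: clipped samples
            x = rng.normal(0, 10, seg)
            x[::50] = 6000.0
            lfp.append(x)
            emg.append(rng.normal(0, 15, seg))
    return (ContinuousSignal(np.concatenate(lfp), FS),
            ContinuousSignal(np.concatenate(emg), FS))


class TestScoreVigilance:
    def test_three_state_recording_scored_correctly(self):
        truth = (["wake"] * 8 + ["NREM"] * 20 + ["REM"] * 6 + ["NREM"] * 10
                 + ["wake"] * 6)
        lfp, emg = _piecewise_session(truth)
        hyp = score_vigilance(lfp, emg)
        agree = np.mean([a == b.value for a, b in zip(truth, hyp.labels)])
        assert agree == 1.0

    def test_pure_slow_recording_is_all_nrem(self):
        lfp, emg = _piecewise_session(["NREM"] * 20)
        hyp = score_vigilance(lfp, emg)
        assert all(l == VigilanceState.NREM for l in hyp.labels)

    def test_pure_theta_high_emg_recording_is_all_wake(self):
        lfp, emg = _piecewise_session(["wake"] * 20)
        hyp = score_vigilance(lfp, emg)
        assert all(l == VigilanceState.WAKE for l in hyp.labels)

    def test_clipped_epoch_is_artifact(self):
        truth = ["NREM"] * 10 + ["artifact"] + ["NREM"] * 9
        lfp, emg = _piecewise_session(truth)
        hyp = score_vigilance(lfp, emg)
        assert hyp.labels[10] == VigilanceState.ARTIFACT
        assert hyp.labels[9] == VigilanceState.NREM

    def test_movement_trace_marks_artifacts(self):
        lfp, emg = _piecewise_session(["NREM"] * 12)
        movement = np.zeros(12)
        movement[3] = 1.0
        hyp = score_vigilance(lfp, emg, movement=movement)
        assert hyp.labels[3] == VigilanceState.ARTIFACT

    def test_mismatched_durations_rejected(self):
        lfp, emg = _piecewise_session(["NREM"] * 10)
        short = ContinuousSignal(emg.samples[: int(8 * FS)], FS)
        with pytest.raises(ValueError):
            score_vigilance(lfp, short)

    def test_agreement_with_generator_hypnogram(self, default_session):
        s = default_session
        hyp = score_vigilance(s.prl_signal, s.emg)
        agree = np.mean([a == b for a, b in zip(hyp.labels, s.hypnogram.labels)])
        assert agree >= 0.85


class TestSleepOnset:
    def test_latency_is_first_nrem_epoch_start(self):
        hyp = Hypnogram(["wake"] * 5 + ["NREM"] * 3)
        assert sleep_onset_latency(hyp) == pytest.approx(20.0)

    def test_no_nrem_returns_none(self):
        assert sleep_onset_latency(Hypnogram(["wake", "REM"])) is None


class TestWindowedMetrics:
    def _manifest(self):
        return SessionManifest(subject="r1", injection_time=1800.0)

    def _events(self, times, kind=EventKind.SLOW_WAVE, amp=300.0):
        return [OscillationEvent(kind, t, t + 0.8, t + 0.5, amp, 1.25)
                for t in times]

    def test_density_per_minute(self):
        # 24 slow waves in the 20-min baseline window -> 1.2 per min
        man = self._manifest()
        evs = self._events(np.linspace(310, 1490, 24))
        df = windowed_event_metrics(evs, man)
        row = df[(df.window == "baseline") & (df.kind == "slow_wave")].iloc[0]
        assert row["n"] == 24
        assert row["density_per_min"] == pytest.approx(1.2)
        assert row["amplitude"] == pytest.approx(300.0)

    def test_empty_window_gives_zero_density_nan_features(self):
        man = self._manifest()
        df = windowed_event_metrics([], man)
        assert (df["density_per_min"] == 0.0).all()
        assert df["amplitude"].isna().all()

    def test_event_on_window_edge_uses_half_open_rule(self):
        man = self._manifest()
        evs = self._events([300.0, 1500.0])  # start edge in, end edge out
        df = windowed_event_metrics(evs, man)
        row = df[(df.window == "baseline") & (df.kind == "slow_wave")].iloc[0]
        assert row["n"] == 1

    def test_state_amounts_sum_to_window_length(self):
        man = self._manifest()
        hyp = Hypnogram(["NREM"] * 1500)  # covers 0..6000 s
        df = window_state_amounts(hyp, man)
        for win in ("baseline", "post"):
            assert df[df.window == win]["minutes"].sum() == pytest.approx(20.0)


class TestChangeRecords:
    def test_percent_change_arithmetic(self):
        r = ChangeRecord("r1", "zolpidem", "swa", baseline=200.0, post=250.0,
                         mode="percent")
        assert r.change == pytest.approx(25.0)

    def test_zero_baseline_percent_is_nan(self):
        r = ChangeRecord("r1", "saline", "density", 0.0, 3.0, mode="percent")
        assert np.isnan(r.change)

    def test_difference_mode(self):
        r = ChangeRecord("r1", "saline", "density", 1.5, 1.2, mode="difference")
        assert r.change == pytest.approx(-0.3)

    def test_records_cover_all_kind_feature_pairs(self):
        man = SessionManifest(subject="r1", injection_time=1800.0)
        df = windowed_event_metrics([], man)
        recs = change_records(df, "r1", "saline")
        assert len(recs) == 3 * 4
        assert {r.condition for r in recs} == {"saline"}


class TestCompareGroups:
    def _gaussian_groups(self, shift=0.0, seed=0, n=8):
        rng = np.random.default_rng(seed)
        return {
            "saline": rng.normal(0, 1, n),
            "zolpidem": rng.normal(shift, 1, n),
            "diazepam": rng.normal(0, 1, n),
            "thip": rng.normal(0, 1, n),
        }

    def test_identical_values_give_p_one(self):
        groups = {c: [2.0, 2.0, 2.0] for c in ("saline", "zolpidem", "thip")}
        res = compare_groups(groups)
        assert res.p == 1.0
        assert res.posthoc is None
        assert "identical" in res.notes

    def test_gaussian_data_uses_anova_path(self):
        res = compare_groups(self._gaussian_groups(shift=3.0, seed=4))
        assert res.test_used == "anova_bonferroni"
        assert res.p < 0.05
        row = res.posthoc.set_index("condition").loc["zolpidem"]
        assert row["significant"]
        assert not res.posthoc.set_index("condition").loc["diazepam"]["significant"]

    def test_outlier_contaminated_data_uses_rank_path(self):
        groups = self._gaussian_groups(shift=3.0, seed=2)
        groups["saline"][0] = 40.0  # gross outlier fails Shapiro-Wilk
        res = compare_groups(groups)
        assert res.test_used == "kruskal_dunn"

    def test_nonsignificant_omnibus_skips_posthoc_by_default(self):
        res = compare_groups(self._gaussian_groups(shift=0.0, seed=3))
        assert res.p > 0.05
        assert res.posthoc is None
        forced = compare_groups(self._gaussian_groups(shift=0.0, seed=3),
                                posthoc_if_ns=True)
        assert forced.posthoc is not None

    def test_small_group_named_in_error(self):
        groups = {"saline": [1.0, 2.0, 3.0], "thip": [1.0, 2.0]}
        with pytest.raises(ValueError, match="thip"):
            compare_groups(groups)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]}, control="saline")

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            groups = {c: rng.normal(0, 1, 8)
                      for c in ("saline", "a", "b", "c")}
            if compare_groups(groups).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        # binomial sampling band around 0.05 for 300 replicates (~4 SD)
        assert 0.0 < rate < 0.10


class TestDunnSidak:
    def test_matches_hand_computed_formula(self):
        groups = {"saline": [1.0, 2.0, 3.0, 4.0],
                  "drug": [5.0, 6.0, 7.0, 8.0]}
        df = dunn_sidak(groups, "saline")
        pooled = np.array(groups["saline"] + groups["drug"], float)
        ranks = stats.rankdata(pooled)
        diff = ranks[4:].mean() - ranks[:4].mean()
        n = 8
        se = np.sqrt((n * (n + 1) / 12.0) * (1 / 4 + 1 / 4))
        z = diff / se
        p = 2 * stats.norm.sf(abs(z))
        row = df.iloc[0]
        assert row["statistic"] == pytest.approx(z, abs=1e-12)
        assert row["p_adj"] == pytest.approx(1 - (1 - p) ** 1, abs=1e-12)

    def test_tie_correction_reduces_variance(self):
        # with ties the SE shrinks, so |z| must grow relative to a naive
        # no-tie computation applied to the same mean-rank difference
        groups = {"saline": [1.0, 1.0, 2.0, 3.0], "drug": [3.0, 4.0, 4.0, 5.0]}
        df = dunn_sidak(groups, "saline")
        pooled = np.array(groups["saline"] + groups["drug"], float)
        ranks = stats.rankdata(pooled)
        diff = ranks[4:].mean() - ranks[:4].mean()
        naive_z = diff / np.sqrt((8 * 9 / 12.0) * 0.5)
        assert abs(df.iloc[0]["statistic"]) > abs(naive_z)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(4)
        groups = {c: rng.normal(0, 1, 6) for c in ("saline", "a", "b")}
        df = dunn_sidak(groups, "saline")
        assert (df["p_adj"] >= df["p"] - 1e-15).all()


class TestPacCompare:
    def test_one_sample_t_matches_scipy(self):
        rng = np.random.default_rng(5)
        changes = {"saline": rng.normal(0, 0.001, 8),
                   "zolpidem": rng.normal(0.004, 0.002, 8)}
        df = pac_compare(changes).set_index("condition")
        t, p = stats.ttest_1samp(changes["zolpidem"], 0.0)
        assert df.loc["zolpidem", "t_vs_baseline"] == pytest.approx(t)
        assert df.loc["zolpidem", "p_vs_baseline"] == pytest.approx(p)

    def test_welch_t_vs_control_and_control_nan(self):
        rng = np.random.default_rng(6)
        changes = {"saline": rng.normal(0, 0.001, 8),
                   "thip": rng.normal(-0.003, 0.004, 8)}
        df = pac_compare(changes).set_index("condition")
        t, p = stats.ttest_ind(changes["thip"], changes["saline"], equal_var=False)
        assert df.loc["thip", "t_vs_control"] == pytest.approx(t)
        assert np.isnan(df.loc["saline", "p_vs_control"])


class TestPerBinSpectral:
    def test_effect_bin_flagged_and_null_bin_not(self):
        rng = np.random.default_rng(7)
        freqs = np.array([1.0, 1.25])
        base = rng.normal(100, 5, (8, 2))
        drug = rng.normal(100, 5, (8, 2))
        drug[:, 0] += 40.0  # strong effect in the first bin only
        df = per_bin_spectral_comparison(
            {"saline": base, "zolpidem": drug}, freqs)
        hit = df[(df.freq == 1.0)].iloc[0]
        miss = df[(df.freq == 1.25)].iloc[0]
        assert hit["significant"] and hit["significant_bonf"]
        assert not miss["significant"]

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            per_bin_spectral_comparison(
                {"saline": np.zeros((4, 3)), "drug": np.zeros((4, 2))},
                np.array([1.0, 1.25, 1.5]))
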