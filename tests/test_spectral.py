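import math

import numpy as np
import pytest

from somnoscope import (
    ContinuousSignal,
    Hypnogram,
    comodulogram,
    modulation_index,
    pac_change,
    swa_timecourse,
    welch_power,
)
from somnoscope.spectral import Comodulogram, state_segments

FS = 500.0


def tone(freq, amp=10.0, duration=60.0, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    return ContinuousSignal(amp * np.sin(2 * np.pi * freq * t), fs)


class TestWelchPower:
    def test_quarter_hz_resolution(self):
        ps = welch_power(tone(2.0))
        assert np.diff(ps.freqs)[0] == pytest.approx(0.25)
        assert ps.n_segments == 15

    def test_sinusoid_peak_at_its_frequency(self):
        ps = welch_power(tone(2.0, amp=10.0))
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(2.0)
        # essentially no power far from the peak
        far = ps.power[ps.freqs > 10.0]
        assert np.max(far) < 1e-6 * np.max(ps.power)

    def test_white_noise_total_power_matches_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 20.0, int(600 * FS))
        ps = welch_power(ContinuousSignal(x, FS))
        total = np.sum(ps.power) * 0.25
        assert total == pytest.approx(400.0, rel=0.05)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 20.0, int(600 * FS))
        ps = welch_power(ContinuousSignal(x, FS))
        lo = ps.band_power((1.0, 50.0))
        hi = ps.band_power((150.0, 240.0))
        assert hi / lo == pytest.approx(1.0, abs=0.1)

    def test_doubling_amplitude_quadruples_power(self):
        a = welch_power(tone(2.0, amp=10.0))
        b = welch_power(tone(2.0, amp=20.0))
        assert b.band_power((0.5, 4.0)) == pytest.approx(
            4.0 * a.band_power((0.5, 4.0)), rel=1e-9)

    def test_mean_over_segments_property(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 10.0, int(16 * FS))
        full = welch_power(ContinuousSignal(x, FS))
        halves = [welch_power(ContinuousSignal(x[: int(8 * FS)], FS)),
                  welch_power(ContinuousSignal(x[int(8 * FS):], FS))]
        mean = 0.5 * (halves[0].power + halves[1].power)
        np.testing.assert_allclose(full.power, mean, rtol=1e-9)

    def test_artifact_epochs_excluded(self):
        # a loud 30 Hz tone confined to artifact epochs must not leak in
        x = np.zeros(int(40 * FS))
        t = np.arange(0, 8, 1 / FS)
        x[: t.size] = 500 * np.sin(2 * np.pi * 30 * t)
        x += np.random.default_rng(3).normal(0, 5.0, x.size)
        labels = ["artifact"] * 2 + ["NREM"] * 8
        ps = welch_power(ContinuousSignal(x, FS), Hypnogram(labels))
        assert ps.n_segments == 8
        assert ps.band_power((29.0, 31.0)) < 1.0

    def test_restriction_without_hypnogram_rejected(self):
        with pytest.raises(ValueError):
            welch_power(tone(2.0), restrict="NREM")

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            welch_power(ContinuousSignal(np.zeros(int(2 * FS)), FS))


class TestSwaTimecourse:
    def test_ten_minutes_gives_two_five_minute_bins(self):
        sig = tone(2.0, duration=600.0)
        t, swa = swa_timecourse(sig)
        assert t.size == swa.size == 2
        np.testing.assert_allclose(t, [0.0, 300.0])

    def test_amplitude_doubling_quadruples_swa(self):
        t = np.arange(0, 600, 1 / FS)
        x = 10 * np.sin(2 * np.pi * 2.0 * t)
        x[t >= 300] *= 2.0
        _, swa = swa_timecourse(ContinuousSignal(x, FS))
        assert swa[1] / swa[0] == pytest.approx(4.0, rel=0.01)

    def test_bin_without_eligible_segment_is_nan(self):
        sig = tone(2.0, duration=600.0)
        labels = ["NREM"] * 75 + ["wake"] * 75
        _, swa = swa_timecourse(sig, Hypnogram(labels), restrict="NREM")
        assert np.isfinite(swa[0])
        assert np.isnan(swa[1])


def mi_oracle(phase, amplitude, n_bins=18):
    """Independent reference MI: explicit per-bin loop, math.log entropy."""
    edges = [-math.pi + k * 2 * math.pi / n_bins for k in range(n_bins + 1)]
    means = []
    for k in range(n_bins):
        sel = [a for p, a in zip(phase, amplitude)
               if edges[k] <= p < edges[k + 1] or (k == n_bins - 1 and p == edges[-1])]
        means.append(sum(sel) / len(sel) if sel else 0.0)
    s = sum(means)
    probs = [m / s for m in means]
    h = -sum(p * math.log(p) for p in probs if p > 0)
    return (math.log(n_bins) - h) / math.log(n_bins)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(-np.pi, np.pi, 20000)
        assert modulation_index(None, None, phase=ph,
                                amplitude=np.ones_like(ph)) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_concentration_gives_one(self):
        ph = np.zeros(1000)
        mi = modulation_index(None, None, phase=ph, amplitude=np.ones(1000))
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_sinusoidal_modulation_matches_closed_form(self):
        n_bins, m = 18, 0.6
        centers = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
        ph = np.repeat(centers, 10)
        amp = 1.0 + m * np.cos(ph)
        p = (1 + m * np.cos(centers))
        p = p / p.sum()
        expected = (np.log(n_bins) + np.sum(p * np.log(p))) / np.log(n_bins)
        mi = modulation_index(None, None, n_bins, phase=ph, amplitude=amp)
        assert mi == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ph = rng.uniform(-np.pi, np.pi, 3000)
            amp = rng.uniform(0.1, 2.0, 3000) * (1 + 0.5 * np.cos(ph))
            got = modulation_index(None, None, phase=ph, amplitude=amp)
            assert abs(got - mi_oracle(ph, amp)) < 1e-10

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(8)
        ph = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1 + 0.4 * np.cos(ph - 1.0)
        a = modulation_index(None, None, phase=ph, amplitude=amp)
        b = modulation_index(None, None, phase=ph, amplitude=amp * 123.0)
        assert a == pytest.approx(b, abs=1e-14)

    def test_phase_rotation_invariance(self):
        rng = np.random.default_rng(9)
        ph = rng.uniform(-np.pi, np.pi, 50000)
        amp = 1 + 0.4 * np.cos(ph)
        rot = np.angle(np.exp(1j * (ph + 2 * np.pi / 18)))  # whole-bin rotation
        a = modulation_index(None, None, phase=ph, amplitude=amp)
        b = modulation_index(None, None, phase=rot, amplitude=amp)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(None, None, phase=np.zeros(10), amplitude=np.zeros(10))

    def test_hilbert_path_agrees_with_precomputed(self):
        t = np.arange(0, 30, 1 / 200.0)
        slow = np.sin(2 * np.pi * 1.0 * t)
        fast = (1 + 0.8 * np.cos(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 12.0 * t)
        import scipy.signal as sps
        direct = modulation_index(slow, fast)
        pre = modulation_index(None, None,
                               phase=np.angle(sps.hilbert(slow)),
                               amplitude=np.abs(sps.hilbert(fast)))
        assert direct == pytest.approx(pre, abs=1e-14)


class TestComodulogram:
    def _coupled_signal(self, duration=120.0, fs=200.0, f_phase=1.0, f_amp=12.0,
                        depth=0.9, seed=0):
        t = np.arange(0, duration, 1 / fs)
        slow = 100 * np.sin(2 * np.pi * f_phase * t)
        fast = 20 * (1 + depth * np.cos(2 * np.pi * f_phase * t)) * \
            np.sin(2 * np.pi * f_amp * t)
        bg = np.random.default_rng(seed).normal(0, 5.0, t.size)
        return ContinuousSignal(slow + fast + bg, fs)

    def test_grid_shape_matches_defaults(self):
        com = comodulogram(self._coupled_signal(duration=40.0))
        assert len(com.phase_bands) == 7   # 0.5 Hz wide, 0.5 Hz step over 0.5-4
        assert len(com.amp_bands) == 11    # 2 Hz wide, 1 Hz step over 8-20
        assert com.mi.shape == (7, 11)

    def test_maximum_lands_on_coupled_cell(self):
        com = comodulogram(self._coupled_signal())
        pb, ab = com.argmax()
        assert pb[0] <= 1.0 <= pb[1]
        assert ab[0] <= 12.0 <= ab[1]

    def test_coupled_window_dominates_far_window(self):
        com = comodulogram(self._coupled_signal())
        near = com.max_in_window((0.5, 1.5), (10.0, 16.0))
        far = com.max_in_window((3.0, 4.0), (17.0, 20.0))
        assert near > 5 * far

    def test_state_restriction_uses_only_nrem(self):
        # coupling present only during NREM epochs; wake is plain noise
        sig = self._coupled_signal(duration=120.0)
        labels = ["NREM"] * 15 + ["wake"] * 15
        x = sig.samples.copy()
        x[int(60 * sig.fs):] = np.random.default_rng(1).normal(0, 20.0, int(60 * sig.fs))
        com = comodulogram(ContinuousSignal(x, sig.fs), Hypnogram(labels))
        assert com.max_in_window((0.5, 1.5), (10.0, 16.0)) > 0.01

    def test_no_state_segments_raises(self):
        sig = self._coupled_signal(duration=40.0)
        with pytest.raises(ValueError, match="segments"):
            comodulogram(sig, Hypnogram(["wake"] * 10))

    def test_min_segment_length_is_8s(self):
        sig = self._coupled_signal(duration=40.0)
        hyp = Hypnogram(["NREM", "wake"] * 5)  # 4 s NREM islands only
        assert state_segments(sig, hyp) == []


class TestPacChange:
    def _com(self, value):
        bands_p = [(0.5, 1.0), (1.0, 1.5)]
        bands_a = [(10.0, 12.0), (12.0, 14.0)]
        mi = np.full((2, 2), 0.001)
        mi[0, 1] = value
        return Comodulogram(bands_p, bands_a, mi)

    def test_change_is_post_minus_pre_window_max(self):
        assert pac_change(self._com(0.002), self._com(0.010)) == pytest.approx(0.008)
        assert pac_change(self._com(0.010), self._com(0.002)) == pytest.approx(-0.008)

    def test_mismatched_grids_rejected(self):
        a = self._com(0.01)
        b = Comodulogram([(0.5, 1.0)], [(10.0, 12.0)], np.array([[0.01]]))
        with pytest.raises(ValueError):
            pac_change(a, b)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            self._com(0.01).max_in_window((30.0, 40.0), (10.0, 16.0))
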