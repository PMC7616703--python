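"""Detector behavior: decimation, DS, SWR, co-occurrence, theta cycles."""

import numpy as np
import pytest

from hippocoact import (
    LaminarLfp,
    decimate_lfp,
    detect_dentate_spikes,
    detect_swr,
    detect_theta_cycles,
    exclude_cooccurring,
    planted_event_set,
)
from hippocoact.lfp_events import bandpass, count_ripple_cycles
from hippocoact.synth import pink_noise

from conftest import match_events


# ----------------------------------------------------------------------
# decimation
# ----------------------------------------------------------------------

class TestDecimate:
    def test_sine_amplitude_preserved(self):
        fs0 = 20000.0
        t = np.arange(int(2 * fs0)) / fs0
        dec = decimate_lfp(LaminarLfp(np.sin(2 * np.pi * 100 * t), fs0, ["gcl"]))
        assert dec.fs_hz == 1250.0
        assert dec.n_samples == len(t) // 16
        spec = np.abs(np.fft.rfft(dec.samples[0]))
        freqs = np.fft.rfftfreq(dec.n_samples, 1 / 1250)
        assert freqs[np.argmax(spec)] == pytest.approx(100.0, abs=0.5)
        assert 2 * spec.max() / dec.n_samples == pytest.approx(1.0, rel=0.01)

    def test_dc_passes_with_filter_ripple_only(self):
        # the Chebyshev-I anti-alias filter has small passband ripple, so
        # a constant comes through constant up to that ripple
        dec = decimate_lfp(LaminarLfp(np.full(32000, 2.5), 20000.0, ["gcl"]))
        assert np.ptp(dec.samples) < 1e-9
        assert dec.samples[0, 0] == pytest.approx(2.5, rel=0.05)

    def test_above_band_tone_attenuated(self):
        fs0 = 20000.0
        t = np.arange(int(2 * fs0)) / fs0
        dec = decimate_lfp(LaminarLfp(np.sin(2 * np.pi * 900 * t), fs0, ["gcl"]))
        attenuation_db = 20 * np.log10(np.sqrt(np.mean(dec.samples**2)) / np.sqrt(0.5))
        assert attenuation_db < -20.0

    def test_rejects_target_above_nyquist(self):
        with pytest.raises(ValueError):
            decimate_lfp(LaminarLfp(np.zeros(100), 2000.0, ["gcl"]), target_fs_hz=1250.0)


# ----------------------------------------------------------------------
# dentate spikes
# ----------------------------------------------------------------------

class TestDentateSpikes:
    fs = 1250.0

    def _noise_lfp(self, seed: int, dur_s: float = 60.0) -> np.ndarray:
        return pink_noise(int(dur_s * self.fs), np.random.default_rng(seed))

    def _transient(self, n: int, center: int, amp: float, width_s: float = 0.045):
        half = int(width_s * self.fs / 2)
        idx = np.arange(max(0, center - 2 * half), min(n, center + 2 * half))
        return idx, amp * np.exp(-0.5 * ((idx - center) / (half / 1.6)) ** 2)

    def test_planted_transients_recovered_within_5ms(self):
        x = self._noise_lfp(0)
        mad = np.median(np.abs(bandpass(x, self.fs, 1, 200)))
        centers = (np.arange(20) * 2.5 + 5.0) * self.fs
        for c in centers:
            idx, tr = self._transient(len(x), int(c), 10 * 6 * mad)
            x[idx] += tr
        es = detect_dentate_spikes(LaminarLfp(x, self.fs, ["gcl"]), channel=0)
        assert len(es) == 20
        prec, rec = match_events(es.peak_times, centers / self.fs, tol_s=0.005)
        assert prec == 1.0 and rec == 1.0

    def test_two_close_peaks_keep_larger(self):
        """Two super-threshold peaks 30 ms apart yield one event at the larger."""
        x = self._noise_lfp(1, 30.0)
        mad = np.median(np.abs(bandpass(x, self.fs, 1, 200)))
        c1 = int(10.0 * self.fs)
        c2 = int((10.0 + 0.030) * self.fs)
        for c, amp in ((c1, 8 * 6 * mad), (c2, 16 * 6 * mad)):
            idx, tr = self._transient(len(x), c, amp, width_s=0.02)
            x[idx] += tr
        es = detect_dentate_spikes(LaminarLfp(x, self.fs, ["gcl"]), channel=0)
        in_frame = es.peak_times[(es.peak_times > 9.9) & (es.peak_times < 10.2)]
        assert len(in_frame) == 1
        assert abs(in_frame[0] - c2 / self.fs) < 0.005

    def test_subthreshold_noise_yields_nothing(self):
        # bounded uniform noise: max |x| = 0.5 < 6 x MAD (= 1.5), so the
        # signal is sub-threshold by construction
        rng = np.random.default_rng(2)
        x = rng.uniform(-0.5, 0.5, int(60 * self.fs))
        es = detect_dentate_spikes(LaminarLfp(x, self.fs, ["gcl"]), channel=0)
        assert len(es) == 0

    def test_gain_invariance(self):
        x = self._noise_lfp(3)
        mad = np.median(np.abs(bandpass(x, self.fs, 1, 200)))
        idx, tr = self._transient(len(x), int(20 * self.fs), 10 * 6 * mad)
        x[idx] += tr
        a = detect_dentate_spikes(LaminarLfp(x, self.fs, ["gcl"]), channel=0)
        b = detect_dentate_spikes(LaminarLfp(x * 37.0, self.fs, ["gcl"]), channel=0)
        np.testing.assert_allclose(a.peak_times, b.peak_times)

    def test_invalid_channel_errors(self):
        with pytest.raises(ValueError):
            detect_dentate_spikes(LaminarLfp(np.zeros(1000), self.fs, ["gcl"]), channel=5)


# ----------------------------------------------------------------------
# sharp-wave ripples
# ----------------------------------------------------------------------

def _swr_base(seed: int, dur_s: float = 60.0, fs: float = 1250.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.stack([pink_noise(int(dur_s * fs), rng) for _ in range(4)])


def _ripple_burst(fs: float, freq: float, n_cycles: float, amp: float) -> np.ndarray:
    dur = n_cycles / freq
    n = int(dur * fs)
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t) * np.hanning(n)


class TestSwr:
    fs = 1250.0
    layers = ["ori", "pyr", "rad", "gcl"]

    def _env_median(self, x):
        from scipy.signal import hilbert

        rip = bandpass(x - x.mean(axis=0), self.fs, 80, 250)
        return np.median(np.abs(hilbert(rip[1])))

    def test_planted_six_cycle_burst_accepted(self):
        x = _swr_base(0)
        med = self._env_median(x)
        burst = _ripple_burst(self.fs, 150.0, 6, 8 * 5 * med)
        c = int(30.0 * self.fs)
        x[1, c : c + len(burst)] += burst
        x[2, c : c + len(burst)] -= 2.0 * np.hanning(len(burst))  # sharp wave
        es = detect_swr(LaminarLfp(x, self.fs, self.layers))
        assert len(es) == 1
        ev = es.events.iloc[0]
        assert abs(ev["peak_t"] - (c + len(burst) / 2) / self.fs) < 0.01
        assert 0.02 < ev["offset_t"] - ev["onset_t"] < 0.08

    def test_three_cycle_burst_rejected(self):
        x = _swr_base(1)
        med = self._env_median(x)
        burst = _ripple_burst(self.fs, 150.0, 3, 8 * 5 * med)
        c = int(30.0 * self.fs)
        x[1, c : c + len(burst)] += burst
        es = detect_swr(LaminarLfp(x, self.fs, self.layers))
        assert len(es) == 0

    def test_broadband_click_rejected_by_supra_band(self):
        """A spectrally flat transient has as much 200-500 Hz as ripple power."""
        x = _swr_base(2)
        med = self._env_median(x)
        rng = np.random.default_rng(7)
        click = rng.standard_normal(int(0.04 * self.fs)) * np.hanning(int(0.04 * self.fs))
        click *= 12 * 5 * med / np.abs(click).max()
        c = int(30.0 * self.fs)
        x[1, c : c + len(click)] += click
        es = detect_swr(LaminarLfp(x, self.fs, self.layers))
        assert len(es) == 0

    def test_needs_two_channels(self):
        with pytest.raises(ValueError):
            detect_swr(LaminarLfp(np.zeros(1000), self.fs, ["pyr"]))

    def test_accepted_events_satisfy_criteria_on_recheck(self, sleep_session):
        cfg, lfp, _, _ = sleep_session
        es = detect_swr(lfp)
        assert len(es) > 0
        car = lfp.samples.mean(axis=0)
        ch = es.provenance["channel"]
        rip = bandpass(lfp.samples[ch] - car, lfp.fs_hz, 80, 250)
        for _, ev in es.events.iterrows():
            i0 = int(ev["onset_t"] * lfp.fs_hz)
            i1 = int(ev["offset_t"] * lfp.fs_hz)
            seg = rip[i0:i1]
            p_rip = np.mean(seg**2)
            p_ref = np.mean(bandpass(car[i0:i1], lfp.fs_hz, 80, 250) ** 2)
            p_supra = np.mean(
                bandpass((lfp.samples[ch] - car)[i0:i1], lfp.fs_hz, 200, 500) ** 2
            )
            assert p_rip >= 2 * p_ref
            assert count_ripple_cycles(seg) >= 4
            assert p_rip >= 2 * p_supra


# ----------------------------------------------------------------------
# co-occurrence exclusion
# ----------------------------------------------------------------------

class TestCooccurrence:
    def _sets(self, ds_t, swr_t):
        import pandas as pd

        from hippocoact import EventSet

        def mk(ts, ty):
            return EventSet(
                pd.DataFrame(
                    {
                        "type": ty,
                        "peak_t": ts,
                        "onset_t": np.asarray(ts) - 0.02,
                        "offset_t": np.asarray(ts) + 0.02,
                        "channel": 0,
                        "peak_amplitude": 1.0,
                    }
                )
            )

        return mk(ds_t, "DS"), mk(swr_t, "SWR")

    def test_pair_within_window_removed_both_sides(self):
        ds, swr = self._sets([10.00], [10.03])
        ds2, swr2, co = exclude_cooccurring(ds, swr)
        assert len(ds2) == 0 and len(swr2) == 0
        assert co > 0

    def test_disjoint_events_unchanged(self):
        ds, swr = self._sets([10.0, 20.0], [10.2, 21.0])
        ds2, swr2, co = exclude_cooccurring(ds, swr)
        assert len(ds2) == 2 and len(swr2) == 2

    def test_survivors_all_separated_brute_force(self):
        rng = np.random.default_rng(0)
        ds_t = np.sort(rng.uniform(0, 600, 200))
        swr_t = np.sort(rng.uniform(0, 600, 350))
        ds, swr = self._sets(ds_t, swr_t)
        ds2, swr2, _ = exclude_cooccurring(ds, swr)
        for t in ds2.peak_times:  # exhaustive pairwise check
            assert np.min(np.abs(swr2.peak_times - t)) > 0.05
        for t in swr2.peak_times:
            assert np.min(np.abs(ds2.peak_times - t)) > 0.05


# ----------------------------------------------------------------------
# theta cycles
# ----------------------------------------------------------------------

class TestThetaCycles:
    fs = 1250.0

    @pytest.mark.parametrize("method", ["masked_sift", "bandpass"])
    def test_pure_8hz_sine(self, method):
        t = np.arange(int(10 * self.fs)) / self.fs
        cycles = detect_theta_cycles(np.sin(2 * np.pi * 8 * t), self.fs, method=method)
        assert abs(len(cycles) - 79) <= 1
        mid = cycles[len(cycles) // 2]
        assert (mid.peak2_t - mid.peak1_t) * 1000 == pytest.approx(125.0, abs=2.0)
        assert (mid.trough_t - mid.peak1_t) * 1000 == pytest.approx(62.5, abs=2.0)

    @pytest.mark.parametrize("method", ["masked_sift", "bandpass"])
    def test_4hz_sine_rejected_by_interval_rule(self, method):
        t = np.arange(int(10 * self.fs)) / self.fs
        assert detect_theta_cycles(np.sin(2 * np.pi * 4 * t), self.fs, method=method) == []

    def test_noisy_8hz_recovery(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(10 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 8 * t) + np.sqrt(0.1) * rng.standard_normal(len(t))
        cycles = detect_theta_cycles(x, self.fs)
        true_peaks = (np.arange(79) + 0.25) / 8.0
        rec = np.mean(
            [min(abs(c.peak1_t - p) for c in cycles) < 0.02 for p in true_peaks[:-1]]
        )
        assert rec >= 0.9

    def test_aperiodic_input_empty(self):
        x = np.linspace(0, 1, int(5 * self.fs))  # pure trend, no oscillation
        assert detect_theta_cycles(x, self.fs) == []
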