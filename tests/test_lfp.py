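"""Trace preprocessing, wavelet spectra, Z transforms, fractional band
changes and burst statistics."""

import numpy as np
import pytest

from raphemap import lfp
from raphemap.lfp import (LfpError, LfpTrace, band_power_envelope,
                          burst_statistics, fractional_band_change,
                          preprocess_traces, trial_average_z,
                          wavelet_amplitude)
from raphemap.protocol import StimProtocol, make_protocol
from raphemap.synthgen import GroundTruth, simulate_site_lfp
from raphemap.synthgen.probe import simulate_spike_times, ProbeTruth

FS_RAW = 25_000.0


class TestPreprocess:
    def _sine(self, freq, duration=2.0):
        t = np.arange(0, duration, 1 / FS_RAW)
        return np.sin(2 * np.pi * freq * t), t

    def test_passband_sinusoid_survives_both_paths(self):
        x, t = self._sine(1000.0)
        out = preprocess_traces(x, FS_RAW)
        interior = slice(int(0.2 * FS_RAW), int(1.8 * FS_RAW))
        assert np.abs(out.mua[interior]).max() == pytest.approx(1.0, rel=0.05)
        lfp_interior = slice(int(0.2 * out.lfp.fs), int(1.8 * out.lfp.fs))
        assert np.abs(out.lfp.samples[lfp_interior]).max() == pytest.approx(
            1.0, rel=0.05)
        assert out.lfp.fs == FS_RAW / 8

    def test_5khz_attenuated_in_lfp_output(self):
        x, _ = self._sine(5000.0)
        out = preprocess_traces(x, FS_RAW)
        # > 20 dB attenuation through the 1.9 kHz low-pass (interior:
        # zero-phase filtering has edge transients)
        interior = slice(int(0.2 * out.lfp.fs), int(1.8 * out.lfp.fs))
        assert np.abs(out.lfp.samples[interior]).max() < 0.1

    def test_dc_removed_from_mua(self):
        x = np.full(int(FS_RAW), 3.0)
        out = preprocess_traces(x, FS_RAW)
        assert np.abs(out.mua[1000:-1000]).max() < 1e-3

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(LfpError, match="too low"):
            preprocess_traces(np.zeros(1000), 5000.0)

    def test_provenance_recorded(self):
        out = preprocess_traces(np.zeros(int(FS_RAW)), FS_RAW)
        assert any("lowpass" in p for p in out.lfp.provenance)
        assert any("downsample" in p for p in out.lfp.provenance)


class TestWaveletAmplitude:
    def test_pure_tone_ridge_at_nearest_bin(self):
        fs = 250.0
        t = np.arange(0, 60, 1 / fs)
        spec = wavelet_amplitude(LfpTrace(np.sin(2 * np.pi * 2 * t), fs))
        interior = (spec.times > 10) & (spec.times < 50)
        ridge = spec.frequencies[np.argmax(spec.amplitude[:, interior], axis=0)]
        nearest = spec.frequencies[np.argmin(np.abs(spec.frequencies - 2.0))]
        assert np.all(ridge == nearest)

    def test_two_tone_amplitude_ratio(self):
        fs = 1000.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 40 * t)
        freqs = np.geomspace(0.5, 100, 40)
        # pin the two tones onto exact grid frequencies
        freqs[np.argmin(np.abs(freqs - 2))] = 2.0
        freqs[np.argmin(np.abs(freqs - 40))] = 40.0
        spec = wavelet_amplitude(LfpTrace(x, fs), frequencies=freqs)
        interior = (spec.times > 15) & (spec.times < 45)
        a2 = spec.amplitude[freqs == 2.0, interior].mean()
        a40 = spec.amplitude[freqs == 40.0, interior].mean()
        assert a2 / a40 == pytest.approx(2.0, rel=0.05)

    def test_zero_trace_zero_spectrum(self):
        spec = wavelet_amplitude(LfpTrace(np.zeros(1000), 250.0))
        assert np.all(spec.amplitude == 0)

    def test_white_noise_power_flat_per_unit_bandwidth(self):
        """Constant-Q sanity: white-noise wavelet power divided by the
        (frequency-proportional) bandwidth is flat across log-frequency."""
        fs = 250.0
        rng = np.random.default_rng(3)
        freqs = np.geomspace(4, 40, 15)
        pw = np.zeros(freqs.size)
        for _ in range(4):
            x = rng.normal(size=int(300 * fs))
            spec = wavelet_amplitude(LfpTrace(x, fs), frequencies=freqs)
            sel = (spec.times > 20) & (spec.times < 280)
            pw += (spec.amplitude[:, sel] ** 2).mean(axis=1)
        rel = pw / freqs
        rel /= rel.mean()
        assert np.abs(rel - 1).max() < 0.10

    def test_frequencies_outside_nyquist_rejected(self):
        with pytest.raises(LfpError, match="fs/2"):
            wavelet_amplitude(LfpTrace(np.zeros(1000), 100.0),
                              frequencies=np.array([60.0]))


class TestTrialAverageZ:
    def test_stationary_noise_baseline_z_near_zero(self, rng):
        fs = 125.0
        protocol = make_protocol("short")
        x = rng.normal(size=int(protocol.duration * fs))
        spec = wavelet_amplitude(LfpTrace(x, fs),
                                 frequencies=np.geomspace(1, 40, 10))
        z = trial_average_z(spec, protocol)
        base = z.times < 0
        assert abs(z.amplitude[:, base].mean()) < 1e-9   # exact by construction
        assert np.abs(z.amplitude).max() < 6

    def test_delta_suppression_shows_negative_z(self, rng):
        protocol = make_protocol("short")
        truth = GroundTruth(delta_suppression=0.4, lfp_power_lag_s=5.0)
        trace = simulate_site_lfp(protocol, truth, rng, fs=125.0,
                                  noise_uv=5.0, am_depth=0.1)
        spec = wavelet_amplitude(trace, frequencies=np.geomspace(1, 40, 12))
        z = trial_average_z(spec, protocol)
        delta_rows = z.band_rows((1.0, 4.0))
        stim_cols = (z.times > 5.0) & (z.times < 20.0)
        assert z.amplitude[np.ix_(delta_rows, stim_cols)].mean() < -1.0

    def test_single_trial_equals_its_own_z(self, rng):
        fs = 125.0
        protocol = StimProtocol(block_onsets=(30.0,), block_duration=10.0,
                                inter_onset=60.0, n_volumes=40)
        x = rng.normal(size=int(protocol.duration * fs))
        spec = wavelet_amplitude(LfpTrace(x, fs),
                                 frequencies=np.geomspace(1, 40, 6))
        z = trial_average_z(spec, protocol, baseline_window=(-10.0, 0.0))
        dt = spec.dt
        rel = np.arange(int(round(-10.0 / dt)),
                        int(round((10.0 + 20.0) / dt)))
        idx = rel + int(round(30.0 / dt))
        single = spec.amplitude[:, idx]
        base = single[:, rel * dt < 0]
        expect = (single - base.mean(axis=1, keepdims=True)) \
            / base.std(axis=1, keepdims=True)
        np.testing.assert_allclose(z.amplitude, expect, atol=1e-10)

    def test_baseline_overlapping_stimulation_rejected(self, rng):
        fs = 125.0
        protocol = make_protocol("short")
        spec = wavelet_amplitude(
            LfpTrace(rng.normal(size=int(protocol.duration * fs)), fs),
            frequencies=np.geomspace(1, 10, 4))
        with pytest.raises(LfpError, match="overlaps stimulation"):
            trial_average_z(spec, protocol, baseline_window=(-10.0, 5.0))


class TestFractionalBandChange:
    def _suppressed_spectrum(self, rng, suppression=0.5, noise=0.0):
        protocol = make_protocol("short")
        truth = GroundTruth(delta_suppression=suppression,
                            lfp_power_lag_s=5.0)
        trace = simulate_site_lfp(protocol, truth, rng, fs=125.0,
                                  noise_uv=noise, am_depth=0.0)
        spec = wavelet_amplitude(trace, frequencies=np.geomspace(1, 60, 15))
        return spec, protocol

    def test_amplitude_halving_gives_power_drop_three_quarters(self, rng):
        spec, protocol = self._suppressed_spectrum(rng, suppression=0.5)
        change = fractional_band_change(spec, protocol, band=(1.0, 4.0))
        assert change == pytest.approx(-0.75, abs=0.05)

    def test_amplitude_mode_gives_half(self, rng):
        spec, protocol = self._suppressed_spectrum(rng, suppression=0.5)
        change = fractional_band_change(spec, protocol, band=(1.0, 4.0),
                                        use="amplitude")
        assert change == pytest.approx(-0.5, abs=0.05)

    def test_no_modulation_no_change(self, rng):
        spec, protocol = self._suppressed_spectrum(rng, suppression=1.0,
                                                   noise=5.0)
        change = fractional_band_change(spec, protocol, band=(1.0, 4.0))
        assert abs(change) < 0.05

    def test_band_outside_signal_unchanged(self, rng):
        spec, protocol = self._suppressed_spectrum(rng, suppression=0.5,
                                                   noise=20.0)
        change = fractional_band_change(spec, protocol, band=(30.0, 60.0))
        assert abs(change) < 0.1

    def test_invariant_to_global_rescaling(self, rng):
        spec, protocol = self._suppressed_spectrum(rng)
        a = fractional_band_change(spec, protocol, band=(1.0, 4.0))
        spec.amplitude = spec.amplitude * 7.3
        b = fractional_band_change(spec, protocol, band=(1.0, 4.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_band_rejected(self, rng):
        spec, protocol = self._suppressed_spectrum(rng)
        with pytest.raises(LfpError, match="no frequency rows"):
            fractional_band_change(spec, protocol, band=(200.0, 300.0))


class TestBurstStatistics:
    def _spike_times(self, seed, burst_suppression, protocol):
        truth = GroundTruth(block_amplitudes=(2.0,) * 6,
                            burst_rate_hz=0.5,
                            burst_suppression=burst_suppression)
        rng = np.random.default_rng(seed)
        _, bursts = simulate_spike_times(protocol, truth, ProbeTruth(), rng,
                                         protocol.duration)
        # dense tonic population floor so the 3 x median-bin threshold
        # sits well above chance coincidences
        spikes = [rng.uniform(0, protocol.duration,
                              int(30 * protocol.duration))]
        for bt in bursts:
            spikes.append(bt + rng.uniform(0, 0.05, 25))
        return np.sort(np.concatenate(spikes)), truth

    @staticmethod
    def _gt_frac(bursts, protocol):
        s = protocol.stim_mask(bursts, transition=5.0)
        b = protocol.baseline_mask(bursts, transition=5.0)
        stim_t = protocol.n_blocks * (protocol.block_duration - 5.0)
        base_t = protocol.duration - protocol.n_blocks * (protocol.block_duration + 5.0)
        return (s.sum() / stim_t) / (b.sum() / base_t) - 1.0

    def test_generator_burst_rate_is_halved(self):
        """The injected inhomogeneous-Poisson bursts show a -0.5
        fractional rate change, within Poisson error over 100 seeds."""
        protocol = make_protocol("short")
        truth = GroundTruth(burst_rate_hz=0.5, burst_suppression=0.5)
        fracs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, bursts = simulate_spike_times(protocol, truth, ProbeTruth(),
                                             rng, protocol.duration)
            fracs.append(self._gt_frac(bursts, protocol))
        sem = np.std(fracs) / np.sqrt(len(fracs))
        assert np.mean(fracs) == pytest.approx(-0.5, abs=max(3 * sem, 0.05))

    def test_detected_change_tracks_ground_truth(self):
        """Detected fractional burst change follows the ground-truth
        fractional change seed by seed (small dilution from chance
        coincidences and burst merging is tolerated)."""
        protocol = make_protocol("short")
        truth = GroundTruth(burst_rate_hz=0.5, burst_suppression=0.5)
        diffs, detected = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            _, bursts = simulate_spike_times(protocol, truth, ProbeTruth(),
                                             rng, protocol.duration)
            spikes = [rng.uniform(0, protocol.duration,
                                  int(30 * protocol.duration))]
            for bt in bursts:
                spikes.append(bt + rng.uniform(0, 0.05, 25))
            out = burst_statistics(np.sort(np.concatenate(spikes)), protocol)
            detected.append(out.fractional_change)
            diffs.append(out.fractional_change - self._gt_frac(bursts, protocol))
        assert abs(np.mean(diffs)) < 0.1
        assert all(d < -0.1 for d in detected)      # suppression always seen

    def test_constant_rate_no_change(self):
        protocol = make_protocol("short")
        changes = []
        for seed in range(5):
            spikes, _ = self._spike_times(seed, 1.0, protocol)
            changes.append(burst_statistics(spikes, protocol).fractional_change)
        assert abs(np.mean(changes)) < 0.15

    def test_no_blocks_in_span_rejected(self):
        protocol = make_protocol("short")
        with pytest.raises(LfpError, match="no stimulation blocks"):
            burst_statistics(np.array([1.0, 2.0]), protocol, duration=30.0)

    def test_no_baseline_bursts_rejected(self):
        protocol = make_protocol("short")
        with pytest.raises(LfpError, match="baseline bursts"):
            burst_statistics(np.array([]), protocol)


class TestBandPowerEnvelope:
    def test_envelope_tracks_band_power(self, rng):
        fs = 3125.0
        t = np.arange(0, 30, 1 / fs)
        x = 2.0 * np.sin(2 * np.pi * 2 * t)
        env, env_fs = band_power_envelope(x, fs, band=(1.0, 4.0))
        # mean power of a 2-amplitude sinusoid is 2
        assert env[10:-10].mean() == pytest.approx(2.0, rel=0.05)
        assert env_fs == pytest.approx(10.0, rel=0.01)
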