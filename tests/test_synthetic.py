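"""Signal generation, noise model and SNR-control tests."""

import numpy as np
import pytest
from scipy import signal as sps

from nlbench.errors import ConfigurationError
from nlbench.head_model import project_sparse
from nlbench.synthetic import (
    DipoleConfiguration,
    EpochedEEG,
    NoiseModelSpec,
    SNRSpec,
    SourceSignalSpec,
    bandpass_epoch,
    baseline_sensor_variance,
    compute_snr_db,
    gaussian_pulse_source,
    load_dataset,
    resting_noise,
    save_dataset,
    scale_to_power_ratio,
    scale_to_snr,
    sensor_band_power,
    simulate_dataset,
    sinusoid_source,
)


class TestSinusoidSource:
    def test_known_values_noise_free(self):
        spec = SourceSignalSpec(kind="sinusoid", frequency=40.0, fs=1600.0, duration=0.1)
        s = sinusoid_source(spec)
        t = spec.times()
        assert s[0] == 0.0
        # quarter period of 40 Hz is 1/160 s
        i = int(round(1 / 160 * spec.fs))
        assert abs(t[i] - 1 / 160) < 1e-12
        assert abs(s[i] - 1.0) < 1e-9

    def test_pi_phase_lag_negates(self):
        base = SourceSignalSpec(kind="sinusoid", frequency=40.0, fs=1000.0)
        lagged = SourceSignalSpec(kind="sinusoid", frequency=40.0, fs=1000.0, phase_lag=np.pi)
        assert np.allclose(
            sinusoid_source(lagged), -sinusoid_source(base), atol=1e-12
        )

    def test_aliasing_rejected(self):
        with pytest.raises(ConfigurationError):
            SourceSignalSpec(kind="sinusoid", frequency=40.0, fs=70.0)


class TestGaussianPulseSource:
    def test_peak_equals_amplitude(self):
        spec = SourceSignalSpec(
            kind="gaussian_mixture", pulse_params=((-1.0, 0.11, 0.02),), fs=1000.0
        )
        s = gaussian_pulse_source(spec)
        assert abs(s[110] - (-1.0)) < 1e-9
        assert np.argmin(s) == 110

    def test_time_lag_is_pure_shift(self):
        spec = SourceSignalSpec(
            kind="gaussian_mixture", pulse_params=((-1.0, 0.11, 0.02),), fs=1000.0
        )
        s = gaussian_pulse_source(spec, time_lag=0.015)
        assert np.argmin(s) == 125

    def test_components_sum_pointwise(self):
        p1, p2 = (-1.0, 0.11, 0.02), (0.6, 0.4, 0.04)
        mk = lambda *p: SourceSignalSpec(kind="gaussian_mixture", pulse_params=p, fs=500.0)
        s = gaussian_pulse_source(mk(p1, p2))
        s1, s2 = gaussian_pulse_source(mk(p1)), gaussian_pulse_source(mk(p2))
        assert np.allclose(s, s1 + s2, atol=1e-12)

    def test_out_of_epoch_pulse_warns(self):
        spec = SourceSignalSpec(
            kind="gaussian_mixture", pulse_params=((1.0, 0.9, 0.02),), duration=1.0
        )
        with pytest.warns(UserWarning, match="outside"):
            gaussian_pulse_source(spec, time_lag=0.2)


class TestRestingNoise:
    def test_deterministic_under_seed(self, small_ctx):
        a = resting_noise(small_ctx.noise_model, small_ctx.leadfield, 2, 0.5, 250.0, seed=9)
        b = resting_noise(small_ctx.noise_model, small_ctx.leadfield, 2, 0.5, 250.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_average_reference_zero_mean(self, small_ctx):
        eeg = resting_noise(small_ctx.noise_model, small_ctx.leadfield, 2, 0.5, 250.0, seed=1)
        scale = np.abs(eeg.data).max()
        assert np.abs(eeg.data.mean(axis=1)).max() < 1e-9 * scale

    def test_spectral_slope_one_over_f(self, small_ctx):
        """Monte-Carlo periodogram oracle: with alpha=1 the 5 Hz/20 Hz power
        ratio should sit near the ideal value 4."""
        model = NoiseModelSpec(spectral_exponent=1.0, n_noise_dipoles=100, seed=3)
        eeg = resting_noise(model, small_ctx.leadfield, 200, 1.0, 250.0)
        freqs, pxx = sps.periodogram(eeg.data, fs=250.0, axis=-1)
        pxx = pxx.mean(axis=0)  # average over epochs -> (sensors, freqs)
        i5 = np.argmin(np.abs(freqs - 5.0))
        i20 = np.argmin(np.abs(freqs - 20.0))
        ratio = np.median(pxx[:, i5] / pxx[:, i20])
        assert 2.8 <= ratio <= 5.6

    def test_alpha_peak_visible(self, small_ctx):
        model = NoiseModelSpec(alpha_peak_gain=3.0, n_noise_dipoles=100, seed=3)
        eeg = resting_noise(model, small_ctx.leadfield, 100, 1.0, 250.0)
        freqs, pxx = sps.periodogram(eeg.data, fs=250.0, axis=-1)
        pxx = pxx.mean(axis=(0, 1))
        p10 = pxx[np.argmin(np.abs(freqs - 10.0))]
        # 1/f floor interpolated from neighbors away from the bump
        floor = np.sqrt(
            pxx[np.argmin(np.abs(freqs - 6.0))] * pxx[np.argmin(np.abs(freqs - 16.0))]
        )
        assert p10 / floor > 1.5

    def test_too_many_noise_dipoles(self, small_ctx):
        model = NoiseModelSpec(n_noise_dipoles=small_ctx.leadfield.n_voxels + 1)
        with pytest.raises(ConfigurationError):
            resting_noise(model, small_ctx.leadfield, 1, 0.1, 250.0)


class TestComputeSnrDb:
    def test_uniform_ratio_ten_gives_ten_db(self):
        v = np.full((4, 100), np.sqrt(10.0))
        assert abs(compute_snr_db(v, np.ones(4)) - 10.0) < 1e-12

    def test_single_sensor_ratio_hundred_gives_twenty_db(self):
        v = np.full((1, 50), 10.0)
        assert abs(compute_snr_db(v, np.ones(1)) - 20.0) < 1e-12

    def test_matches_brute_force_summation(self, rng):
        v = rng.normal(size=(5, 64))
        eta = rng.uniform(0.5, 2.0, size=5)
        total = 0.0
        for u in range(5):  # independent elementwise oracle
            mean_sq = sum(x * x for x in v[u]) / v.shape[1]
            total += mean_sq / eta[u]
        expected = 10 * np.log10(total / 5)
        assert abs(compute_snr_db(v, eta) - expected) < 1e-12

    def test_zero_signal_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert compute_snr_db(np.zeros((3, 10)), np.ones(3)) == -np.inf


class TestScaleToSnr:
    @pytest.fixture()
    def setup(self, small_ctx):
        lf = small_ctx.leadfield
        noise = resting_noise(small_ctx.noise_model, lf, 5, 1.0, 250.0, seed=2)
        idx = np.array([lf.grid.nearest_voxel((-60.0, -28.0, 6.0))])
        spec = SourceSignalSpec(kind="sinusoid", frequency=40.0, fs=250.0, duration=1.0)
        moments = sinusoid_source(spec)[None, :]
        return lf, noise, idx, moments

    def test_round_trip_to_hundredth_db(self, setup):
        lf, noise, idx, moments = setup
        for target in (19.0, 25.0, 31.0):
            k = scale_to_snr(moments, idx, lf, noise, SNRSpec(mode="snr_db", snr_db=target))
            achieved = compute_snr_db(
                project_sparse(lf, idx, k * moments), baseline_sensor_variance(noise)
            )
            assert abs(achieved - target) < 0.01

    def test_identity_when_target_equals_current(self, setup):
        lf, noise, idx, moments = setup
        current = compute_snr_db(
            project_sparse(lf, idx, moments), baseline_sensor_variance(noise)
        )
        k = scale_to_snr(moments, idx, lf, noise, SNRSpec(mode="snr_db", snr_db=current))
        assert abs(k - 1.0) < 1e-6

    def test_six_db_doubles_scale(self, setup):
        lf, noise, idx, moments = setup
        k1 = scale_to_snr(moments, idx, lf, noise, SNRSpec(mode="snr_db", snr_db=20.0))
        k2 = scale_to_snr(
            moments, idx, lf, noise, SNRSpec(mode="snr_db", snr_db=20.0 + 20 * np.log10(2))
        )
        assert abs(k2 / k1 - 2.0) < 1e-9


class TestScaleToPowerRatio:
    def test_own_power_reference_gives_unity(self, rng):
        fs = 250.0
        t = np.arange(500) / fs
        v = np.sin(2 * np.pi * 40 * t)[None, :] * rng.uniform(0.5, 2, size=(6, 1))
        ref = sensor_band_power(v, fs, 40.0)
        assert abs(scale_to_power_ratio(v, ref, fs, 1.0) - 1.0) < 1e-9

    def test_sqrt_two_amplitude_doubles_power(self, rng):
        fs = 250.0
        t = np.arange(500) / fs
        v = np.sin(2 * np.pi * 40 * t)[None, :] * rng.uniform(0.5, 2, size=(6, 1))
        p1 = sensor_band_power(v, fs, 40.0)
        p2 = sensor_band_power(np.sqrt(2) * v, fs, 40.0)
        assert abs(p2 / p1 - 2.0) < 1e-9

    def test_scale_verified_by_periodogram(self, rng):
        fs, ratio = 500.0, 1.3
        t = np.arange(1000) / fs
        v = np.sin(2 * np.pi * 40 * t)[None, :] * rng.uniform(0.5, 2, size=(4, 1))
        reference = 2.5 * sensor_band_power(v, fs, 40.0)
        k = scale_to_power_ratio(v, reference, fs, ratio)
        achieved = sensor_band_power(k * v, fs, 40.0)
        assert abs(achieved / (ratio * reference) - 1.0) < 0.01


class TestSimulateDataset:
    def test_single_mode_truth_and_lag_warning(self, small_ctx):
        with pytest.warns(UserWarning, match="lag ignored"):
            task, base, truth = simulate_dataset(
                DipoleConfiguration(mode="single", seeds=((-60.0, -28.0, 6.0),)),
                SourceSignalSpec(kind="sinusoid", fs=250.0, duration=1.0),
                np.pi,
                SNRSpec(mode="snr_db", snr_db=25.0),
                small_ctx.noise_model,
                small_ctx.leadfield,
                n_epochs=3,
                seed=4,
            )
        assert truth.seeds.shape == (1, 3)
        assert len(truth.member_indices) == 1

    def test_distributed_member_count_matches_lattice_oracle(self, full_ctx):
        """Cluster membership equals a brute-force lattice count; an interior
        12 mm-radius cluster on the 5 mm lattice holds 50-150 voxels."""
        grid = full_ctx.leadfield.grid

        def brute_count(seed_pos):  # independent loop-based oracle
            count = 0
            for p in grid.voxel_positions:
                if sum((a - b) ** 2 for a, b in zip(p, seed_pos)) <= 12.0**2:
                    count += 1
            return count

        interior = ((-30.0, -20.0, 10.0), (30.0, -20.0, 10.0))
        task, base, truth = simulate_dataset(
            DipoleConfiguration(mode="distributed", seeds=interior),
            SourceSignalSpec(kind="sinusoid", fs=1000.0, duration=1.0),
            0.0,
            SNRSpec(mode="snr_db", snr_db=25.0),
            full_ctx.noise_model,
            full_ctx.leadfield,
            n_epochs=2,
            seed=5,
        )
        for members, seed_pos in zip(truth.member_indices, interior):
            assert members.size == brute_count(seed_pos)
            assert 50 <= members.size <= 150
        # at the auditory seeds the grid boundary truncates the ball, so the
        # count still matches the oracle but may drop below the interior range
        task, base, truth = simulate_dataset(
            DipoleConfiguration(
                mode="distributed", seeds=((-60.0, -28.0, 6.0), (64.0, -24.0, 6.0))
            ),
            SourceSignalSpec(kind="sinusoid", fs=1000.0, duration=1.0),
            0.0,
            SNRSpec(mode="snr_db", snr_db=25.0),
            full_ctx.noise_model,
            full_ctx.leadfield,
            n_epochs=2,
            seed=5,
        )
        for members, seed_pos in zip(truth.member_indices, ((-60.0, -28.0, 6.0), (64.0, -24.0, 6.0))):
            assert members.size == brute_count(seed_pos)

    def test_task_minus_signal_equals_baseline(self, small_ctx):
        task, base, truth = simulate_dataset(
            DipoleConfiguration(mode="single", seeds=((-60.0, -28.0, 6.0),)),
            SourceSignalSpec(kind="sinusoid", fs=250.0, duration=1.0),
            0.0,
            SNRSpec(mode="snr_db", snr_db=25.0),
            small_ctx.noise_model,
            small_ctx.leadfield,
            n_epochs=3,
            seed=6,
        )
        spec = SourceSignalSpec(kind="sinusoid", fs=250.0, duration=1.0)
        moments = truth.scale * sinusoid_source(spec)[None, :]
        projected = project_sparse(small_ctx.leadfield, truth.member_indices[0], moments)
        # additive construction: equality up to float rounding of (noise + s) - s
        residual = task.data - projected[None, :, :] - base.data
        assert np.abs(residual).max() < 1e-12 * np.abs(task.data).max()

    def test_phase_pi_negates_right_hemisphere_waveform(self):
        left = sinusoid_source(SourceSignalSpec(kind="sinusoid", fs=1000.0))
        right = sinusoid_source(
            SourceSignalSpec(kind="sinusoid", fs=1000.0, phase_lag=np.pi)
        )
        assert np.allclose(right, -left, atol=1e-12)

    def test_bit_identical_under_same_seed(self, small_ctx):
        args = (
            DipoleConfiguration(mode="two_point", seeds=((-60.0, -28.0, 6.0), (64.0, -24.0, 6.0))),
            SourceSignalSpec(kind="gaussian_mixture", fs=250.0, duration=1.0),
            0.015,
            SNRSpec(mode="snr_db", snr_db=25.0),
            small_ctx.noise_model,
            small_ctx.leadfield,
        )
        a_task, a_base, a_truth = simulate_dataset(*args, n_epochs=2, seed=8)
        b_task, b_base, b_truth = simulate_dataset(*args, n_epochs=2, seed=8)
        assert np.array_equal(a_task.data, b_task.data)
        assert np.array_equal(a_base.data, b_base.data)
        assert a_truth.scale == b_truth.scale

    def test_dataset_round_trip(self, small_ctx, tmp_path):
        task, base, truth = simulate_dataset(
            DipoleConfiguration(mode="single", seeds=((-60.0, -28.0, 6.0),)),
            SourceSignalSpec(kind="sinusoid", fs=250.0, duration=0.5),
            0.0,
            SNRSpec(mode="snr_db", snr_db=25.0),
            small_ctx.noise_model,
            small_ctx.leadfield,
            n_epochs=2,
            seed=3,
        )
        path = tmp_path / "ds.h5"
        save_dataset(path, task, base, truth, {"note": "round trip"})
        t2, b2, tr2 = load_dataset(path)
        assert np.array_equal(t2.data, task.data)
        assert np.array_equal(b2.data, base.data)
        assert np.array_equal(tr2.member_indices[0], truth.member_indices[0])
        assert tr2.scale == truth.scale


class TestBandpass:
    def _carrier(self, sensors, freq, fs=1000.0, n=2000):
        t = np.arange(n) / fs
        data = np.sin(2 * np.pi * freq * t)[None, None, :].repeat(sensors.n_sensors, axis=1)
        return EpochedEEG(data=data, fs=fs, sensors=sensors)

    def test_in_band_amplitude_preserved(self, small_ctx):
        eeg = self._carrier(small_ctx.leadfield.sensors, 40.0)
        out = bandpass_epoch(eeg, 5.0, 48.0)
        mid = slice(500, 1500)  # avoid filter edges
        ratio = out.data[0, 0, mid].std() / eeg.data[0, 0, mid].std()
        assert abs(ratio - 1.0) < 0.02

    def test_out_of_band_attenuated(self, small_ctx):
        eeg = self._carrier(small_ctx.leadfield.sensors, 1.0)
        out = bandpass_epoch(eeg, 5.0, 48.0)
        mid = slice(500, 1500)
        assert out.data[0, 0, mid].std() < 0.10 * eeg.data[0, 0, mid].std()

    def test_idempotent_for_in_band_content(self, small_ctx):
        eeg = self._carrier(small_ctx.leadfield.sensors, 40.0)
        once = bandpass_epoch(eeg, 5.0, 48.0)
        twice = bandpass_epoch(once, 5.0, 48.0)
        mid = slice(500, 1500)
        ratio = twice.data[0, 0, mid].std() / once.data[0, 0, mid].std()
        assert abs(ratio - 1.0) < 0.02

    def test_invalid_band_rejected(self, small_ctx):
        eeg = self._carrier(small_ctx.leadfield.sensors, 10.0)
        with pytest.raises(ConfigurationError):
            bandpass_epoch(eeg, 48.0, 5.0)
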