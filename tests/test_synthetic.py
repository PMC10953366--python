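import numpy as np
import pytest

import pygrics as pg
from pygrics.encoding import EncodingOperator
from pygrics.fourier import cifft2
from pygrics.motion import predict_displacement
from pygrics.synthetic import sampled_phase_encodes


class TestPhantom:
    def test_deterministic_per_seed(self):
        a, _ = pg.make_phantom(64, seed=3)
        b, _ = pg.make_phantom(64, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_distinct_seeds_differ(self):
        a, _ = pg.make_phantom(64, seed=3)
        b, _ = pg.make_phantom(64, seed=4)
        assert np.any(a.data != b.data)

    def test_support_fraction_reasonable(self):
        for seed in (0, 1, 2):
            _, support = pg.make_phantom(64, seed=seed)
            assert 0.2 < support.mean() < 0.6

    def test_intensity_normalized(self):
        phantom, _ = pg.make_phantom(64, seed=5)
        assert phantom.data.min() == 0.0
        assert phantom.data.max() == 1.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            pg.make_phantom(16)


class TestResp:
    def test_noiseless_driftless_signal_is_periodic(self):
        sig = pg.make_resp(40.0, rate_hz=50.0, period_s=4.0, seed=0)
        n_period = 200  # 4 s at 50 Hz
        np.testing.assert_allclose(
            sig.values[:n_period], sig.values[n_period : 2 * n_period], atol=1e-10
        )

    def test_drift_recovered_by_correction(self):
        drift = (0.0, 0.01, 0.0005)
        clean = pg.make_resp(60.0, period_s=4.0, seed=1)
        drifted = pg.make_resp(60.0, period_s=4.0, drift_coeffs=drift, seed=1)
        from pygrics.resp import correct_drift

        corrected = correct_drift(drifted)
        ref = correct_drift(clean)  # same curve minus its own quadratic fit
        rms = np.sqrt(np.mean((corrected.values - ref.values) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(ref.values**2))

    def test_fundamental_frequency_matches_period(self):
        sig = pg.make_resp(120.0, rate_hz=50.0, period_s=4.0, seed=2)
        spec = np.abs(np.fft.rfft(sig.values - sig.values.mean()))
        freqs = np.fft.rfftfreq(sig.values.size, 1 / 50.0)
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.02)

    def test_sensor_rate_floor(self):
        with pytest.raises(ValueError):
            pg.make_resp(10.0, rate_hz=5.0)


class TestAlphaPatterns:
    def test_zero_amplitude_gives_zero_maps(self, geometry32):
        alpha = pg.make_alpha(geometry32, "vertical", 0.0)
        assert np.all(alpha.coeff == 0)

    def test_vertical_pattern_dominated_by_y(self):
        geo = pg.Geometry(64, 64)
        alpha = pg.make_alpha(geo, "vertical", 5.0, seed=0)
        assert np.mean(np.abs(alpha.coeff[0])) > 3 * np.mean(np.abs(alpha.coeff[1]))

    @pytest.mark.parametrize("pattern", ["vertical", "expansion", "shear"])
    def test_fields_are_smooth(self, pattern):
        geo = pg.Geometry(64, 64)
        alpha = pg.make_alpha(geo, pattern, 5.0, seed=1)
        for c in range(2):
            gy, gx = np.gradient(alpha.coeff[c])
            assert np.max(np.hypot(gy, gx)) < 1.0  # < 1 px change per pixel

    def test_unknown_pattern_rejected(self, geometry32):
        with pytest.raises(ValueError, match="pattern"):
            pg.make_alpha(geometry32, "spiral", 2.0)

    def test_amplitude_cap(self, geometry32):
        with pytest.raises(ValueError):
            pg.make_alpha(geometry32, "vertical", 9.0)


class TestCoilGenerator:
    def test_single_coil_is_flat_unit(self, geometry32):
        maps = pg.make_coils(1, geometry32)
        np.testing.assert_array_equal(maps.maps, np.ones((1, 32, 32)))

    def test_rss_normalized_everywhere(self, geometry32):
        maps = pg.make_coils(6, geometry32, seed=2)
        np.testing.assert_allclose(maps.rss(), 1.0, atol=1e-6)

    def test_distinct_seeds_give_distinct_maps(self, geometry32):
        a = pg.make_coils(4, geometry32, seed=1)
        b = pg.make_coils(4, geometry32, seed=2)
        assert np.any(np.abs(a.maps - b.maps) > 1e-3)


class TestSampling:
    def test_acceleration_two_with_center_counts(self):
        rows = sampled_phase_encodes(64, acceleration=2, n_center_lines=24)
        # 32 strided rows plus the 12 center rows not already on the stride
        assert rows.size == 32 + 12
        lo, hi = 32 - 12, 32 + 12
        center = rows[(rows >= lo) & (rows < hi)]
        assert center.size == 24  # calibration band fully sampled
        outside = rows[(rows < lo) | (rows >= hi)]
        assert np.all(np.diff(outside) % 2 == 0)


class TestSimulateAcquisition:
    def test_static_flat_coil_adjoint_recovers_phantom(self):
        phantom, _ = pg.make_phantom(32, seed=6)
        coils = pg.make_coils(1, phantom.geometry)
        resp = pg.make_resp(40.0, seed=6)
        proto = pg.Protocol(lines_per_shot=1, shot_interval_s=40.0 / 32)
        ks, _ = pg.simulate_acquisition(
            phantom, pg.AlphaMaps.zeros(phantom.geometry), resp, coils, proto, seed=6
        )
        grid = np.zeros((32, 32), complex)
        grid[ks.line_meta.phase_encode_index, :] = ks.samples[0]
        np.testing.assert_allclose(cifft2(grid).real, phantom.data[0], atol=1e-6)

    def test_binned_mode_consistent_with_encoding_operator(self, moving_dataset):
        # the module-consistency oracle: E built from the same alpha, states
        # and coils reproduces the simulated noiseless k-space to 1e-10
        ks = moving_dataset["ks"]
        truth = moving_dataset["truth"]
        coils = moving_dataset["coils"]
        sv = np.unique(truth.shot_sensor_values)
        remap = {v: i for i, v in enumerate(sv)}
        states = np.array([remap[v] for v in truth.shot_sensor_values])
        disps = [predict_displacement(truth.alpha, float(s)) for s in sv]
        op = EncodingOperator(
            coils, states, ks.line_meta.phase_encode_index, disps, ks.geometry
        )
        predicted = op.forward(truth.phantom.data[0].astype(complex))
        measured = op.pack_measurements(ks.samples)
        err = np.linalg.norm(predicted - measured) / np.linalg.norm(measured)
        assert err < 1e-10

    def test_motion_blurs_the_zero_motion_reconstruction(self, moving_dataset):
        ks = moving_dataset["ks"]
        coils = moving_dataset["coils"]
        static_grid = np.zeros((64, 64), complex)
        moving_grid = np.zeros((64, 64), complex)
        phantom = moving_dataset["phantom"]
        resp = moving_dataset["resp"]
        proto = moving_dataset["protocol"]
        ks0, _ = pg.simulate_acquisition(
            phantom, pg.AlphaMaps.zeros(phantom.geometry), resp, coils, proto, seed=7
        )
        for grid, data in ((static_grid, ks0), (moving_grid, ks)):
            imgs = np.zeros((4, 64, 64), complex)
            imgs[:, data.line_meta.phase_encode_index, :] = data.samples
            grid += np.sum(np.conj(coils.maps) * cifft2(imgs), axis=0)
        si_static = pg.sharpness_index(np.abs(static_grid))
        si_moving = pg.sharpness_index(np.abs(moving_grid))
        assert si_moving < si_static

    def test_deterministic_per_seed(self, moving_dataset):
        d = moving_dataset
        ks2, _ = pg.simulate_acquisition(
            d["phantom"], d["alpha"], d["resp"], d["coils"], d["protocol"],
            seed=7, support=d["support"], binned_states=6,
        )
        np.testing.assert_array_equal(ks2.samples, d["ks"].samples)

    def test_respiration_must_cover_acquisition(self):
        phantom, _ = pg.make_phantom(32, seed=8)
        coils = pg.make_coils(1, phantom.geometry)
        resp = pg.make_resp(10.0, seed=8)
        proto = pg.Protocol(lines_per_shot=1, shot_interval_s=1.0)
        with pytest.raises(ValueError, match="shorter"):
            pg.simulate_acquisition(
                phantom, pg.AlphaMaps.zeros(phantom.geometry), resp, coils, proto
            )
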