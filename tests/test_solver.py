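import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import pygrics as pg
from pygrics.encoding import EncodingOperator
from pygrics.fourier import cifft2
from pygrics.motion import AlphaMaps, DisplacementField, predict_displacement
from pygrics.solver import (
    GricsConfig,
    MotionLinearization,
    PROJECTOR_REG,
    cg_solve,
    grad_reg_normal,
    make_range_projector,
    solve_motion_update,
    solve_reconstruction,
)


def smooth_u(rng, n, amp):
    u = np.stack([gaussian_filter(rng.normal(size=(n, n)), n * 0.1) for _ in range(2)])
    return DisplacementField(u * amp / max(np.abs(u).max(), 1e-12))


def small_operator(rng, n=12, n_coils=3, n_states=2, amp=2.0):
    geo = pg.Geometry(n, n)
    coils = pg.make_coils(n_coils, geo, seed=int(rng.integers(1 << 16)))
    states = rng.integers(0, n_states, n)
    disps = [smooth_u(rng, n, amp) for _ in range(n_states)]
    return EncodingOperator(coils, states, np.arange(n), disps, geo)


class TestCg:
    def test_matches_direct_solve_on_spd_system(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(20, 20))
        A = M @ M.T + 20 * np.eye(20)
        b = rng.normal(size=20)
        x, hist = cg_solve(lambda v: A @ v, b, maxit=200, tol=1e-12)
        np.testing.assert_allclose(x, np.linalg.solve(A, b), rtol=1e-8)
        assert hist[-1] < 1e-12

    def test_zero_rhs_returns_zero(self):
        x, hist = cg_solve(lambda v: v, np.zeros(5), maxit=10, tol=1e-6)
        assert np.all(x == 0) and hist == [0.0]


class TestSolveReconstruction:
    def test_zero_data_gives_zero_image(self):
        op = small_operator(np.random.default_rng(1))
        rho = solve_reconstruction(op, np.zeros(op.n_out, complex), 1e-4, 10, 1e-3)
        assert np.all(rho == 0)

    def test_unitary_case_recovers_inverse_fft(self):
        rng = np.random.default_rng(2)
        n = 8
        geo = pg.Geometry(n, n)
        coils = pg.CoilMaps(np.ones((1, n, n), complex))
        u0 = DisplacementField(np.zeros((2, n, n)))
        op = EncodingOperator(coils, np.zeros(n, np.int64), np.arange(n), [u0], geo)
        m = rng.normal(size=op.n_out) + 1j * rng.normal(size=op.n_out)
        rho = solve_reconstruction(op, m, 1e-12, 50, 1e-10)
        np.testing.assert_allclose(rho, cifft2(m.reshape(n, n)), atol=1e-6)

    def test_matches_dense_normal_equations_solve(self):
        # CG vs explicit dense assembly of (E^H E + lambda I) rho = E^H m
        rng = np.random.default_rng(3)
        op = small_operator(rng, n=12, n_coils=3, n_states=2)
        m = rng.normal(size=op.n_out) + 1j * rng.normal(size=op.n_out)
        lam = 1e-4
        E = op.as_dense()
        A = E.conj().T @ E + lam * np.eye(144)
        expect = np.linalg.solve(A, E.conj().T @ m)
        got = solve_reconstruction(op, m, lam, maxit=300, tol=1e-8).ravel()
        assert np.linalg.norm(got - expect) / np.linalg.norm(expect) < 1e-3

    def test_non_finite_data_rejected(self):
        op = small_operator(np.random.default_rng(4))
        bad = np.zeros(op.n_out, complex)
        bad[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            solve_reconstruction(op, bad, 1e-4, 5, 1e-3)


class TestSolveMotionUpdate:
    def test_consistent_data_gives_zero_update(self):
        rng = np.random.default_rng(5)
        n = 12
        geo = pg.Geometry(n, n)
        coils = pg.make_coils(3, geo, seed=6)
        alpha = AlphaMaps.zeros(geo)
        sv = np.array([0.0, 1.0])
        disps = [predict_displacement(alpha, s) for s in sv]
        op = EncodingOperator(coils, rng.integers(0, 2, n), np.arange(n), disps, geo)
        rho = (rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)))
        m = op.forward(rho)  # residual is exactly zero, alpha = 0
        da = solve_motion_update(op, m, rho, alpha, sv, 0.25, 10, 1e-2)
        assert np.max(np.abs(da)) < 1e-12

    def test_all_zero_image_rejected(self):
        rng = np.random.default_rng(7)
        op = small_operator(rng, n=8)
        with pytest.raises(ValueError, match="empty image"):
            solve_motion_update(
                op, np.zeros(op.n_out, complex), np.zeros((8, 8), complex),
                AlphaMaps.zeros(pg.Geometry(8, 8)), np.array([0.0, 1.0]),
                0.25, 5, 1e-2,
            )

    def test_recovers_global_translation_direction(self, phantom64):
        # 1-parameter oracle: data from a constant x-translation proportional
        # to s; the update's constant x-component should dominate y
        n = 32
        phantom, support = pg.make_phantom(n, seed=3)
        geo = phantom.geometry
        coils = pg.make_coils(3, geo, seed=1)
        a_true = np.zeros((2, n, n))
        a_true[1] = 1.5
        sv = np.array([0.0, 1.0])
        states = (np.arange(n) % 2).astype(np.int64)
        op_true = EncodingOperator(
            coils, states, np.arange(n),
            [predict_displacement(AlphaMaps(a_true, geo), s) for s in sv], geo,
        )
        img = phantom.data[0].astype(complex)
        m = op_true.forward(img)
        alpha0 = AlphaMaps.zeros(geo)
        op0 = EncodingOperator(
            coils, states, np.arange(n),
            [predict_displacement(alpha0, s) for s in sv], geo,
        )
        da = solve_motion_update(op0, m, img, alpha0, sv, 0.25, 30, 1e-4)
        mean_dx = da[1][support].mean()
        mean_dy = abs(da[0][support].mean())
        assert mean_dx > 0.5 * 1.5 * 0.5  # moves toward truth
        assert mean_dy < 0.3 * mean_dx

    def test_matches_dense_solve_of_reduced_system(self):
        # dense oracle: assemble L and the regularized range projector
        # explicitly, solve the same projected normal equations directly
        rng = np.random.default_rng(8)
        n = 8
        geo = pg.Geometry(n, n)
        coils = pg.make_coils(2, geo, seed=9)
        sv = np.array([0.0, 0.8])
        states = (np.arange(n) % 2).astype(np.int64)
        alpha = AlphaMaps(0.2 * rng.normal(size=(2, n, n)), geo)
        disps = [predict_displacement(alpha, s) for s in sv]
        op = EncodingOperator(coils, states, np.arange(n), disps, geo)
        rho = gaussian_filter(rng.normal(size=(n, n)), 1.5) + 0j
        m = op.forward(rho) + 0.05 * (
            rng.normal(size=op.n_out) + 1j * rng.normal(size=op.n_out)
        )
        mu = 0.25

        lin = MotionLinearization(op, rho, sv)
        E = op.as_dense()
        P = E @ np.linalg.solve(
            E.conj().T @ E + PROJECTOR_REG * np.eye(n * n), E.conj().T
        )
        L = lin.as_dense()
        mu_eff = mu * lin.mean_diag()
        G = np.zeros((2 * n * n, 2 * n * n))
        for i in range(2 * n * n):
            e = np.zeros(2 * n * n)
            e[i] = 1.0
            G[:, i] = grad_reg_normal(e, (n, n))
        A = (L.conj().T @ (np.eye(op.n_out) - P) @ L).real + mu_eff * G
        eps = m - op.forward(rho)
        b = (L.conj().T @ ((np.eye(op.n_out) - P) @ eps)).real - mu_eff * (
            G @ alpha.coeff.ravel()
        )
        expect = np.linalg.solve(A, b)
        got = solve_motion_update(
            op, m, rho, alpha, sv, mu, maxit=400, tol=1e-8,
            proj_maxit=200, proj_tol=1e-10,
        ).ravel()
        assert np.linalg.norm(got - expect) / np.linalg.norm(expect) < 1e-2


class TestRangeProjector:
    def test_annihilates_range_of_encoding_operator(self):
        rng = np.random.default_rng(10)
        op = small_operator(rng, n=12)
        proj = make_range_projector(op, maxit=100, tol=1e-10)
        x = rng.normal(size=(12, 12)) + 1j * rng.normal(size=(12, 12))
        y = op.forward(x)
        assert np.linalg.norm(proj(y)) < 1e-2 * np.linalg.norm(y)


class TestRunGrics:
    def test_static_signal_reduces_to_plain_sense(self, phantom64):
        phantom, _ = phantom64
        coils = pg.make_coils(4, phantom.geometry, seed=7)
        proto = pg.Protocol(lines_per_shot=1, shot_interval_s=150.0 / 64)
        resp = pg.RespSignal(np.full(7600, 3.3), 50.0)
        ks, _ = pg.simulate_acquisition(
            phantom, pg.AlphaMaps.zeros(phantom.geometry), resp, coils, proto, seed=7
        )
        res = pg.run_grics(ks, resp, GricsConfig(n_states=6))
        assert np.max(np.abs(res.corrected.data - res.uncorrected.data)) < 1e-6
        assert np.max(np.abs(res.alpha.coeff)) < 0.01  # 1% of 1 px

    def test_residuals_monotone_within_levels(self, grics_result):
        for level in grics_result.residual_history:
            r = level["residuals"]
            for a, b in zip(r, r[1:]):
                assert b <= a * 1.01  # <=1% jitter

    def test_motion_correction_halves_rmse(self, grics_result, moving_dataset, rmse_fn):
        gt = moving_dataset["phantom"].data[0]
        rc = rmse_fn(grics_result.corrected.data[0], gt)
        ru = rmse_fn(grics_result.uncorrected.data[0], gt)
        assert rc <= 0.5 * ru

    def test_recovered_displacement_correlates_with_truth(
        self, grics_result, moving_dataset
    ):
        support = moving_dataset["support"]
        s_ref = grics_result.state_values[-1]
        ur = grics_result.alpha.coeff * s_ref
        ut = moving_dataset["truth"].alpha.coeff * s_ref
        corr = np.corrcoef(
            np.concatenate([ur[0][support], ur[1][support]]),
            np.concatenate([ut[0][support], ut[1][support]]),
        )[0, 1]
        assert corr >= 0.9

    def test_recon_only_requires_alpha(self, moving_dataset):
        with pytest.raises(ValueError, match="alpha_init"):
            pg.run_grics(
                moving_dataset["ks"], moving_dataset["resp"],
                GricsConfig(n_states=6), motion_update=False,
            )

    def test_recon_only_reuse_matches_full_run(self, grics_result, moving_dataset):
        # alpha round-tripped through a finer geometry, then recon-only
        geo = moving_dataset["phantom"].geometry
        fine = pg.Geometry(96, 96, (geo.ny / 96, geo.nx / 96), geo.slice_thickness)
        a = pg.interpolate_alpha(pg.interpolate_alpha(grics_result.alpha, fine), geo)
        res = pg.run_grics(
            moving_dataset["ks"], moving_dataset["resp"],
            GricsConfig(n_states=6), alpha_init=a, motion_update=False,
        )
        num = np.linalg.norm(np.abs(res.corrected.data) - np.abs(grics_result.corrected.data))
        den = np.linalg.norm(np.abs(grics_result.corrected.data))
        assert num / den <= 0.05


@pytest.fixture(scope="module")
def three_slice_dataset():
    geo = None
    chunks = []
    resp = pg.make_resp(80.0, period_s=4.1, seed=11)
    for s in range(3):
        phantom, support = pg.make_phantom(32, seed=20 + s)
        geo = phantom.geometry
        alpha = pg.make_alpha(geo, "vertical", 3.0, seed=20 + s)
        coils = pg.make_coils(3, geo, seed=20 + s)
        proto = pg.Protocol(lines_per_shot=1, shot_interval_s=80.0 / 32)
        ks, _ = pg.simulate_acquisition(
            phantom, alpha, resp, coils, proto, seed=20 + s,
            binned_states=4, slice_index=s,
        )
        chunks.append(ks)
    samples = np.concatenate([c.samples for c in chunks], axis=1)
    meta = pg.LineMeta(
        np.concatenate([c.line_meta.phase_encode_index for c in chunks]),
        np.concatenate([c.line_meta.slice_index for c in chunks]),
        np.concatenate([c.line_meta.timestamp for c in chunks]),
    )
    return pg.KSpaceData(samples, meta, geo), resp


class TestSliceParallel:
    def test_parallel_bit_identical_to_sequential(self, three_slice_dataset):
        ks, resp = three_slice_dataset
        cfg = GricsConfig(n_states=4, n_levels=2, n_fixed_point=1, n_center_lines=16)
        seq = pg.run_grics(ks, resp, cfg)
        par = pg.reconstruct_slices_parallel(ks, resp, cfg, n_workers=4)
        np.testing.assert_array_equal(seq.corrected.data, par.corrected.data)
        np.testing.assert_array_equal(seq.uncorrected.data, par.uncorrected.data)

    def test_each_slice_matches_its_own_run(self, three_slice_dataset):
        ks, resp = three_slice_dataset
        cfg = GricsConfig(n_states=4, n_levels=2, n_fixed_point=1, n_center_lines=16)
        stacked = pg.run_grics(ks, resp, cfg)
        solo = pg.run_grics(ks.for_slice(1), resp, cfg)
        np.testing.assert_array_equal(stacked.corrected.data[1], solo.corrected.data[0])
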