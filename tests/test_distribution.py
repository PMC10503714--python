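"""Grid construction, NNLS core, design matrices, systematic-noise
elimination and the regularized inversion."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.optimize

from svengine.distribution import (
    DistributionResult,
    NoiseProjector,
    RegularizationSpec,
    SGrid,
    build_design_matrix,
    build_grid,
    fit_linear,
    fold_noise,
    grid_from_file,
    integrate_distribution,
    nnls,
    write_sdist,
)
from svengine.lamm import CellGeometry, SolutionConditions, nondiffusing_profile
from svengine.scan_io import Scan, ScanSet

WATER = SolutionConditions(vbar=0.73, density=0.99823, viscosity=0.01002, temperature=293.15)
GEOM = CellGeometry(meniscus=6.0, bottom=7.2)
RPM = 50000.0


def toy_scanset(times=(0.0, 1200.0, 2400.0), n_points=60, signal=None):
    radii = np.linspace(6.05, 7.15, n_points)
    scans = []
    eps = 1e-9  # scan times must be strictly increasing and positive-ordered
    for k, t in enumerate(times):
        y = np.zeros(n_points) if signal is None else np.asarray(signal[k], dtype=float)
        scans.append(
            Scan(
                description=f"toy {k}",
                data_type="R",
                cell=1,
                temperature=20.0,
                rpm=RPM,
                time_s=float(t) if t > 0 else eps * (k + 1),
                w2t=(RPM * np.pi / 30) ** 2 * float(t),
                wavelength=280.0,
                radii=radii,
                signal=y,
            )
        )
    return ScanSet(scans=scans, channel="ra2")


class TestGrids:
    def test_linear_progression(self):
        assert np.allclose(build_grid(1, 10, 10).values, np.arange(1.0, 11.0))

    def test_log_progression(self):
        assert np.allclose(build_grid(1, 100, 3, log_spaced=True).values, [1, 10, 100])

    def test_two_node_grid_is_endpoints(self):
        assert np.array_equal(build_grid(2.5, 9.0, 2).values, [2.5, 9.0])

    def test_invalid_ranges_rejected(self):
        for args in [(0, 10, 5), (5, 5, 5), (1, 10, 1)]:
            with pytest.raises(ValueError):
                build_grid(*args)

    def test_grid_file_round_trip(self, tmp_path):
        p = tmp_path / "sdist.ra2"
        p.write_text("1\n2\n5\n")
        assert np.array_equal(grid_from_file(p).values, [1.0, 2.0, 5.0])
        g = build_grid(1.5, 20.0, 17, log_spaced=True)
        back = grid_from_file(write_sdist(g, tmp_path / "sdist2.ra2"))
        assert np.allclose(back.values, g.values, rtol=1e-7)

    def test_grid_file_errors(self, tmp_path):
        bad_order = tmp_path / "a.ra2"
        bad_order.write_text("2\n1\n")
        with pytest.raises(ValueError):
            grid_from_file(bad_order)
        bad_value = tmp_path / "b.ra2"
        bad_value.write_text("1\nxyz\n")
        with pytest.raises(ValueError):
            grid_from_file(bad_value)


def brute_force_nnls(A, b):
    """Exhaustive oracle: best solution over all active/passive sign patterns."""
    n = A.shape[1]
    best_x, best_ssr = np.zeros(n), float(b @ b)
    for pattern in itertools.product([False, True], repeat=n):
        idx = [i for i, on in enumerate(pattern) if on]
        if not idx:
            continue
        sol, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
        if np.any(sol < 0):
            continue
        x = np.zeros(n)
        x[idx] = sol
        ssr = float(np.sum((A @ x - b) ** 2))
        if ssr < best_ssr - 1e-12:
            best_x, best_ssr = x, ssr
    return best_x, best_ssr


class TestNNLS:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_sign_pattern_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(5, 3))
        b = rng.normal(size=5)
        x = nnls(A.T @ A, A.T @ b)
        x_ref, ssr_ref = brute_force_nnls(A, b)
        assert float(np.sum((A @ x - b) ** 2)) == pytest.approx(ssr_ref, abs=1e-10)
        assert np.allclose(x, x_ref, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = rng.normal(size=(40, 12)) + 0.3
        b = rng.normal(size=40)
        x = nnls(A.T @ A, A.T @ b)
        x_ref, _ = scipy.optimize.nnls(A, b)
        assert np.allclose(x, x_ref, atol=1e-7)

    def test_kkt_conditions_at_exit(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(30, 8))
        b = rng.normal(size=30)
        G, h = A.T @ A, A.T @ b
        x = nnls(G, h)
        grad = h - G @ x  # negative gradient
        assert np.all(x >= 0)
        assert np.all(grad[x == 0] <= 1e-8)  # inactive: no descent direction
        assert np.allclose(grad[x > 0], 0, atol=1e-8)  # active: stationary


class TestDesignMatrix:
    def test_shape_matches_points_and_grid(self):
        ss = toy_scanset()
        grid = build_grid(2, 10, 9)
        dm = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss, n_radial=80)
        assert dm.X.shape == (ss.n_points, 9)

    def test_initial_condition_rows_are_unity(self):
        """Rows at t ~ 0 sample the uniform unit initial condition."""
        ss = toy_scanset(times=(0.0, 600.0))
        grid = build_grid(2, 10, 5)
        dm = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss, n_radial=80)
        first = dm.X[dm.scan_slices[0], :]
        assert np.allclose(first, 1.0, atol=1e-6)

    def test_lsgofs_columns_equal_closed_form(self):
        ss = toy_scanset(times=(600.0, 2400.0))
        grid = build_grid(2, 10, 5)
        dm = build_design_matrix(grid, "lsgofs", 1.0, WATER, GEOM, RPM, ss)
        for j, s in enumerate(grid.values):
            for k, sl in enumerate(dm.scan_slices):
                expected = nondiffusing_profile(s, GEOM, RPM, ss.scans[k].time_s, ss.scans[k].radii)
                assert np.array_equal(dm.X[sl, j], expected)


class TestFitLinear:
    def test_single_species_self_consistency(self):
        """Noiseless data built from one grid node's kernel: the inversion
        returns the loading at that node and (numerically) nothing elsewhere."""
        ss0 = toy_scanset(times=(600.0, 1800.0, 3000.0))
        grid = build_grid(2, 10, 9)  # spacing 1 S; s0 = 5 S is node 3
        dm0 = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss0, n_radial=120)
        loading = 0.8
        j0 = 3
        signal = [loading * dm0.X[sl, j0] for sl in dm0.scan_slices]
        ss = toy_scanset(times=(600.0, 1800.0, 3000.0), signal=signal)
        dm = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss, n_radial=120)
        res = fit_linear(ss, dm, None, {})
        w = np.trapezoid(res.c, grid.values)
        assert w == pytest.approx(loading, rel=1e-3)
        peak = res.c[j0]
        others = np.delete(res.c, j0)
        assert np.all(others < 1e-3 * peak)

    def test_pure_ti_profile_absorbed_by_noise_model(self):
        ss0 = toy_scanset(times=(600.0, 1800.0))
        ti = 0.3 * np.sin(np.linspace(0, 3, ss0.scans[0].n_points))
        ss = toy_scanset(times=(600.0, 1800.0), signal=[ti, ti])
        grid = build_grid(2, 10, 5)
        dm = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss, n_radial=80)
        res = fit_linear(ss, dm, None, {"ti": True})
        assert np.allclose(res.c, 0.0, atol=1e-10)
        rms = np.sqrt(np.mean((res.ti_noise - ti) ** 2))
        assert rms < 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_projection_equals_joint_noise_solve(self, seed):
        """Eliminating TI/RI/baseline by orthogonal projection must give the
        same fitted values as jointly solving for unbounded noise unknowns
        (oracle: NNLS on [X | Q | -Q], free coefficients split into +/-)."""
        rng = np.random.default_rng(seed)
        n_scans, n_radii, n_grid = 3, 12, 4
        radii = np.linspace(6.1, 7.0, n_radii)
        times = [600.0 * (k + 1) for k in range(n_scans)]
        signal = [rng.normal(0.5, 0.2, size=n_radii) for _ in range(n_scans)]
        ss = ScanSet(
            scans=[
                Scan("r", "R", 1, 20.0, RPM, t, (RPM * np.pi / 30) ** 2 * t, 280.0,
                     radii, y)
                for t, y in zip(times, signal)
            ],
            channel="ra2",
        )
        grid = build_grid(2, 10, n_grid)
        dm = build_design_matrix(grid, "lsgofs", 1.0, WATER, GEOM, RPM, ss)
        flags = {"ti": True, "ri": True, "baseline": True}
        res = fit_linear(ss, dm, None, flags)

        proj = NoiseProjector(dm.radii, dm.scan_slices, True, True, True)
        from svengine.distribution import _trapezoid_weights

        Xw = dm.X * _trapezoid_weights(grid.values)
        A = np.hstack([Xw, proj.Q, -proj.Q])
        y = np.concatenate(signal)
        sol, _ = scipy.optimize.nnls(A, y, maxiter=10 * A.shape[1])
        fitted_oracle = A @ sol
        rms = np.sqrt(np.mean((fitted_oracle - res.fitted) ** 2))
        assert rms < 1e-8

    def test_ssr_monotone_in_lambda_and_breadth_in_pvalue(self, small_fit):
        """More regularization can only worsen SSR; a larger p-value can only
        broaden the distribution."""
        scanset, dm, _ = small_fit
        flags = {"ti": True, "ri": True, "baseline": False}
        ssrs, spreads = [], []
        for p in (0.55, 0.68, 0.90, 0.99):
            res = fit_linear(scanset, dm, RegularizationSpec("Tikhonov", p), flags)
            ssrs.append(res.ssr)
            s = dm.grid.values
            total = np.trapezoid(res.c, s)
            mean = np.trapezoid(res.c * s, s) / total
            spreads.append(np.sqrt(np.trapezoid(res.c * (s - mean) ** 2, s) / total))
        assert all(b >= a * (1 - 1e-9) for a, b in zip(ssrs, ssrs[1:]))
        assert all(b >= a * (1 - 1e-6) for a, b in zip(spreads, spreads[1:]))

    def test_maxent_regularization_runs_and_smooths(self, small_fit):
        scanset, dm, _ = small_fit
        flags = {"ti": True, "ri": True, "baseline": False}
        res0 = fit_linear(scanset, dm, None, flags)
        res = fit_linear(scanset, dm, RegularizationSpec("maxent", 0.68), flags)
        assert np.all(res.c >= 0)
        assert res.ssr >= res0.ssr * (1 - 1e-9)

    def test_zero_data_returns_zero_distribution(self):
        ss = toy_scanset(times=(600.0, 1800.0))
        grid = build_grid(2, 10, 5)
        dm = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss, n_radial=80)
        with pytest.warns(UserWarning):
            res = fit_linear(ss, dm, RegularizationSpec("Tikhonov", 0.68), {})
        assert np.array_equal(res.c, np.zeros(5))

    def test_fit_is_deterministic(self, small_fit):
        """Repeating the same linear fit reproduces the distribution exactly
        (no hidden randomness; scan order is normalized by the loader)."""
        scanset, dm, _ = small_fit
        flags = {"ti": True, "ri": True, "baseline": False}
        res1 = fit_linear(scanset, dm, None, flags)
        res2 = fit_linear(scanset, dm, None, flags)
        assert np.array_equal(res1.c, res2.c)
        assert res1.ssr == res2.ssr


class TestFoldAndIntegrate:
    def _two_peak_result(self):
        s = np.arange(2.0, 12.01, 0.25)
        c = np.zeros_like(s)
        c[np.argmin(np.abs(s - 6.5))] = 0.3 / 0.25
        c[np.argmin(np.abs(s - 9.5))] = 0.1 / 0.25
        return DistributionResult(
            grid=SGrid(s), c=c, ti_noise=np.zeros(2), ti_radii=np.array([6.0, 7.0]),
            ri_noise=np.zeros(2), baseline=0.0, ssr=0.0, lam=0.0,
        )

    def test_two_peak_window_fraction_and_weighted_mean(self):
        res = self._two_peak_result()
        frac, sw, load = integrate_distribution(res, 5.0, 8.0)
        assert frac == pytest.approx(75.0, abs=1e-9)
        assert sw == pytest.approx(6.5, abs=1e-9)
        _, sw_all, _ = integrate_distribution(res, 2.0, 12.0)
        assert sw_all == pytest.approx(7.25, abs=1e-9)

    def test_full_range_is_total(self):
        res = self._two_peak_result()
        frac, _, load = integrate_distribution(res, 2.0, 12.0)
        assert frac == pytest.approx(100.0)
        assert load == pytest.approx(0.4, abs=1e-12)

    def test_empty_window_flagged(self):
        res = self._two_peak_result()
        frac, sw, load = integrate_distribution(res, 3.0, 4.0)
        assert frac == 0.0 and load == 0.0 and np.isnan(sw)
        with pytest.raises(ValueError):
            integrate_distribution(res, 8.0, 5.0)

    def test_fold_noise_reconstruction_identity(self, small_fit):
        scanset, dm, dist = small_fit
        ti_text, ri_text = fold_noise(dist, scanset)
        assert len(ri_text.strip().splitlines()) == len(scanset)
        # X c + TI + RI + b reproduces the stored fitted values
        from svengine.distribution import NoiseProjector, _trapezoid_weights

        model = dm.X @ (dist.c * _trapezoid_weights(dm.grid.values))
        proj = NoiseProjector(dm.radii, dm.scan_slices, True, True, False)
        recon = model + dist.ti_noise[proj.radius_idx]
        for k, sl in enumerate(dm.scan_slices):
            recon[sl] += dist.ri_noise[k]
        recon += dist.baseline
        assert np.allclose(recon, dist.fitted, atol=1e-10)

    def test_fold_noise_disabled_ti_is_zero(self):
        ss = toy_scanset(times=(600.0, 1800.0), signal=[np.full(60, 0.2)] * 2)
        grid = build_grid(2, 10, 5)
        dm = build_design_matrix(grid, "cofs", 1.3, WATER, GEOM, RPM, ss, n_radial=80)
        res = fit_linear(ss, dm, None, {"ri": True})
        ti_text, _ = fold_noise(res, ss)
        values = [float(line.split("\t")[1]) for line in ti_text.strip().splitlines()]
        assert all(v == 0.0 for v in values)
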