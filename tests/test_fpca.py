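"""Sparse FPCA: smoothers, eigenstructure, BLUP scores, reconstructions."""

import numpy as np
import pandas as pd
import pytest

from declinefpca import fpca as fp
from declinefpca import synthetic as sg

GRID = fp.DEFAULT_GRID


def records_from(ages_by_pid, values_by_pid):
    rows = []
    for pid in ages_by_pid:
        for a, v in zip(ages_by_pid[pid], values_by_pid[pid]):
            rows.append((pid, 2000, "A", a, v))
    return pd.DataFrame(rows, columns=["patient_id", "year", "center_id",
                                       "encounter_age", "fev1pp"])


def quad_weights(grid):
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


class TestEstimateMean:
    def test_constant_data(self):
        ages = np.tile(np.linspace(6, 21, 40), 3)
        rec = records_from({"P": ages}, {"P": np.full_like(ages, 84.0)})
        np.testing.assert_allclose(fp.estimate_mean(rec, GRID), 84.0, atol=1e-8)

    def test_linear_data_reproduced(self):
        ages = np.tile(np.linspace(6, 21, 60), 2)
        vals = 100.0 - 1.5 * ages
        rec = records_from({"P": ages}, {"P": vals})
        np.testing.assert_allclose(fp.estimate_mean(rec, GRID),
                                   100.0 - 1.5 * GRID, atol=1e-3)

    def test_recovers_generator_mean(self, default_run):
        interior = (GRID >= 7.0) & (GRID <= 20.0)
        err = np.abs(default_run.model.mean_curve - sg.default_mean(GRID))
        assert err[interior].max() < 2.0

    def test_grid_outside_range_raises(self):
        ages = np.linspace(8, 15, 30)
        rec = records_from({"P": ages}, {"P": np.full_like(ages, 80.0)})
        with pytest.raises(ValueError, match="outside"):
            fp.estimate_mean(rec, GRID)


class TestEstimateCovariance:
    def test_rank_one_noiseless(self):
        rng = np.random.default_rng(0)
        phi = np.sin(np.pi * (GRID - 6) / 15)
        phi = phi / np.sqrt(np.trapezoid(phi**2, GRID))
        ages = {f"P{i}": GRID for i in range(150)}
        xis = rng.normal(scale=3.0, size=150)
        vals = {f"P{i}": xis[i] * phi for i in range(150)}
        rec = records_from(ages, vals)
        surf, _, sigma2 = fp.estimate_covariance(rec, np.zeros_like(GRID), GRID)
        target = xis.var(ddof=0) * np.outer(phi, phi)
        assert np.linalg.norm(surf - target) / np.linalg.norm(target) < 0.15
        assert sigma2 < 0.2

    def test_pure_noise(self):
        rng = np.random.default_rng(1)
        noise_sd = 4.0
        ages = {f"P{i}": np.sort(rng.uniform(6, 21, 12)) for i in range(300)}
        vals = {p: rng.normal(scale=noise_sd, size=12) for p in ages}
        rec = records_from(ages, vals)
        surf, _, sigma2 = fp.estimate_covariance(rec, np.zeros_like(GRID), GRID)
        assert np.abs(surf).max() < 0.25 * noise_sd**2
        assert abs(sigma2 - noise_sd**2) / noise_sd**2 < 0.20

    def test_symmetric_exactly(self, default_run):
        surf, _, _ = fp.estimate_covariance(
            default_run.cohort.records, default_run.model.mean_curve, GRID)
        np.testing.assert_array_equal(surf, surf.T)

    def test_single_visit_patients_rejected(self):
        rec = records_from({"P1": [10.0], "P2": [12.0]}, {"P1": [80.0], "P2": [85.0]})
        with pytest.raises(ValueError, match="pairs"):
            fp.estimate_covariance(rec, np.full_like(GRID, 80.0), GRID)


class TestEigendecompose:
    def test_rank_one_identity(self):
        phi = np.cos(np.pi * (GRID - 6) / 15)
        phi = phi / np.sqrt(np.trapezoid(phi**2, GRID))
        surf = 5.0 * np.outer(phi, phi)
        funcs, vals = fp.eigendecompose(surf, GRID, 2)
        assert vals[0] == pytest.approx(5.0, rel=1e-6)
        assert vals[1] == pytest.approx(0.0, abs=1e-8)
        ip = np.trapezoid(funcs[0] * phi, GRID)
        assert abs(ip) == pytest.approx(1.0, abs=1e-6)

    def test_recovers_generator_components(self):
        cfg = sg.GeneratorConfig(seed=0)
        phi = np.vstack([f(GRID) for f in cfg.eigenfunctions])
        lam = np.asarray(cfg.score_sds) ** 2
        surf = (phi.T * lam) @ phi
        funcs, vals = fp.eigendecompose(surf, GRID, 2)
        np.testing.assert_allclose(vals, lam, rtol=0.05)
        for k in range(2):
            ang = np.degrees(np.arccos(min(1.0, abs(np.trapezoid(funcs[k] * phi[k], GRID)))))
            assert ang < 5.0

    def test_trace_bound(self, default_run):
        # on a positive-semidefinite surface the top-K eigenvalue sum cannot
        # exceed the integrated diagonal (spectral identity)
        m = default_run.model
        surf = (m.eigenfunctions.T * m.eigenvalues) @ m.eigenfunctions
        _, vals = fp.eigendecompose(surf, GRID, 10)
        trace = np.trapezoid(np.diag(surf), GRID)
        assert vals.sum() <= trace + 1e-6

    def test_too_many_components_raises(self):
        surf = np.eye(GRID.size)
        with pytest.raises(ValueError, match="exceeds"):
            fp.eigendecompose(surf, GRID, GRID.size + 1)


class TestPredictScores:
    def test_zero_residual_gives_zero_scores(self, default_run):
        m = default_run.model
        ages = np.array([8.0, 12.0, 16.0])
        mu = np.interp(ages, m.grid, m.mean_curve)
        np.testing.assert_allclose(m.score_patient(ages, mu), 0.0, atol=1e-12)

    def test_hand_computed_single_visit(self):
        # one component, one visit: lam=4, sigma2=1, phi(t0)=0.5, residual=2
        grid = np.array([10.0, 11.0])
        out = fp.predict_scores(np.array([10.0]), np.array([2.0]),
                                grid=grid, mean_curve=np.zeros(2),
                                eigenfunctions=np.array([[0.5, 0.5]]),
                                eigenvalues=np.array([4.0]), sigma2=1.0)
        assert out[0] == pytest.approx(4 * 0.5 * 2 / (0.25 * 4 + 1))

    def test_noiseless_dense_limit_is_least_squares(self, default_run):
        m = default_run.model
        rng = np.random.default_rng(3)
        ages = np.linspace(6.5, 20.5, 40)
        resid = rng.normal(size=40)
        Phi = np.vstack([np.interp(ages, m.grid, f) for f in m.eigenfunctions]).T
        expected, *_ = np.linalg.lstsq(Phi, resid, rcond=None)
        mu = np.interp(ages, m.grid, m.mean_curve)
        out = fp.predict_scores(ages, mu + resid, grid=m.grid,
                                mean_curve=m.mean_curve,
                                eigenfunctions=m.eigenfunctions,
                                eigenvalues=m.eigenvalues, sigma2=0.0)
        np.testing.assert_allclose(out, expected, atol=1e-4)

    def test_matches_joint_gaussian_conditional_mean(self, default_run):
        # oracle: assemble the joint covariance of (xi, Y) and condition
        m = default_run.model
        rng = np.random.default_rng(7)
        for n_visits in (1, 2, 3, 5):
            ages = np.sort(rng.uniform(6.5, 20.5, n_visits))
            y = rng.normal(loc=85.0, scale=10.0, size=n_visits)
            Phi = np.vstack([np.interp(ages, m.grid, f) for f in m.eigenfunctions]).T
            Lam = np.diag(m.eigenvalues)
            cov_y = Phi @ Lam @ Phi.T + m.error_variance * np.eye(n_visits)
            cov_xy = Lam @ Phi.T
            mu = np.interp(ages, m.grid, m.mean_curve)
            oracle = cov_xy @ np.linalg.inv(cov_y) @ (y - mu)
            ours = m.score_patient(ages, y)
            np.testing.assert_allclose(ours, oracle, atol=1e-8)


class TestFitFpca:
    def test_selects_two_components_by_fve(self, default_run):
        # lambda1/(lambda1+lambda2) = 0.81 < 0.90 <= cumulative at K=2
        assert default_run.model.n_components == 2

    def test_refit_identical(self, default_run):
        again = fp.fit_fpca(default_run.cohort.records)
        np.testing.assert_array_equal(again.mean_curve, default_run.model.mean_curve)
        np.testing.assert_array_equal(again.eigenfunctions,
                                      default_run.model.eigenfunctions)
        pd.testing.assert_frame_equal(again.scores, default_run.model.scores)

    def test_scores_centered(self, default_run):
        s = default_run.model.scores["fpc1"]
        assert abs(s.mean()) < 0.05 * s.std()

    def test_eigenfunctions_orthonormal_under_quadrature(self, default_run):
        m = default_run.model
        w = quad_weights(m.grid)
        gram = m.eigenfunctions @ (w[:, None] * m.eigenfunctions.T)
        np.testing.assert_allclose(gram, np.eye(m.n_components), atol=1e-6)

    def test_eigenvalues_sorted_nonnegative(self, default_run):
        ev = default_run.model.eigenvalues
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 0)

    def test_parameter_recovery(self, default_run):
        m = default_run.model
        truth = default_run.truth
        lam_true = truth.score_sds**2
        rel = np.abs(m.eigenvalues[:2] - lam_true) / lam_true
        assert rel.max() < 0.15
        phi_true = truth.eigenfunctions_on_grid[0]
        ip = np.trapezoid(m.eigenfunctions[0] * phi_true, m.grid)
        assert np.degrees(np.arccos(min(1.0, abs(ip)))) < 10.0
        assert abs(m.error_variance - truth.noise_sd**2) / truth.noise_sd**2 < 0.20

    def test_residuals_consistent_with_error_variance(self, default_run):
        m = default_run.model
        recs = default_run.cohort.records
        fitted = m.scores.to_numpy() @ m.eigenfunctions + m.mean_curve
        fitted = pd.DataFrame(fitted, index=m.scores.index, columns=m.grid)
        resid = []
        for pid, g in recs.groupby("patient_id"):
            f = np.interp(g["encounter_age"], m.grid, fitted.loc[pid].to_numpy())
            resid.extend((g["fev1pp"].to_numpy() - f).tolist())
        resid = np.asarray(resid)
        assert abs(resid.mean()) < 0.3
        assert abs(resid.var() - m.error_variance) / m.error_variance < 0.20


class TestOrientation:
    def test_higher_score_means_more_decline(self, default_run):
        m = default_run.model
        curves, _ = fp.fitted_curves(m)
        change = curves.iloc[:, -1] - curves.iloc[:, 0]
        assert np.corrcoef(m.scores["fpc1"], change)[0, 1] < 0

    def test_idempotent(self, default_run):
        m = default_run.model
        before = m.eigenfunctions.copy()
        fp.orient_components(m)
        np.testing.assert_array_equal(m.eigenfunctions, before)

    def test_sign_flip_invariance_of_reconstruction(self, default_run):
        import copy
        m = copy.deepcopy(default_run.model)
        curves_before, _ = fp.fitted_curves(m)
        m.eigenfunctions[0] = -m.eigenfunctions[0]
        m.scores["fpc1"] = -m.scores["fpc1"]
        fp.orient_components(m)
        curves_after, _ = fp.fitted_curves(m)
        np.testing.assert_allclose(curves_after.to_numpy(),
                                   curves_before.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(m.eigenfunctions,
                                   default_run.model.eigenfunctions, atol=1e-12)


class TestFittedCurves:
    def test_zero_scores_give_mean(self, default_run):
        import copy
        m = copy.deepcopy(default_run.model)
        pid = m.scores.index[0]
        m.scores.loc[pid] = 0.0
        fc = fp.fitted_curve(m, pid)
        np.testing.assert_allclose(fc.values, m.mean_curve)

    def test_derivative_of_constant_curve_is_zero(self):
        from declinefpca.fpca import _spline_derivative
        np.testing.assert_allclose(_spline_derivative(GRID, np.full_like(GRID, 80.0)),
                                   0.0, atol=1e-10)

    def test_reconstruction_identity_on_grid(self, default_run):
        m = default_run.model
        pid = m.scores.index[5]
        fc = fp.fitted_curve(m, pid)
        manual = m.mean_curve + m.scores.loc[pid].to_numpy() @ m.eigenfunctions
        np.testing.assert_array_equal(fc.values, manual)

    def test_unknown_patient_raises(self, default_run):
        with pytest.raises(KeyError):
            fp.fitted_curve(default_run.model, "NOPE")

    def test_derivative_agrees_with_central_differences(self, default_run):
        m = default_run.model
        _, deriv = fp.fitted_curves(m)
        curves, _ = fp.fitted_curves(m)
        vals = curves.to_numpy()
        central = np.gradient(vals, m.grid, axis=1)
        inner = slice(1, -1)
        assert np.abs(deriv.to_numpy()[:, inner] - central[:, inner]).max() < 0.1

    def test_low_noise_recovery_of_true_trajectories(self, lownoise_run):
        curves = lownoise_run.curves
        errs = np.array([
            np.abs(curves.loc[p].to_numpy()
                   - sg.true_trajectory(lownoise_run.truth, p, GRID)).max()
            for p in curves.index])
        assert np.median(errs) < 3.0
        assert np.quantile(errs, 0.8) < 3.0


def test_model_csv_roundtrip(tmp_path, default_run):
    m = default_run.model
    m.save(tmp_path)
    back = fp.FpcaModel.load(tmp_path)
    np.testing.assert_allclose(back.grid, m.grid)
    np.testing.assert_allclose(back.mean_curve, m.mean_curve)
    np.testing.assert_allclose(back.eigenfunctions, m.eigenfunctions)
    np.testing.assert_allclose(back.eigenvalues, m.eigenvalues)
    assert back.error_variance == pytest.approx(m.error_variance)
    pd.testing.assert_frame_equal(back.scores, m.scores, check_names=False)
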