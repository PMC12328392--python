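"""NIPALS-PLS/OPLS against independent oracles, CV, metrics and markers."""

import numpy as np
import pandas as pd
import pytest

import fpchem as f
from fpchem.chemometrics import (
    find_marker_intervals,
    fit_fingerprint_model,
    fit_metrics,
    fit_opls,
    fit_pls,
    loo_cv,
    match_standards,
    predict,
    regression_coefficients,
)
from conftest import response_for


def svd_pls_oracle_predictions(X, y, n_components):
    """Independent sequential PLS1: per component the weight is the leading
    right singular vector of the column covariance X'y (computed via SVD),
    with explicit deflation and prediction accumulated score by score."""
    Xc = X - X.mean(0)
    yc = y - y.mean()
    Xd, yd = Xc.copy(), yc.copy()
    y_hat = np.full(y.shape, y.mean())
    for _ in range(n_components):
        cov = (Xd.T @ yd)[:, None]
        u, s, _ = np.linalg.svd(cov, full_matrices=False)
        w = u[:, 0] * np.sign(u[:, 0] @ (Xd.T @ yd))
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = yd @ t / tt
        y_hat = y_hat + q * t
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
    return y_hat


class TestPLS:
    def test_single_informative_column_perfect_fit(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=10)
        X = y[:, None]
        m = fit_pls(X, y, 1)
        assert np.allclose(predict(m, X), y, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        m = fit_pls(X, y, 2)
        assert np.allclose(
            predict(m, X), svd_pls_oracle_predictions(X, y, 2), atol=1e-8
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_cross_check(self, seed):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(12, 7))
        y = rng.normal(size=12)
        m = fit_pls(X, y, 3)
        ref = sklearn_pls.PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        assert np.allclose(predict(m, X), ref.predict(X).ravel(), atol=1e-8)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        m = fit_pls(X, y, 5)
        Xc = X - X.mean(0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(predict(m, X), Xc @ beta + y.mean(), atol=1e-8)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 30))
        y = rng.normal(size=15)
        m = fit_pls(X, y, 4)
        T = m.T
        for a in range(4):
            for b in range(a + 1, 4):
                bound = 1e-8 * np.linalg.norm(T[:, a]) * np.linalg.norm(T[:, b])
                assert abs(T[:, a] @ T[:, b]) <= bound

    def test_invalid_requests_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(6), 1)  # constant y
        with pytest.raises(ValueError):
            fit_pls(X, rng.normal(size=6), 7)  # too many components


class TestOPLS:
    def test_planted_orthogonal_direction_recovered(self):
        rng = np.random.default_rng(4)
        n, p = 30, 10
        a = np.zeros(p); a[0] = 1.0
        b = np.zeros(p); b[1] = 1.0
        y = rng.normal(size=n)
        z = rng.normal(size=n)
        z -= (z @ y) / (y @ y) * y  # z orthogonal to y
        X = np.outer(y, a) + np.outer(z, b)
        m = fit_opls(X, y, 1)
        t_o = m.T_o[:, 0]
        corr_with_z = abs(np.corrcoef(t_o, z)[0, 1])
        assert corr_with_z > 0.99
        assert abs(np.corrcoef(t_o, y)[0, 1]) <= 1e-8

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_predictions_equal_pls_with_one_more_component(self, k):
        rng = np.random.default_rng(5 + k)
        diffs = []
        for _ in range(50):
            X = rng.normal(size=(12, 20))
            y = rng.normal(size=12)
            o = fit_opls(X, y, k)
            p = fit_pls(X, y, k + 1)
            diffs.append(np.max(np.abs(predict(o, X) - predict(p, X))))
        assert max(diffs) <= 1e-8

    def test_orthogonal_scores_uncorrelated_with_y(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            X = rng.normal(size=(15, 25))
            y = rng.normal(size=15)
            m = fit_opls(X, y, 2)
            for col in m.T_o.T:
                assert abs(np.corrcoef(col, y)[0, 1]) <= 1e-8

    def test_zero_orthogonal_components_identical_to_pls1(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        o = fit_opls(X, y, 0)
        p = fit_pls(X, y, 1)
        assert o.kind == "opls"
        assert np.allclose(o.B, p.B, atol=1e-12)


class TestPredict:
    def test_training_rows_and_mean_row(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        m = fit_pls(X, y, 2)
        assert np.allclose(predict(m, X), m.T @ m.q + m.y_mean, atol=1e-8)
        assert predict(m, X.mean(0)[None, :])[0] == pytest.approx(m.y_mean)

    def test_linearity(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        m = fit_pls(X, y, 2)
        a, b = rng.normal(size=(2, 5))
        # prediction is affine: increments superpose once the offset
        # predict(0) is removed
        lhs = predict(m, (a + b)[None])[0]
        rhs = (
            predict(m, a[None])[0]
            + predict(m, b[None])[0]
            - predict(m, np.zeros((1, 5)))[0]
        )
        assert lhs == pytest.approx(rhs, abs=1e-10)
        assert predict(m, (a + b)[None])[0] - predict(m, a[None])[0] == pytest.approx(
            float(b @ m.B), abs=1e-10
        )

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        m = fit_pls(rng.normal(size=(6, 4)), rng.normal(size=6), 1)
        with pytest.raises(ValueError, match="columns"):
            predict(m, np.zeros((1, 5)))


class TestLooCV:
    def test_noiseless_linear_signal_recovered(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 4))
        y = 2.0 * X[:, 0] + 1.0
        # full-rank fit recovers the noiseless linear signal in every fold
        cv = loo_cv(X, y, n_components=4)
        assert cv.q2 >= 0.999

    def test_pure_noise_has_no_predictive_power(self):
        rng = np.random.default_rng(12)
        q2s = []
        for _ in range(50):
            X = rng.normal(size=(30, 10))
            y = rng.normal(size=30)
            q2s.append(loo_cv(X, y, n_components=2).q2)
        assert np.median(q2s) <= 0.1

    def test_matches_explicit_fold_loop(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        cv = loo_cv(X, y, n_components=2)
        preds = []
        for i in range(10):
            keep = np.arange(10) != i
            m = fit_pls(X[keep], y[keep], 2)
            preds.append(predict(m, X[i : i + 1])[0])
        press = np.sum((y - np.array(preds)) ** 2)
        assert np.allclose(cv.y_hat_cv, preds, atol=1e-12)
        assert cv.rmsecv == pytest.approx(np.sqrt(press / 10), abs=1e-12)
        assert cv.q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2), abs=1e-12)


class TestFitMetrics:
    def test_perfect_fit_sentinels(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=10)
        X = y[:, None]
        m = fit_pls(X, y, 1)
        met = fit_metrics(m, X, y)
        assert met.r2y == pytest.approx(1.0, abs=1e-12)
        assert met.rmsec == pytest.approx(0.0, abs=1e-8)
        assert met.rpd_cal == np.inf or met.rpd_cal > 1e6

    def test_rpd_is_sd_over_rmse(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        m = fit_pls(X, y, 2)
        met = fit_metrics(m, X, y)
        resid = y - predict(m, X)
        rmse = np.sqrt(np.mean(resid**2))
        assert met.rmsec == pytest.approx(rmse, abs=1e-12)
        assert met.rpd_cal == pytest.approx(y.std(ddof=1) / rmse, abs=1e-10)
        assert met.msec == pytest.approx(rmse**2, abs=1e-12)

    def test_r2x_components_complete_at_full_rank(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        m = fit_pls(X, y, 4)
        met = fit_metrics(m, X, y)
        assert met.r2x_total == pytest.approx(1.0, abs=1e-8)
        assert np.all(met.r2x_per_component >= 0)

    def test_cv_metrics_attached(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 6))
        y = X[:, 0] + 0.1 * rng.normal(size=12)
        cv = loo_cv(X, y, n_components=1)
        met = fit_metrics(fit_pls(X, y, 1), X, y, cv)
        assert met.rmsecv == cv.rmsecv and met.q2 == cv.q2
        assert met.rpd_cv == pytest.approx(y.std(ddof=1) / cv.rmsecv)


class TestCoefficientsAndMarkers:
    def test_closed_form_identity(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        m = fit_pls(X, y, 3)
        B_closed = m.W @ np.linalg.solve(m.P.T @ m.W, m.q)
        assert np.allclose(m.B, B_closed, atol=1e-10)
        assert m.B.size == 10

    def test_orthogonal_design_single_active_column(self):
        y = np.array([-1.5, -0.5, 0.5, 1.5])
        X = np.zeros((4, 5))
        X[:, 2] = y
        m = fit_pls(X, y, 1)
        assert abs(m.B[2]) > 0.1
        mask = np.ones(5, bool); mask[2] = False
        assert np.all(np.abs(m.B[mask]) <= 1e-10)

    def test_time_axis_round_trip(self, fingerprints_280, default_index):
        F, _ = fingerprints_280
        y = response_for(F, default_index)
        m = fit_fingerprint_model(F, y, kind="pls", n_components=2)
        t, B = regression_coefficients(m)
        assert np.array_equal(t, F.grid.points)
        assert B.size == F.grid.n_points
        plain = fit_pls(F.X, y, 2)
        with pytest.raises(ValueError, match="time"):
            regression_coefficients(plain)

    def test_marker_intervals_on_constructed_coefficients(self):
        t = np.linspace(0, 60, 601)  # 0.1-min steps
        B = np.zeros_like(t)
        B[(t >= 26.5) & (t <= 27.5)] = 1.0  # bump at 27 min
        B[(t >= 40) & (t <= 41)] = 0.5
        B[(t >= 50) & (t <= 51)] = -2.0  # trough must be ignored
        rep = find_marker_intervals(t, B)
        assert len(rep.intervals) == 2
        assert rep.intervals[0].start_min <= 27.0 <= rep.intervals[0].end_min
        assert 20.0 <= rep.intervals[0].apex_min <= 35.0
        empty = find_marker_intervals(t, np.zeros_like(t))
        assert empty.intervals == []
        negative = find_marker_intervals(t, -np.abs(B))
        assert negative.intervals == []

    def test_standards_matching_tolerance(self):
        iv = f.chemometrics.MarkerInterval(23.5, 24.5, 24.0, 1.0)
        rep = f.MarkerReport(intervals=[iv], matches=[], wavelength_nm=280)
        standards = pd.DataFrame(
            {"compound": ["near", "far"], "retention_min": [24.3, 25.0], "wavelength_nm": [280, 280]}
        )
        matched = match_standards(rep, standards, tolerance_min=0.5)
        assert [m.compound for m in matched.matches] == ["near"]
        assert matched.matches[0].delta_min == pytest.approx(0.3)

    def test_default_run_matches_every_planted_standard(self, default_dataset,
                                                        fingerprints_280, fingerprints_330,
                                                        default_index):
        matched_compounds = set()
        for F in (fingerprints_280[0], fingerprints_330[0]):
            y = response_for(F, default_index)
            m = fit_fingerprint_model(F, y, kind="pls", n_components=2)
            t, B = regression_coefficients(m)
            rep = find_marker_intervals(t, B, wavelength_nm=F.wavelength_nm)
            rep = match_standards(rep, default_dataset.standards)
            matched_compounds |= {mm.compound for mm in rep.matches}
        assert matched_compounds >= set(default_dataset.standards["compound"])

    def test_rmsecv_not_better_than_rmsec(self, fingerprints_280, default_index):
        F, _ = fingerprints_280
        y = response_for(F, default_index)
        m = fit_fingerprint_model(F, y, kind="pls", n_components=2)
        cv = loo_cv(F.X, y, n_components=2)
        met = fit_metrics(m, F.X, y, cv)
        assert met.rmsecv >= met.rmsec
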