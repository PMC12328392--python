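"""Latent-variable regression of fingerprints on antioxidant capacity.

NIPALS partial least squares (PLS1, scalar response) and its orthogonal
variant (OPLS) link the fingerprint matrix X (samples x retention-time
absorbances) to the composite antioxidant index y.  OPLS first filters out
of X the variation orthogonal to y (scores exactly uncorrelated with the
response) and then fits a single predictive component; with k orthogonal
components its predictions coincide with a (k+1)-component PLS, but the
predictive information is concentrated in one component, which simplifies
coefficient interpretation.

The regression-coefficient vector B lives on the retention-time axis:
contiguous runs of large positive coefficients mark chromatographic peaks
whose abundance rises with antioxidant capacity, and their apexes are
matched against a standards retention-time table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatogram import FingerprintMatrix

_MAX_NIPALS_ITER = 500
_NIPALS_TOL = 1e-12


@dataclass
class LatentModel:
    """Fitted PLS/OPLS decomposition.

    ``B`` are regression coefficients on the original (uncentred,
    unscaled) X so that ``predict = (X - x_mean) @ B + y_mean`` — for
    autoscaled fits the scaling is folded into B.
    """

    kind: str  # "pls" | "opls"
    scale_mode: str  # "center" | "autoscale"
    x_mean: np.ndarray = field(repr=False)
    x_scale: np.ndarray = field(repr=False)
    y_mean: float = 0.0
    W: np.ndarray = field(default=None, repr=False)  # weights (p x A)
    P: np.ndarray = field(default=None, repr=False)  # x-loadings (p x A)
    T: np.ndarray = field(default=None, repr=False)  # scores (n x A)
    q: np.ndarray = field(default=None, repr=False)  # y-loadings (A,)
    W_o: np.ndarray | None = field(default=None, repr=False)
    P_o: np.ndarray | None = field(default=None, repr=False)
    T_o: np.ndarray | None = field(default=None, repr=False)
    B: np.ndarray = field(default=None, repr=False)
    n_components: int = 0
    n_orthogonal: int = 0
    x_ss: float = 0.0  # total centred (scaled) X sum of squares
    time_min: np.ndarray | None = field(default=None, repr=False)


@dataclass
class FitMetrics:
    """Calibration/cross-validation figures of merit.

    ``rpd`` is the sample standard deviation of y over the corresponding
    RMSE; both the mean squared error and its root are reported explicitly.
    """

    r2x_per_component: np.ndarray
    r2x_total: float
    r2y: float
    msec: float
    rmsec: float
    rpd_cal: float
    msecv: float | None = None
    rmsecv: float | None = None
    q2: float | None = None
    rpd_cv: float | None = None


@dataclass
class MarkerInterval:
    start_min: float
    end_min: float
    apex_min: float
    peak_coefficient: float


@dataclass
class MarkerMatch:
    interval: MarkerInterval
    compound: str
    retention_min: float
    delta_min: float


@dataclass
class MarkerReport:
    intervals: list[MarkerInterval]
    matches: list[MarkerMatch]
    wavelength_nm: int | None = None


@dataclass
class CVResult:
    y_hat_cv: np.ndarray
    msecv: float
    rmsecv: float
    q2: float


def _prepare(X, y, scale_mode):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if np.ptp(y) == 0:
        raise ValueError("constant response y")
    x_mean = X.mean(axis=0)
    if scale_mode == "center":
        x_scale = np.ones(X.shape[1])
    elif scale_mode == "autoscale":
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        raise ValueError("scale_mode must be 'center' or 'autoscale'")
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean
    return Xc, yc, x_mean, x_scale, y_mean


def _nipals_weight(Xd: np.ndarray, yd: np.ndarray) -> np.ndarray:
    """One NIPALS weight vector, deterministic start from X'y."""
    w = Xd.T @ yd
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("no X-y covariance left; reduce n_components")
    w = w / nw
    # for a scalar response the inner loop is stationary after one pass;
    # iterate anyway and fail loudly if it ever is not
    for _ in range(_MAX_NIPALS_ITER):
        t = Xd @ w
        q = float(yd @ t / (t @ t))
        u = yd * q
        w_new = Xd.T @ u
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            return w_new
        w = w_new
    raise RuntimeError(f"NIPALS did not converge in {_MAX_NIPALS_ITER} iterations")


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale_mode: str = "center",
    time_min: np.ndarray | None = None,
) -> LatentModel:
    """NIPALS PLS1 with deflation of X and y.

    Coefficients ``B = W (P'W)^-1 q`` reproduce the sequential NIPALS
    predictions on the training data exactly.
    """
    Xc, yc, x_mean, x_scale, y_mean = _prepare(X, y, scale_mode)
    n, p = Xc.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    Xd, yd = Xc.copy(), yc.copy()
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    for a in range(n_components):
        w = _nipals_weight(Xd, yd)
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("degenerate score vector; reduce n_components")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
    B_scaled = W @ np.linalg.solve(P.T @ W, q)
    return LatentModel(
        kind="pls",
        scale_mode=scale_mode,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        W=W,
        P=P,
        T=T,
        q=q,
        B=B_scaled / x_scale,
        n_components=n_components,
        x_ss=float((Xc**2).sum()),
        time_min=None if time_min is None else np.asarray(time_min, dtype=float),
    )


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    scale_mode: str = "center",
    time_min: np.ndarray | None = None,
) -> LatentModel:
    """OPLS: orthogonal-variation filtering plus one predictive component.

    Each orthogonal weight is the part of the current x-loading orthogonal
    to the predictive weight; the resulting orthogonal scores are exactly
    uncorrelated with y.  ``n_orthogonal=0`` degenerates to one-component
    PLS (same predictions).
    """
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    if n_orthogonal == 0:
        m = fit_pls(X, y, 1, scale_mode=scale_mode, time_min=time_min)
        m.kind = "opls"
        m.W_o = np.empty((m.W.shape[0], 0))
        m.P_o = np.empty((m.W.shape[0], 0))
        m.T_o = np.empty((m.T.shape[0], 0))
        return m
    Xc, yc, x_mean, x_scale, y_mean = _prepare(X, y, scale_mode)
    n, p = Xc.shape
    if n_orthogonal + 1 > min(n - 1, p):
        raise ValueError("too many orthogonal components for this data size")
    w = Xc.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with y")
    w /= nw
    Xd = Xc.copy()
    W_o = np.empty((p, n_orthogonal))
    P_o = np.empty((p, n_orthogonal))
    T_o = np.empty((n, n_orthogonal))
    for k in range(n_orthogonal):
        t = Xd @ w
        pvec = Xd.T @ t / float(t @ t)
        w_o = pvec - float(w @ pvec) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ValueError(
                f"no orthogonal variation left after {k} component(s)"
            )
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o
    # predictive component on the filtered X (X'y is unchanged by the
    # orthogonal deflations, so the predictive weight direction is w)
    t = Xd @ w
    tt = float(t @ t)
    pvec = Xd.T @ t / tt
    qa = float(yc @ t / tt)
    # fold the sequential orthogonal filtering into one coefficient vector
    c = qa * w
    for k in reversed(range(n_orthogonal)):
        c = c - float(P_o[:, k] @ c) * W_o[:, k]
    return LatentModel(
        kind="opls",
        scale_mode=scale_mode,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        W=w[:, None],
        P=pvec[:, None],
        T=t[:, None],
        q=np.array([qa]),
        W_o=W_o,
        P_o=P_o,
        T_o=T_o,
        B=c / x_scale,
        n_components=1,
        n_orthogonal=n_orthogonal,
        x_ss=float((Xc**2).sum()),
        time_min=None if time_min is None else np.asarray(time_min, dtype=float),
    )


def predict(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted response, ``(X_new - x_mean) @ B + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model expects {model.x_mean.size}"
        )
    return (X_new - model.x_mean) @ model.B + model.y_mean


def fit_fingerprint_model(
    F: FingerprintMatrix,
    y: np.ndarray,
    kind: str = "pls",
    n_components: int = 2,
    n_orthogonal: int = 1,
    scale_mode: str = "center",
) -> LatentModel:
    """Fit a latent model to a fingerprint matrix, keeping the time axis."""
    if kind == "pls":
        return fit_pls(F.X, y, n_components, scale_mode, time_min=F.grid.points)
    if kind == "opls":
        return fit_opls(F.X, y, n_orthogonal, scale_mode, time_min=F.grid.points)
    raise ValueError("kind must be 'pls' or 'opls'")


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "pls",
    n_components: int = 2,
    n_orthogonal: int = 1,
    scale_mode: str = "center",
) -> CVResult:
    """Leave-one-out cross-validation with per-fold re-centring.

    ``q2 = 1 - PRESS / TSS`` with TSS taken about the full-data mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("LOO-CV needs n >= 3")
    y_hat = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = y[keep]
        if np.ptp(y_tr) == 0:
            raise ValueError(f"fold {i}: constant training response")
        if kind == "pls":
            m = fit_pls(X[keep], y_tr, n_components, scale_mode)
        else:
            m = fit_opls(X[keep], y_tr, n_orthogonal, scale_mode)
        y_hat[i] = predict(m, X[i : i + 1])[0]
    press = float(np.sum((y - y_hat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    mse = press / n
    return CVResult(y_hat_cv=y_hat, msecv=mse, rmsecv=float(np.sqrt(mse)), q2=1.0 - press / tss)


def fit_metrics(
    model: LatentModel,
    X: np.ndarray,
    y: np.ndarray,
    cv_result: CVResult | None = None,
) -> FitMetrics:
    """Explained variance, R2Y, (R)MSE and RPD for a fitted model.

    ``r2x_per_component`` covers the predictive components followed by any
    orthogonal ones; a perfect fit reports ``rpd_cal = inf``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sd_y = float(y.std(ddof=1))
    if sd_y == 0:
        raise ValueError("zero-variance response")
    comps = []
    for a in range(model.n_components):
        comps.append(float((model.T[:, a] @ model.T[:, a]) * (model.P[:, a] @ model.P[:, a])))
    if model.T_o is not None:
        for k in range(model.T_o.shape[1]):
            comps.append(
                float((model.T_o[:, k] @ model.T_o[:, k]) * (model.P_o[:, k] @ model.P_o[:, k]))
            )
    r2x = np.array(comps) / model.x_ss
    y_hat = predict(model, X)
    rss = float(np.sum((y - y_hat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    mse = rss / y.size
    rmse = float(np.sqrt(mse))
    metrics = FitMetrics(
        r2x_per_component=r2x,
        r2x_total=float(r2x.sum()),
        r2y=1.0 - rss / tss,
        msec=mse,
        rmsec=rmse,
        rpd_cal=float(np.inf) if rmse == 0 else sd_y / rmse,
    )
    if cv_result is not None:
        metrics.msecv = cv_result.msecv
        metrics.rmsecv = cv_result.rmsecv
        metrics.q2 = cv_result.q2
        metrics.rpd_cv = float(np.inf) if cv_result.rmsecv == 0 else sd_y / cv_result.rmsecv
    return metrics


def regression_coefficients(model: LatentModel) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient vector aligned to retention times (minutes)."""
    if model.time_min is None:
        raise ValueError("model was not fitted with a time axis (use fit_fingerprint_model)")
    if model.time_min.size != model.B.size:
        raise ValueError("time axis does not match coefficient length")
    return model.time_min, model.B


def find_marker_intervals(
    time_min: np.ndarray,
    B: np.ndarray,
    rel_threshold: float = 0.1,
    min_width_min: float = 0.1,
    wavelength_nm: int | None = None,
) -> MarkerReport:
    """Positive-coefficient runs marking putative antioxidant peaks.

    Keeps maximal runs where ``B > rel_threshold * max(B)`` of at least
    ``min_width_min`` minutes; only positive coefficients matter, since
    compounds tracking the antioxidant index have positive coefficients.
    All-nonpositive B gives an empty report.
    """
    time_min = np.asarray(time_min, dtype=float)
    B = np.asarray(B, dtype=float)
    if time_min.size != B.size:
        raise ValueError("time and coefficient vectors must align")
    b_max = B.max(initial=-np.inf)
    if b_max <= 0:
        return MarkerReport(intervals=[], matches=[], wavelength_nm=wavelength_nm)
    mask = B > rel_threshold * b_max
    intervals: list[MarkerInterval] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        t0, t1 = time_min[start], time_min[stop - 1]
        if t1 - t0 < min_width_min:
            continue
        apex = start + int(np.argmax(B[start:stop]))
        intervals.append(
            MarkerInterval(
                start_min=float(t0),
                end_min=float(t1),
                apex_min=float(time_min[apex]),
                peak_coefficient=float(B[apex]),
            )
        )
    return MarkerReport(intervals=intervals, matches=[], wavelength_nm=wavelength_nm)


def match_standards(
    report: MarkerReport,
    standards: pd.DataFrame,
    tolerance_min: float = 0.5,
) -> MarkerReport:
    """Match interval apexes to standards retention times within tolerance.

    ``standards`` columns: compound, retention_min, wavelength_nm.  Only
    standards recorded at the report's wavelength are considered (all, if
    the report carries no wavelength).  Unmatched intervals are retained
    with no match entry.
    """
    matches: list[MarkerMatch] = []
    subset = standards
    if report.wavelength_nm is not None and "wavelength_nm" in standards.columns:
        subset = standards[standards["wavelength_nm"] == report.wavelength_nm]
    for iv in report.intervals:
        for _, row in subset.iterrows():
            delta = float(row["retention_min"]) - iv.apex_min
            if abs(delta) <= tolerance_min:
                matches.append(
                    MarkerMatch(
                        interval=iv,
                        compound=str(row["compound"]),
                        retention_min=float(row["retention_min"]),
                        delta_min=delta,
                    )
                )
    return MarkerReport(
        intervals=list(report.intervals),
        matches=matches,
        wavelength_nm=report.wavelength_nm,
    )
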