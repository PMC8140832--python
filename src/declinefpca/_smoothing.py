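"""Penalized B-spline (P-spline) scatterplot smoothers.

One- and two-dimensional weighted P-splines with a second-order difference
penalty and generalized cross-validation (GCV) for the smoothing parameter.
Uniform interior knots are used throughout, so the penalty null space
contains exactly the linear functions: constants and straight lines are
reproduced without bias at any smoothing level.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["bspline_design", "fit_pspline_1d", "fit_pspline_2d", "PSplineFit"]

_DEGREE = 3


def _uniform_knots(lo: float, hi: float, n_basis: int, degree: int = _DEGREE) -> np.ndarray:
    """Clamped uniform knot vector giving `n_basis` B-splines on [lo, hi]."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError(f"n_basis={n_basis} too small for degree {degree}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def bspline_design(x: np.ndarray, lo: float, hi: float, n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of `n_basis` cubic B-splines at points `x`; returns (B, knots)."""
    x = np.asarray(x, dtype=float)
    knots = _uniform_knots(lo, hi, n_basis)
    # design_matrix requires points inside the base interval
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, knots, _DEGREE).toarray()
    return B, knots


def _diff_penalty(p: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(p), n=order, axis=0)
    return D.T @ D


class PSplineFit:
    """A fitted P-spline: coefficients plus the basis needed to evaluate it."""

    def __init__(self, coef: np.ndarray, knots: np.ndarray, lam: float, edf: float):
        self.coef = coef
        self.knots = knots
        self.lam = lam
        self.edf = edf
        self._spline = BSpline(knots, coef, _DEGREE, extrapolate=True)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.knots[_DEGREE], self.knots[-_DEGREE - 1]
        return self._spline(np.clip(np.asarray(x, dtype=float), lo, hi))


def _gcv_solve(BtWB: np.ndarray, BtWy: np.ndarray, P: np.ndarray,
               lambdas: np.ndarray, n_obs: float,
               yty: float) -> tuple[np.ndarray, float, float]:
    """Pick lambda by GCV from precomputed normal-equation blocks.

    GCV(lam) = n * RSS / (n - edf)^2 with edf = tr[(BtWB + lam P)^-1 BtWB].
    RSS here is the weighted residual sum of squares, expanded as
    y'Wy - 2 c'B'Wy + c'B'WB c.
    """
    best = None
    for lam in lambdas:
        A = BtWB + lam * P
        try:
            coef = np.linalg.solve(A, BtWy)
            edf = float(np.trace(np.linalg.solve(A, BtWB)))
        except np.linalg.LinAlgError:
            continue
        rss = float(yty - 2.0 * coef @ BtWy + coef @ BtWB @ coef)
        rss = max(rss, 0.0)
        denom = max(n_obs - edf, 1e-8)
        gcv = n_obs * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, edf)
    if best is None:
        raise np.linalg.LinAlgError("all candidate smoothing parameters failed")
    _, lam, coef, edf = best
    return coef, float(lam), edf


def fit_pspline_1d(x: np.ndarray, y: np.ndarray, *,
                   weights: np.ndarray | None = None,
                   domain: tuple[float, float] | None = None,
                   n_basis: int = 15,
                   lam: float | None = None) -> PSplineFit:
    """Weighted penalized cubic-spline regression of y on x.

    lam=None selects the smoothing parameter by GCV over a log-spaced grid;
    a fixed lam gives fully reproducible smoothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points to smooth")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    lo, hi = domain if domain is not None else (float(x.min()), float(x.max()))
    B, knots = bspline_design(x, lo, hi, n_basis)
    P = _diff_penalty(B.shape[1])
    BtWB = B.T @ (w[:, None] * B)
    BtWy = B.T @ (w * y)
    yty = float(w @ y**2)
    # GCV counts rows, not weight mass: with binned cell means, each cell is
    # one observation whose weight only sets its relative precision
    n_eff = float(x.size)
    if lam is not None:
        lambdas = np.array([lam], dtype=float)
    else:
        scale = np.trace(BtWB) / B.shape[1]
        lambdas = scale * np.logspace(-6, 4, 21)
    coef, lam_used, edf = _gcv_solve(BtWB, BtWy, P, lambdas, n_eff, yty)
    return PSplineFit(coef, knots, lam_used, edf)


class PSpline2DFit:
    """Tensor-product P-spline surface fit on a rectangular domain."""

    def __init__(self, coef: np.ndarray, knots_s: np.ndarray, knots_t: np.ndarray,
                 lam: float, edf: float):
        self.coef = coef  # (p_s, p_t)
        self.knots_s = knots_s
        self.knots_t = knots_t
        self.lam = lam
        self.edf = edf

    def __call__(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Evaluate on the grid s x t; returns (len(s), len(t))."""
        lo_s, hi_s = self.knots_s[_DEGREE], self.knots_s[-_DEGREE - 1]
        Bs = BSpline.design_matrix(np.clip(s, lo_s, hi_s), self.knots_s, _DEGREE).toarray()
        lo_t, hi_t = self.knots_t[_DEGREE], self.knots_t[-_DEGREE - 1]
        Bt = BSpline.design_matrix(np.clip(t, lo_t, hi_t), self.knots_t, _DEGREE).toarray()
        return Bs @ self.coef @ Bt.T


def fit_pspline_2d(s: np.ndarray, t: np.ndarray, z: np.ndarray, *,
                   weights: np.ndarray | None = None,
                   domain: tuple[float, float] | None = None,
                   n_basis: int = 10,
                   lam: float | None = None) -> PSpline2DFit:
    """Weighted tensor-product P-spline regression of z on (s, t)."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if domain is None:
        lo = float(min(s.min(), t.min()))
        hi = float(max(s.max(), t.max()))
    else:
        lo, hi = domain
    Bs, knots = bspline_design(s, lo, hi, n_basis)
    Bt, _ = bspline_design(t, lo, hi, n_basis)
    # row-wise Kronecker product: design for coef vector of length n_basis^2
    B = Bs[:, :, None] * Bt[:, None, :]
    B = B.reshape(len(z), n_basis * n_basis)
    P1 = _diff_penalty(n_basis)
    I = np.eye(n_basis)
    P = np.kron(P1, I) + np.kron(I, P1)
    BtWB = B.T @ (w[:, None] * B)
    BtWy = B.T @ (w * z)
    yty = float(w @ z**2)
    n_eff = float(len(z))
    if lam is not None:
        lambdas = np.array([lam], dtype=float)
    else:
        scale = np.trace(BtWB) / B.shape[1]
        lambdas = scale * np.logspace(-6, 4, 15)
    coef, lam_used, edf = _gcv_solve(BtWB, BtWy, P, lambdas, n_eff, yty)
    return PSpline2DFit(coef.reshape(n_basis, n_basis), knots, knots, lam_used, edf)
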