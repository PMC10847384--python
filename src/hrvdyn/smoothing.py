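"""Penalized B-spline smoothing with analytic first derivatives.

Each per-second series is approximated by an order-5 B-spline (degree 4, the
functional-data-analysis convention order = degree + 1) with a knot at every
sample, minimizing

    sum_t (y_t - f(t))^2  +  lambda * integral (f'''(u))^2 du.

The penalty null space is the quadratics, so lambda -> infinity shrinks the
fit to the least-squares quadratic while any quadratic input is reproduced
exactly at every lambda.  Fitted levels and the spline's analytic first
derivative are returned at the sample times; each contiguous observed run is
smoothed independently (no imputation across gaps), and runs shorter than
``min_run`` samples are left missing.

Default smoothing parameters for the pipeline: lambda = 0.5 for IBI, 0.1 for
RSA, and 1.0 for behavior densities, applied on the per-second time scale with
variables in native units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SmoothedTrajectory",
    "fit_penalized_spline",
    "gcv_profile",
    "DEFAULT_LAMBDAS",
]

DEFAULT_LAMBDAS = {"ibi": 0.5, "rsa": 0.1, "pos": 1.0, "neg": 1.0}
#: shortest observed run that is smoothed (samples)
MIN_RUN = 31
SPLINE_ORDER = 5
PENALTY_DERIV = 3


@dataclass
class SmoothedTrajectory:
    """Smoothed level and first derivative on the sample grid."""

    level: np.ndarray
    deriv: np.ndarray
    missing: np.ndarray
    lam: float
    order: int = SPLINE_ORDER
    penalty_deriv: int = PENALTY_DERIV

    @property
    def n(self) -> int:
        return int(self.level.size)


def _knot_vector(x: np.ndarray, degree: int) -> np.ndarray:
    """Clamped knot vector with a knot at every sample point."""
    return np.concatenate(
        [np.full(degree, x[0]), x, np.full(degree, x[-1])]
    )


def _basis_matrices(
    x: np.ndarray, degree: int, penalty_deriv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix B, derivative design D, penalty matrix P, knots t."""
    t = _knot_vector(x, degree)
    nb = t.size - degree - 1
    eye = np.eye(nb)
    spl = BSpline(t, eye, degree, extrapolate=False)
    B = spl(x)
    D = spl(x, nu=1)
    # integral of products of penalty_deriv-th basis derivatives, exact by
    # Gauss-Legendre (integrand is piecewise polynomial of degree
    # 2*(degree - penalty_deriv) = 2 for the order-5 / 3rd-derivative case)
    npts = degree - penalty_deriv + 1
    gx, gw = np.polynomial.legendre.leggauss(npts)
    P = np.zeros((nb, nb))
    for a, b in zip(x[:-1], x[1:]):
        if b <= a:
            continue
        half = 0.5 * (b - a)
        pts = a + half * (gx + 1.0)
        Dp = spl(pts, nu=penalty_deriv)
        P += half * (Dp * gw[:, None]).T @ Dp
    return B, D, P, t


def _fit_run(
    y: np.ndarray, lam: float, degree: int, penalty_deriv: int
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Fit one contiguous run; returns (level, deriv, rss, edf)."""
    x = np.arange(y.size, dtype=float)
    B, D, P, _ = _basis_matrices(x, degree, penalty_deriv)
    # solve min ||y - B c||^2 + lam ||L c||^2 with P = L'L in augmented
    # least-squares form; conditioning is the square root of the normal
    # equations', which keeps the lam -> infinity limit accurate
    s, V = np.linalg.eigh(0.5 * (P + P.T))
    L = np.sqrt(np.clip(s, 0.0, None))[:, None] * V.T
    nb = B.shape[1]
    aug = np.vstack([B, np.sqrt(lam) * L])
    rhs = np.concatenate([y, np.zeros(nb)])
    coef = np.linalg.lstsq(aug, rhs, rcond=None)[0]
    level = B @ coef
    deriv = D @ coef
    resid = y - level
    rss = float(resid @ resid)
    # effective degrees of freedom trace((B'B + lam P)^-1 B'B)
    BtB = B.T @ B
    A = 0.5 * (BtB + lam * P + (BtB + lam * P).T)
    try:
        c_low = cho_factor(A)
        H = cho_solve(c_low, BtB)
    except np.linalg.LinAlgError:
        H = np.linalg.pinv(A, hermitian=True) @ BtB
    edf = float(np.trace(H))
    return level, deriv, rss, edf


def _observed_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index spans of consecutive non-missing samples."""
    ok = ~np.asarray(missing, dtype=bool)
    runs = []
    start = None
    for i, v in enumerate(ok):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, ok.size))
    return runs


def fit_penalized_spline(
    values: np.ndarray,
    missing: np.ndarray | None = None,
    lam: float = 1.0,
    order: int = SPLINE_ORDER,
    penalty_deriv: int = PENALTY_DERIV,
    min_run: int = MIN_RUN,
) -> SmoothedTrajectory:
    """Penalized-spline smooth of a per-second series with a missing mask.

    Parameters
    ----------
    values, missing
        Per-second samples; missing samples split the series into contiguous
        runs which are smoothed independently.
    lam
        Non-negative roughness penalty weight on the integrated squared
        ``penalty_deriv``-th derivative.
    order
        Spline order in the FDA convention (order = degree + 1); default 5,
        i.e. quartic pieces, consistent with a 3rd-derivative penalty.
    min_run
        Runs shorter than this stay missing in the output.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = np.asarray(values, dtype=float)
    miss = (
        np.zeros(y.size, dtype=bool)
        if missing is None
        else np.asarray(missing, dtype=bool)
    )
    level = np.full(y.size, np.nan)
    deriv = np.full(y.size, np.nan)
    out_missing = np.ones(y.size, dtype=bool)
    fitted_any = False
    for i0, i1 in _observed_runs(miss):
        if i1 - i0 < min_run:
            continue
        lev, der, _, _ = _fit_run(y[i0:i1], lam, order - 1, penalty_deriv)
        level[i0:i1] = lev
        deriv[i0:i1] = der
        out_missing[i0:i1] = False
        fitted_any = True
    if not fitted_any:
        raise ValueError(f"no observed run of length >= {min_run} to smooth")
    return SmoothedTrajectory(level, deriv, out_missing, lam, order, penalty_deriv)


def gcv_profile(
    values: np.ndarray,
    lam_grid: np.ndarray,
    missing: np.ndarray | None = None,
    order: int = SPLINE_ORDER,
    penalty_deriv: int = PENALTY_DERIV,
    min_run: int = MIN_RUN,
) -> list[tuple[float, float]]:
    """Generalized cross-validation scores over a grid of lambda values.

    GCV(lambda) = n * RSS / (n - edf)^2, pooled over the smoothed runs.  A
    diagnostic aid: the pipeline defaults keep the fixed per-variable lambdas.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0 or np.any(lam_grid <= 0):
        raise ValueError("lam_grid must be non-empty and positive")
    y = np.asarray(values, dtype=float)
    miss = (
        np.zeros(y.size, dtype=bool)
        if missing is None
        else np.asarray(missing, dtype=bool)
    )
    runs = [
        (i0, i1) for i0, i1 in _observed_runs(miss) if i1 - i0 >= min_run
    ]
    if not runs:
        raise ValueError(f"no observed run of length >= {min_run}")
    out = []
    for lam in lam_grid:
        rss_tot, edf_tot, n_tot = 0.0, 0.0, 0
        for i0, i1 in runs:
            _, _, rss, edf = _fit_run(y[i0:i1], lam, order - 1, penalty_deriv)
            rss_tot += rss
            edf_tot += edf
            n_tot += i1 - i0
        gcv = n_tot * rss_tot / (n_tot - edf_tot) ** 2
        out.append((float(lam), float(gcv)))
    return out
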