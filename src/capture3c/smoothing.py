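"""Penalized cubic smoothing spline with the classical `spar` parameterization.

The distance-decay background is fitted with a cubic smoothing spline whose
roughness penalty is controlled by a dimensionless smoothing parameter
``spar`` on the familiar scale of the classical implementation: the penalty
weight is

    lambda = r * 256 ** (3 * spar - 1),

where r = tr(X'WX) / tr(Omega) is the design-dependent factor that puts the
fidelity and roughness terms on a common scale (X is the cubic B-spline
design matrix on predictors rescaled to [0, 1], Omega the Gram matrix of
second derivatives of the basis).  The fit minimizes

    sum_i w_i (y_i - f(x_i))**2 + lambda * int f''(u)**2 du.

Duplicate x values are aggregated to their (weighted) mean with multiplicity
weights, and the basis uses knots at the unique predictor values, thinned to
at most ``max_knots`` quantile-spaced knots for large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


def _second_derivative_gram(t: np.ndarray, k: int) -> np.ndarray:
    """Gram matrix of second derivatives of the B-spline basis on knots t."""
    n_basis = len(t) - k - 1
    basis = BSpline(t, np.eye(n_basis), k, extrapolate=False)
    d2 = basis.derivative(2)
    # second derivatives of cubics are piecewise linear, so their pairwise
    # products are piecewise quadratic: 2-point Gauss-Legendre is exact
    spans = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    omega = np.zeros((n_basis, n_basis))
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gauss
        vals = d2(pts)  # (2, n_basis)
        vals = np.nan_to_num(vals)
        omega += half * (vals.T @ vals)
    return omega


@dataclass
class SmoothingSpline:
    spar: float = 0.1
    max_knots: int = 200
    # fitted state
    _t: np.ndarray = field(default=None, repr=False)
    _coef: np.ndarray = field(default=None, repr=False)
    _xmin: float = field(default=0.0, repr=False)
    _xrange: float = field(default=1.0, repr=False)
    lambda_: float = field(default=np.nan, repr=False)

    def fit(self, x, y, weights=None) -> "SmoothingSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        w = np.ones_like(x) if weights is None else np.asarray(weights, float)
        # aggregate ties: weighted mean y per unique x, summed weights
        order = np.argsort(x)
        x, y, w = x[order], y[order], w[order]
        ux, inv = np.unique(x, return_inverse=True)
        if len(ux) < 4:
            raise ValueError(f"need >= 4 distinct x values, got {len(ux)}")
        wsum = np.bincount(inv, weights=w)
        ymean = np.bincount(inv, weights=w * y) / wsum
        self._xmin = float(ux[0])
        self._xrange = float(ux[-1] - ux[0])
        xs = (ux - self._xmin) / self._xrange
        # knots: all unique x, or quantile-thinned for large n
        if len(xs) <= self.max_knots:
            knots = xs
        else:
            qs = np.linspace(0, 1, self.max_knots)
            knots = np.unique(np.quantile(xs, qs))
        k = 3
        t = np.concatenate([[0.0] * (k + 1), knots[1:-1], [1.0] * (k + 1)])
        X = BSpline.design_matrix(xs, t, k).toarray()
        omega = _second_derivative_gram(t, k)
        xtwx = X.T @ (X * wsum[:, None])
        r = np.trace(xtwx) / np.trace(omega)
        self.lambda_ = float(r * 256.0 ** (3.0 * self.spar - 1.0))
        a = xtwx + self.lambda_ * omega
        b = X.T @ (wsum * ymean)
        # tiny ridge for numerical safety with near-coincident knots
        a[np.diag_indices_from(a)] += 1e-10 * np.trace(a) / len(a)
        self._coef = np.linalg.solve(a, b)
        self._t = t
        return self

    def predict(self, x) -> np.ndarray:
        if self._coef is None:
            raise RuntimeError("spline not fitted")
        x = np.asarray(x, dtype=float)
        xs = (x - self._xmin) / self._xrange
        xs = np.clip(xs, 0.0, 1.0)  # constant extrapolation beyond the data
        X = BSpline.design_matrix(xs, self._t, 3).toarray()
        return X @ self._coef
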