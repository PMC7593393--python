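"""Spherical spline interpolation of scalp potentials (Perrin-type).

The interpolating function over the unit sphere is

    v(r) = c0 + sum_i c_i g(cos gamma(r, r_i))

with the kernel truncated at Legendre degree N:

    g(x) = (1 / 4 pi) * sum_{n=1}^{N} (2n + 1) / (n (n + 1))^m * P_n(x)

where ``m`` is the spline order (stiffness) and ``gamma`` the central angle
between scalp points.  Coefficients solve the constrained linear system

    [ G + lambda I   1 ] [ c  ]   [ v ]
    [ 1^T            0 ] [ c0 ] = [ 0 ]

so a constant field is reproduced exactly and, at ``lambda = 0``, the
spline passes through the measured electrode values.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg

from .montage import Montage

__all__ = ["spline_kernel", "spline_interpolate", "SplineInterpolator"]


def spline_kernel(cosgamma, order_m: int = 4, degree_n: int = 10) -> np.ndarray:
    """Evaluate the spherical-spline kernel g(cos gamma)."""
    n = np.arange(1, degree_n + 1, dtype=float)
    coeffs = np.zeros(degree_n + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** order_m
    x = np.clip(np.asarray(cosgamma, dtype=float), -1.0, 1.0)
    return npleg.legval(x, coeffs) / (4 * np.pi)


class SplineInterpolator:
    """Factorized spherical-spline system for repeated interpolation.

    Build once per (montage, targets) pair, then apply to many samples:
    the LU factorization of the constrained system is reused.
    """

    def __init__(self, positions, targets, order_m: int = 4,
                 degree_n: int = 10, lambda_reg: float = 0.0):
        from scipy.linalg import lu_factor, lu_solve

        self._lu_solve = lu_solve
        E = np.asarray(positions, dtype=float)
        T = np.atleast_2d(np.asarray(targets, dtype=float))
        if E.ndim != 2 or E.shape[1] != 3:
            raise ValueError("positions must be (n_electrodes, 3) unit vectors")
        self.n_electrodes = E.shape[0]
        G = spline_kernel(E @ E.T, order_m, degree_n)
        if lambda_reg:
            G = G + lambda_reg * np.eye(self.n_electrodes)
        A = np.zeros((self.n_electrodes + 1, self.n_electrodes + 1))
        A[:-1, :-1] = G
        A[:-1, -1] = 1.0
        A[-1, :-1] = 1.0
        try:
            self._factors = lu_factor(A)
            # reject numerically singular systems up front
            if not np.all(np.isfinite(self._factors[0])) or np.min(
                np.abs(np.diag(self._factors[0]))
            ) < 1e-12 * np.max(np.abs(np.diag(self._factors[0]))):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, ValueError):
            raise np.linalg.LinAlgError(
                "spherical-spline system is singular (duplicate electrode "
                "positions?); set lambda_reg > 0 to regularize"
            )
        self._Gt = spline_kernel(T @ E.T, order_m, degree_n)  # targets x electrodes

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Interpolate per-channel values (last axis = electrodes) at targets."""
        v = np.asarray(values, dtype=float)
        single = v.ndim == 1
        v2 = np.atleast_2d(v)
        if v2.shape[-1] != self.n_electrodes:
            raise ValueError("values length must equal electrode count")
        rhs = np.zeros((v2.shape[0], self.n_electrodes + 1))
        rhs[:, :-1] = v2
        sol = self._lu_solve(self._factors, rhs.T).T
        c, c0 = sol[:, :-1], sol[:, -1:]
        out = c0 + c @ self._Gt.T
        return out[0] if single else out


def spline_interpolate(montage: Montage, values, targets, order_m: int = 4,
                       degree_n: int = 10, lambda_reg: float = 0.0) -> np.ndarray:
    """Interpolate one map's channel values at target unit vectors.

    ``values`` may also be (n_samples, n_channels) to interpolate a whole
    series with one factorization.
    """
    interp = SplineInterpolator(
        montage.cartesian, targets, order_m=order_m, degree_n=degree_n,
        lambda_reg=lambda_reg,
    )
    return interp(values)
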