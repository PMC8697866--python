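"""Legendre-polynomial lactation basis.

Every stage of a random-regression test-day model — simulation, mixed-model
assembly, variance curves, breeding values — evaluates the same covariate
vector z_j at a given days-in-milk (DIM) j.  This module is the single place
where that vector is defined.

DIM is standardized to x in [-1, +1] over the modelled lactation window
(days 5..305 by default) and the basis functions are the *orthonormal*
Legendre polynomials

    phi_t(x) = sqrt((2t + 1) / 2) * P_t(x),

so that the integral of phi_s * phi_t over [-1, 1] is the Kronecker delta.
Orthonormality is a convention, not a necessity, but it must be applied
consistently on the generative and the estimation side; coefficient
covariance matrices (G0, P0) are only meaningful relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["DimRange", "standardize_dim", "basis_vector", "basis_matrix"]


@dataclass(frozen=True)
class DimRange:
    """Inclusive modelled range of days in milk (calendar days from calving)."""

    first_day: int = 5
    last_day: int = 305

    def __post_init__(self) -> None:
        if int(self.first_day) != self.first_day or int(self.last_day) != self.last_day:
            raise ValueError("DIM bounds must be integers")
        if self.first_day <= 0:
            raise ValueError(f"first_day must be positive, got {self.first_day}")
        if self.first_day >= self.last_day:
            raise ValueError(
                f"first_day must be < last_day, got [{self.first_day}, {self.last_day}]"
            )

    @property
    def days(self) -> np.ndarray:
        """All integer DIM in the range, first..last inclusive."""
        return np.arange(self.first_day, self.last_day + 1)

    @property
    def n_days(self) -> int:
        return self.last_day - self.first_day + 1

    def __contains__(self, j) -> bool:
        return self.first_day <= j <= self.last_day


def standardize_dim(j, dim_range: DimRange = DimRange()):
    """Map DIM j affinely onto [-1, +1]; endpoint-exact.

    x = -1 + 2 (j - first) / (last - first).  Accepts scalars or arrays;
    raises if any value lies outside the modelled range.
    """
    j_arr = np.asarray(j, dtype=float)
    lo, hi = dim_range.first_day, dim_range.last_day
    if np.any(j_arr < lo) or np.any(j_arr > hi):
        bad = np.atleast_1d(j_arr)[(np.atleast_1d(j_arr) < lo) | (np.atleast_1d(j_arr) > hi)]
        raise ValueError(f"DIM outside modelled range [{lo}, {hi}]: {bad[:5]}")
    x = -1.0 + 2.0 * (j_arr - lo) / (hi - lo)
    return float(x) if np.isscalar(j) or x.ndim == 0 else x


def _norms(order: int) -> np.ndarray:
    return np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)


def basis_vector(j, order: int = 3, dim_range: DimRange = DimRange()) -> np.ndarray:
    """Orthonormal Legendre basis vector z_j = (phi_0(x), ..., phi_order(x))."""
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    x = standardize_dim(j, dim_range)
    return npleg.legvander(np.asarray([x]), order)[0] * _norms(order)


def basis_matrix(dims, order: int = 3, dim_range: DimRange = DimRange()) -> np.ndarray:
    """Stack basis vectors for many DIM values; row i is basis_vector(dims[i]).

    An empty `dims` yields a (0, order+1) matrix.
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    dims = np.asarray(dims, dtype=float)
    if dims.size == 0:
        return np.empty((0, order + 1))
    x = standardize_dim(dims, dim_range)
    return npleg.legvander(np.atleast_1d(x), order) * _norms(order)
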