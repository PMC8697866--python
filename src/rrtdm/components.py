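"""Variance components of the random-regression test-day model.

G0 and P0 are the covariance matrices of the additive-genetic and
permanent-environmental random-regression coefficients (on the orthonormal
Legendre basis), sigma2_e the homogeneous residual variance and sigma2_htd
the herd-test-day variance.  All in kg^2 of daily milk yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np

__all__ = ["VarianceComponents", "nearest_psd"]


def nearest_psd(K: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Symmetrize and clip eigenvalues at floor_frac * trace ("bending").

    The floor keeps bent matrices invertible without wrecking the conditioning
    of the mixed-model coefficient matrix (whose log-determinant REML needs);
    1e-6 of the trace is far below any statistically meaningful eigenvalue.
    """
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    floor = floor_frac * max(np.trace(K), 0.0)
    if w[0] >= floor:
        return K
    w = np.maximum(w, floor)
    return (V * w) @ V.T


@dataclass
class VarianceComponents:
    G0: np.ndarray
    P0: np.ndarray
    sigma2_e: float
    sigma2_htd: float = 0.0

    def __post_init__(self) -> None:
        self.G0 = np.asarray(self.G0, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        if self.G0.shape != self.P0.shape or self.G0.ndim != 2:
            raise ValueError("G0 and P0 must be square matrices of equal size")
        for name, K in (("G0", self.G0), ("P0", self.P0)):
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(K)[0] < -1e-8 * max(np.trace(K), 1.0):
                raise ValueError(f"{name} must be positive semidefinite")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be > 0")
        if self.sigma2_htd < 0:
            raise ValueError("sigma2_htd must be >= 0")

    @property
    def order(self) -> int:
        return self.G0.shape[0] - 1

    @property
    def n_parameters(self) -> int:
        k = self.G0.shape[0]
        return k * (k + 1) + 2  # two symmetric matrices + two scalars

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            self.G0.copy(), self.P0.copy(), float(self.sigma2_e), float(self.sigma2_htd)
        )

    def to_dict(self) -> dict:
        return {
            "G0": self.G0.tolist(),
            "P0": self.P0.tolist(),
            "sigma2_e": float(self.sigma2_e),
            "sigma2_htd": float(self.sigma2_htd),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceComponents":
        return cls(
            np.asarray(d["G0"]), np.asarray(d["P0"]), d["sigma2_e"], d.get("sigma2_htd", 0.0)
        )

    @classmethod
    def from_json(cls, path) -> "VarianceComponents":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
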