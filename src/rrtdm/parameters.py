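"""Daily genetic-parameter curves from coefficient covariances.

With z_j the Legendre covariate vector at DIM j, the fitted coefficient
covariances translate into day-by-day quantities:

    additive variance        sigma2_a(j)  = z_j' G0 z_j
    perm.-env. variance      sigma2_pe(j) = z_j' P0 z_j
    heritability             h2(j) = sigma2_a(j) / sigma2_P(j)
    repeatability            r(j)  = (sigma2_a(j) + sigma2_pe(j)) / sigma2_P(j)

where the phenotypic variance sigma2_P(j) is the sum of additive,
permanent-environmental and residual variances.  The herd-test-day variance
is *excluded* from that denominator by default (it describes a shared
management environment, not the cow); `include_htd=True` adds it for
sensitivity analysis.

Between-day correlation surfaces use the same quadratic forms off the
diagonal; the phenotypic covariance between two distinct days carries no
residual contribution (residuals are independent across test days).

Standard errors of the curves are obtained by parametric sampling: parameter
vectors are drawn from the asymptotic normal of the REML estimates (the
inverse average-information matrix), each draw bent to the parameter space,
and the per-day empirical SD across draws is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import DimRange, basis_matrix, basis_vector
from .components import VarianceComponents, nearest_psd

__all__ = [
    "DailyCurve",
    "CorrelationSurface",
    "daily_variance",
    "variance_curve",
    "heritability_curve",
    "repeatability_curve",
    "correlation_surface",
    "curve_standard_errors",
]


@dataclass
class DailyCurve:
    dim: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None
    name: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"dim": self.dim, "value": self.values})
        if self.se is not None:
            out["se"] = self.se
        return out


@dataclass
class CorrelationSurface:
    dim: np.ndarray
    matrix: np.ndarray
    kind: str

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(range(len(self.dim)), range(len(self.dim)), indexing="ij")
        return pd.DataFrame(
            {
                "dim_i": self.dim[ii.ravel()],
                "dim_j": self.dim[jj.ravel()],
                "corr": self.matrix.ravel(),
            }
        )


def daily_variance(K: np.ndarray, j: int, dim_range: DimRange = DimRange()) -> float:
    """z_j' K z_j for a coefficient covariance K (kg^2)."""
    K = np.asarray(K, dtype=float)
    z = basis_vector(j, order=K.shape[0] - 1, dim_range=dim_range)
    if K.shape != (z.size, z.size):
        raise ValueError(f"covariance dimension {K.shape} does not match basis")
    return float(z @ K @ z)


def variance_curve(K: np.ndarray, dim_range: DimRange = DimRange()) -> DailyCurve:
    Z = basis_matrix(dim_range.days, np.asarray(K).shape[0] - 1, dim_range)
    return DailyCurve(dim=dim_range.days, values=np.einsum("ij,jk,ik->i", Z, K, Z))


def _phenotypic_parts(vc: VarianceComponents, dim_range: DimRange, include_htd: bool):
    Z = basis_matrix(dim_range.days, vc.order, dim_range)
    va = np.einsum("ij,jk,ik->i", Z, vc.G0, Z)
    vp = np.einsum("ij,jk,ik->i", Z, vc.P0, Z)
    denom = va + vp + vc.sigma2_e + (vc.sigma2_htd if include_htd else 0.0)
    if np.any(denom <= 0):
        raise ValueError("phenotypic variance is zero or negative on some day")
    return va, vp, denom


def heritability_curve(
    vc: VarianceComponents,
    dim_range: DimRange = DimRange(),
    include_htd: bool = False,
) -> DailyCurve:
    """h2(j) over the modelled DIM grid."""
    va, _, denom = _phenotypic_parts(vc, dim_range, include_htd)
    return DailyCurve(dim=dim_range.days, values=va / denom, name="heritability")


def repeatability_curve(
    vc: VarianceComponents,
    dim_range: DimRange = DimRange(),
    include_htd: bool = False,
) -> DailyCurve:
    """r(j) over the modelled DIM grid; always >= h2(j)."""
    va, vp, denom = _phenotypic_parts(vc, dim_range, include_htd)
    return DailyCurve(dim=dim_range.days, values=(va + vp) / denom, name="repeatability")


def correlation_surface(
    vc: VarianceComponents,
    kind: str = "genetic",
    dim_range: DimRange = DimRange(),
) -> CorrelationSurface:
    """Between-day genetic or phenotypic correlation matrix.

    Days with zero variance get NaN rows/columns (flagged undefined) rather
    than raising.
    """
    Z = basis_matrix(dim_range.days, vc.order, dim_range)
    if kind == "genetic":
        cov = Z @ vc.G0 @ Z.T
    elif kind == "phenotypic":
        cov = Z @ (vc.G0 + vc.P0) @ Z.T + vc.sigma2_e * np.eye(len(Z))
    else:
        raise ValueError(f"kind must be 'genetic' or 'phenotypic', got {kind!r}")
    cov = 0.5 * (cov + cov.T)  # exact symmetry (quadratic-form roundoff)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return CorrelationSurface(dim=dim_range.days, matrix=corr, kind=kind)


def curve_standard_errors(
    fit,
    kind: str = "heritability",
    dim_range: DimRange = DimRange(),
    n_draws: int = 1000,
    include_htd: bool = False,
    seed: int = 0,
) -> DailyCurve:
    """Per-day SE of a parameter curve by sampling the asymptotic normal.

    `fit` is a RemlFit carrying `param_cov` (inverse AI matrix).  Each draw is
    projected back to the parameter space (PSD bending, positive variances)
    before the curve is recomputed.
    """
    if fit.param_cov is None:
        raise ValueError("fit carries no asymptotic parameter covariance")
    vc0 = fit.varcomp
    k = vc0.G0.shape[0]
    m = k * (k + 1) // 2
    iu = np.triu_indices(k)
    mean = np.concatenate([vc0.G0[iu], vc0.P0[iu], [vc0.sigma2_htd, vc0.sigma2_e]])
    cov = nearest_psd(np.asarray(fit.param_cov), floor_frac=0.0)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="eigh")

    curves = np.empty((n_draws, dim_range.n_days))
    for i, th in enumerate(draws):
        G0 = np.zeros((k, k))
        G0[iu] = th[:m]
        G0 = nearest_psd(G0 + G0.T - np.diag(np.diag(G0)))
        P0 = np.zeros((k, k))
        P0[iu] = th[m : 2 * m]
        P0 = nearest_psd(P0 + P0.T - np.diag(np.diag(P0)))
        s2h = max(th[2 * m], 0.0)
        s2e = max(th[2 * m + 1], 1e-10)
        vc = VarianceComponents(G0, P0, s2e, s2h)
        if kind == "heritability":
            curves[i] = heritability_curve(vc, dim_range, include_htd).values
        elif kind == "repeatability":
            curves[i] = repeatability_curve(vc, dim_range, include_htd).values
        elif kind == "genetic_variance":
            curves[i] = variance_curve(vc.G0, dim_range).values
        elif kind == "pe_variance":
            curves[i] = variance_curve(vc.P0, dim_range).values
        else:
            raise ValueError(f"unknown curve kind {kind!r}")
    return DailyCurve(dim=dim_range.days, values=curves.mean(axis=0),
                      se=curves.std(axis=0, ddof=1), name=f"{kind}_se")
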