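"""Breeding values on the daily and 305-day scale.

An animal's estimated breeding value at DIM j is the quadratic-form-free
inner product EBV_mj = z_j' a_hat_m; its total over the standard lactation,
EBVT = sum_{j=5..305} EBV_mj, is the 305-day genetic merit in kg.  The
permanent-environment total TPe is the same functional applied to pe_hat
(defined only for cows with records), and the estimated total milk yield
deviation is TMY = EBVT + TPe — a genetic-plus-permanent deviation, not a
phenotypic forecast, since fixed effects and herd-test-day are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import DimRange, basis_matrix, basis_vector

__all__ = ["daily_ebv", "total_ebv", "total_pe", "total_milk_yield", "ebv_table"]


def _check(vec, j=None, dim_range=DimRange()):
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1:
        raise ValueError("coefficient vector must be 1-D")
    return vec


def daily_ebv(a_hat, j: int, dim_range: DimRange = DimRange()) -> float:
    """z_j' a_hat (kg/day)."""
    a_hat = _check(a_hat)
    z = basis_vector(j, order=a_hat.size - 1, dim_range=dim_range)
    return float(z @ a_hat)


def _summed_basis(order: int, dim_range: DimRange) -> np.ndarray:
    return basis_matrix(dim_range.days, order, dim_range).sum(axis=0)


def total_ebv(a_hat, dim_range: DimRange = DimRange()) -> float:
    """Sum of daily EBVs over the full modelled lactation (kg)."""
    a_hat = _check(a_hat)
    return float(_summed_basis(a_hat.size - 1, dim_range) @ a_hat)


def total_pe(pe_hat, dim_range: DimRange = DimRange()) -> float:
    """Summed permanent-environment value over the lactation (kg)."""
    return total_ebv(pe_hat, dim_range)


def total_milk_yield(a_hat, pe_hat, dim_range: DimRange = DimRange()) -> float:
    """TMY = EBVT + TPe (kg over days 5..305)."""
    return total_ebv(a_hat, dim_range) + total_pe(pe_hat, dim_range)


def ebv_table(solutions, dim_range: DimRange = DimRange(), daily: bool = False) -> pd.DataFrame:
    """Totals for every animal in a SolutionSet.

    TPe and TMY are NaN for animals without records (permanent environment is
    defined only for recorded cows).  With `daily=True`, wide per-day EBV
    columns are appended.
    """
    phi = _summed_basis(solutions.order, dim_range)
    ebvt = solutions.a_hat @ phi
    out = pd.DataFrame({"animal": solutions.animals, "ebvt": ebvt})
    tpe = pd.Series(solutions.pe_hat @ phi, index=solutions.recorded_cows)
    out["tpe"] = out["animal"].map(tpe)
    out["tmy"] = out["ebvt"] + out["tpe"]
    if daily:
        Z = basis_matrix(dim_range.days, solutions.order, dim_range)
        daily_vals = pd.DataFrame(
            solutions.a_hat @ Z.T, columns=[f"ebv_{d}" for d in dim_range.days]
        )
        out = pd.concat([out, daily_vals], axis=1)
    return out
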