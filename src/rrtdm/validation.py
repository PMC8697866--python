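"""Forward cross-validation of sequential genetic evaluations (LR method).

Yearly evaluation runs are emulated by slicing the edited dataset at
successive calendar-year cutoffs: partial dataset i contains records of cows
calving up to the cutoff year with test dates up to the end of that year, so
lactations in progress appear truncated exactly as they would in a real
evaluation.  Consecutive evaluations (i-1, i) are compared on the E-L cohort:
cows still in early lactation (latest DIM 5-90) at cutoff i-1 that have
reached late lactation (latest DIM 181-305) by cutoff i.  For the cohort's
total EBVs u the comparison statistics are

    b   = cov(u_i, u_{i-1}) / var(u_{i-1})      dispersion, expectation 1
    rho = corr(u_i, u_{i-1})                    population accuracy
    M   = mean(u_{i-1}) - mean(u_i)             bias, expectation 0

computed for the cohort cows and for their sires (the sires' own EBVs,
restricted to sires with enough recorded daughters).  The significance of
M = 0 is assessed with a paired bootstrap over animals, and early selection
of total milk yield is summarized by the cohort correlation of
TMY = EBVT + TPe between the two evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .basis import DimRange
from .components import VarianceComponents
from .ebv import ebv_table
from .editing import EditConfig, apply_edits
from .model import RemlOptions, build_model_frame, reml_estimate, solve_mme
from .pedigree import KinshipResult

__all__ = [
    "PartialDataset",
    "Cohort",
    "LRStatistics",
    "slice_partials",
    "run_sequential_evaluations",
    "el_cohort",
    "lr_statistics",
    "m_significance",
    "tmy_correlation",
    "sire_ebv_table",
    "forward_validate",
]

EARLY_DIM = (5, 90)
LATE_DIM = (181, 305)

# Partial datasets legitimately contain single-record lactations in progress,
# so per-partial re-editing keeps record-level rules only.
PARTIAL_EDITS = EditConfig(min_records=1, herd_min=0, year_min=0)


@dataclass
class PartialDataset:
    index: int
    cutoff_year: int
    records: pd.DataFrame


@dataclass
class Cohort:
    comparison: tuple               # (index_prev, index_next)
    cows: list
    sires: dict                     # sire -> number of cohort daughters
    qualifying_sires: list          # sires with >= min_daughters recorded daughters

    def __len__(self) -> int:
        return len(self.cows)


class LRStatistics(NamedTuple):
    b: float
    rho: float
    M: float
    n: int
    se_b: float = np.nan
    se_rho: float = np.nan
    se_M: float = np.nan


def _with_years(records: pd.DataFrame) -> pd.DataFrame:
    df = records
    if "calving_year" not in df.columns or "dim" not in df.columns:
        df = df.copy()
        cd, td = pd.to_datetime(df["calving_date"]), pd.to_datetime(df["test_date"])
        df["calving_year"] = cd.dt.year
        df["dim"] = (td - cd).dt.days
    return df


def slice_partials(records: pd.DataFrame, first_cut_year: int) -> list[PartialDataset]:
    """Nested yearly partial datasets, first cutoff after `first_cut_year`.

    Partial i keeps records with calving year <= cutoff AND test date within
    the cutoff year, so late tests of earlier calvers are excluded from the
    earlier partials.
    """
    df = _with_years(records)
    test_dates = pd.to_datetime(df["test_date"])
    if first_cut_year > int(df["calving_year"].max()):
        raise ValueError(
            f"first_cut_year {first_cut_year} is beyond the data "
            f"(last calving year {int(df['calving_year'].max())})"
        )
    # run until every record is included (tests may spill past the last calving year)
    last_year = max(int(df["calving_year"].max()), int(test_dates.dt.year.max()))
    partials = []
    for i, cut in enumerate(range(first_cut_year, last_year + 1), start=1):
        end = pd.Timestamp(year=cut, month=12, day=31)
        sub = df[(df["calving_year"] <= cut) & (test_dates <= end)]
        partials.append(PartialDataset(index=i, cutoff_year=cut, records=sub))
    return partials


def _latest_dim(records: pd.DataFrame, rule: str) -> pd.Series:
    if rule == "max":
        return records.groupby("cow")["dim"].max()
    if rule == "mean":
        return records.groupby("cow")["dim"].mean()
    raise ValueError(f"cohort rule must be 'max' or 'mean', got {rule!r}")


def el_cohort(
    prev: PartialDataset,
    nxt: PartialDataset,
    sire_of: dict,
    min_daughters: int = 5,
    rule: str = "max",
) -> Cohort:
    """Cows early (DIM 5-90) at the old cutoff and late (181-305) at the new one.

    Sire qualification counts a sire's recorded daughters in the *old* partial
    dataset, since cohort-internal daughter groups are tiny by construction.
    """
    early = _latest_dim(prev.records, rule)
    late = _latest_dim(nxt.records, rule)
    cows = sorted(
        set(early[(early >= EARLY_DIM[0]) & (early <= EARLY_DIM[1])].index)
        & set(late[(late >= LATE_DIM[0]) & (late <= LATE_DIM[1])].index)
    )
    if not cows:
        warnings.warn(
            f"empty E-L cohort for comparison ({prev.index}, {nxt.index}); "
            "statistics will be skipped"
        )
    sires = {}
    for cow in cows:
        s = sire_of.get(cow)
        if s is not None:
            sires[s] = sires.get(s, 0) + 1
    daughters_recorded = (
        prev.records.drop_duplicates("cow")["cow"].map(sire_of).value_counts()
    )
    qualifying = sorted(
        s for s in sires if daughters_recorded.get(s, 0) >= min_daughters
    )
    return Cohort(
        comparison=(prev.index, nxt.index), cows=cows, sires=sires, qualifying_sires=qualifying
    )


def lr_statistics(u_prev, u_next) -> LRStatistics:
    """Dispersion b, accuracy rho and bias M between two evaluations.

    `u_prev`, `u_next` are EBV-per-id mappings (dict or Series); statistics
    are computed on the ids present in both, with n-1 covariance denominators.
    """
    up = pd.Series(u_prev, dtype=float)
    un = pd.Series(u_next, dtype=float)
    ids = up.index.intersection(un.index)
    n = len(ids)
    if n < 2:
        raise ValueError(f"need >= 2 matched ids for LR statistics, got {n}")
    up, un = up[ids].to_numpy(), un[ids].to_numpy()
    if not (np.all(np.isfinite(up)) and np.all(np.isfinite(un))):
        raise ValueError("non-finite EBVs passed to lr_statistics")
    # shared centered products so identical inputs give (1, 1, 0) bit-exactly
    dup = up - up.mean()
    dun = un - un.mean()
    var_prev = float(dup @ dup) / (n - 1)
    var_next = float(dun @ dun) / (n - 1)
    cov = float(dup @ dun) / (n - 1)
    M = float(np.mean(up) - np.mean(un))
    d = up - un
    se_M = float(np.std(d, ddof=1) / np.sqrt(n))
    if var_prev <= 0:
        warnings.warn("zero variance in the older evaluation; b undefined")
        return LRStatistics(np.nan, np.nan, M, n, se_M=se_M)
    b = cov / var_prev
    rho = cov / np.sqrt(var_prev * var_next) if var_next > 0 else np.nan
    if n > 2:
        mse = max(var_next - cov**2 / var_prev, 0.0) * (n - 1) / (n - 2)
        se_b = float(np.sqrt(mse / ((n - 1) * var_prev)))
        se_rho = (
            float(np.sqrt(max(1 - rho**2, 0.0) / (n - 2))) if np.isfinite(rho) else np.nan
        )
    else:
        se_b = se_rho = np.nan
    return LRStatistics(float(b), float(rho), M, n, se_b, se_rho, se_M)


def m_significance(u_prev, u_next, n_boot: int = 2000, seed: int = 0) -> float:
    """Two-sided paired-bootstrap p-value for the bias M = 0."""
    up = pd.Series(u_prev, dtype=float)
    un = pd.Series(u_next, dtype=float)
    ids = up.index.intersection(un.index)
    if len(ids) < 10:
        raise ValueError(f"need >= 10 matched ids for the bootstrap, got {len(ids)}")
    d = (up[ids] - un[ids]).to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    m_star = d[idx].mean(axis=1)
    p = 2.0 * min(float(np.mean(m_star <= 0.0)), float(np.mean(m_star >= 0.0)))
    return min(p, 1.0)


def tmy_correlation(tmy_prev, tmy_next) -> float:
    """Pearson correlation of estimated total milk yield across the cohort."""
    tp = pd.Series(tmy_prev, dtype=float)
    tn = pd.Series(tmy_next, dtype=float)
    ids = tp.index.intersection(tn.index)
    if len(ids) < 2:
        raise ValueError("need >= 2 matched cows for the TMY correlation")
    a, b = tp[ids].to_numpy(), tn[ids].to_numpy()
    if np.var(a) == 0 or np.var(b) == 0:
        warnings.warn("zero TMY variance; correlation undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def sire_ebv_table(ebv_prev: pd.DataFrame, ebv_next: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """The qualifying sires' own EBVTs in the old and new evaluations."""
    prev = ebv_prev.set_index("animal")["ebvt"]
    nxt = ebv_next.set_index("animal")["ebvt"]
    rows = [
        {"sire": s, "ebvt_prev": prev[s], "ebvt_next": nxt[s], "n_cohort_daughters": cohort.sires[s]}
        for s in cohort.qualifying_sires
        if s in prev.index and s in nxt.index
    ]
    return pd.DataFrame(rows, columns=["sire", "ebvt_prev", "ebvt_next", "n_cohort_daughters"])


def run_sequential_evaluations(
    partials: list[PartialDataset],
    kin: KinshipResult,
    varcomp: VarianceComponents | None = None,
    order: int = 3,
    dim_range: DimRange = DimRange(),
    dim_class_width: int = 1,
    edit_config: EditConfig = PARTIAL_EDITS,
    reml_each_partial: bool = False,
    reml_options: RemlOptions | None = None,
) -> list[dict]:
    """Solve the MME for every partial dataset and tabulate EBVs.

    Variance components are normally estimated once (or supplied, e.g. the
    simulator's truth) and reused across partials, mirroring production
    systems; `reml_each_partial=True` re-estimates inside every evaluation.
    """
    if varcomp is None and not reml_each_partial:
        raise ValueError("supply variance components or set reml_each_partial=True")
    evaluations = []
    for part in partials:
        edited, report = apply_edits(part.records, edit_config)
        frame = build_model_frame(
            edited, kin, order=order, dim_range=dim_range, dim_class_width=dim_class_width
        )
        vc = varcomp
        if reml_each_partial:
            fit = reml_estimate(frame, kin, start=varcomp, options=reml_options or RemlOptions())
            vc = fit.varcomp
        try:
            solutions = solve_mme(frame, vc, kin)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"evaluation failed at partial {part.index}: {err}") from err
        evaluations.append(
            {
                "index": part.index,
                "cutoff_year": part.cutoff_year,
                "records": edited,
                "edit_report": report,
                "solutions": solutions,
                "ebv": ebv_table(solutions, dim_range),
            }
        )
    return evaluations


def forward_validate(
    records: pd.DataFrame,
    kin: KinshipResult,
    sire_of: dict,
    varcomp: VarianceComponents,
    first_cut_year: int,
    order: int = 3,
    dim_range: DimRange = DimRange(),
    dim_class_width: int = 1,
    min_daughters: int = 5,
    cohort_rule: str = "max",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Slice, evaluate and compare across all consecutive yearly cutoffs.

    Returns one row per comparison x group (cows, sires) with the LR triple,
    standard errors, the bootstrap p-value for M = 0 (cows with n >= 10) and
    the cohort TMY correlation (cows only).
    """
    partials = slice_partials(records, first_cut_year)
    evals = run_sequential_evaluations(
        partials, kin, varcomp=varcomp, order=order, dim_range=dim_range,
        dim_class_width=dim_class_width,
    )
    rows = []
    for prev_ev, next_ev, prev_pd, next_pd in zip(
        evals[:-1], evals[1:], partials[:-1], partials[1:]
    ):
        cohort = el_cohort(
            PartialDataset(prev_pd.index, prev_pd.cutoff_year, prev_ev["records"]),
            PartialDataset(next_pd.index, next_pd.cutoff_year, next_ev["records"]),
            sire_of,
            min_daughters=min_daughters,
            rule=cohort_rule,
        )
        if len(cohort) < 2:
            continue
        prev_ebv = prev_ev["ebv"].set_index("animal")
        next_ebv = next_ev["ebv"].set_index("animal")

        u_prev = prev_ebv.loc[cohort.cows, "ebvt"]
        u_next = next_ebv.loc[cohort.cows, "ebvt"]
        stats = lr_statistics(u_prev, u_next)
        p_m = (
            m_significance(u_prev, u_next, n_boot=n_boot, seed=seed + prev_pd.index)
            if len(cohort) >= 10
            else np.nan
        )
        rho_tmy = tmy_correlation(
            prev_ebv.loc[cohort.cows, "tmy"], next_ebv.loc[cohort.cows, "tmy"]
        )
        rows.append(
            {
                "comparison": prev_pd.index,
                "group": "cows",
                "n": stats.n,
                "b": stats.b,
                "se_b": stats.se_b,
                "rho": stats.rho,
                "se_rho": stats.se_rho,
                "M": stats.M,
                "se_M": stats.se_M,
                "p_M": p_m,
                "rho_tmy": rho_tmy,
            }
        )
        sires = sire_ebv_table(prev_ev["ebv"], next_ev["ebv"], cohort)
        if len(sires) >= 2:
            s_prev = sires.set_index("sire")["ebvt_prev"]
            s_next = sires.set_index("sire")["ebvt_next"]
            sstats = lr_statistics(s_prev, s_next)
            sp_m = (
                m_significance(s_prev, s_next, n_boot=n_boot, seed=seed + 10_000 + prev_pd.index)
                if len(sires) >= 10
                else np.nan
            )
            rows.append(
                {
                    "comparison": prev_pd.index,
                    "group": "sires",
                    "n": sstats.n,
                    "b": sstats.b,
                    "se_b": sstats.se_b,
                    "rho": sstats.rho,
                    "se_rho": sstats.se_rho,
                    "M": sstats.M,
                    "se_M": sstats.se_M,
                    "p_M": sp_m,
                    "rho_tmy": np.nan,
                }
            )
    return pd.DataFrame(rows)
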