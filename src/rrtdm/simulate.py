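"""Synthetic test-day data with known truth.

Generates pedigree + first-lactation test-day datasets with exactly the
generative structure the estimation model assumes: fixed herd-year, DIM and
age-at-calving effects, a random herd-test-day effect, additive-genetic and
permanent-environmental random-regression curves on the orthonormal Legendre
basis, and homogeneous residual noise.  Because every effect is drawn from
the model's own distributions (a ~ N(0, A otimes G0) realized by Mendelian
sampling down the pedigree), downstream estimators can be validated against
known truth.

What is emulated, and how:

* population structure: base sires and dams (founders), recorded daughters
  assigned a random sire/dam (progeny groups), herds crossed with calving
  years, calving dates uniform within the year, age at first calving drawn
  on [20, 50] months with its mode near 27 months;
* recording scheme: each herd tests all its cows on one day per month
  (herd-specific day of month), so herd-test-day groups contain several cows
  and a cow's first test falls at a DIM of roughly 5-35; records stop at
  DIM 305 or at the end of the data window, leaving lactations in progress
  truncated — the raw material for forward validation;
* the fixed lactation curve is a Wilmink-type rise-and-decline (peak around
  weeks 6-8), although estimation fits DIM as a free step function;
* herd-year solutions drift upward over years (management trend).

The default variance components were tuned once, numerically, so that the
implied daily heritability stays within about 0.14-0.18 (peak mid-lactation)
and repeatability within about 0.66-0.80 (minimum mid-lactation), and then
frozen; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .basis import DimRange, basis_matrix
from .components import VarianceComponents
from .pedigree import PedigreeEntry, KinshipResult, kinship

__all__ = [
    "SimConfig",
    "TrueEffects",
    "SimulatedData",
    "default_variance_components",
    "simulate_pedigree",
    "simulate_true_effects",
    "simulate_testday_records",
    "simulate_dataset",
]

# Frozen default coefficient covariances (orthonormal Legendre, order 3, kg^2).
_G0_DEFAULT = np.array(
    [
        [11.3648, 0.3892, -1.0528, -0.0160],
        [0.3892, 3.0087, 0.0203, -0.2507],
        [-1.0528, 0.0203, 0.3509, -0.0037],
        [-0.0160, -0.2507, -0.0037, 0.2728],
    ]
)
_P0_DEFAULT = np.array(
    [
        [33.5270, 2.3931, -1.6947, -0.0900],
        [2.3931, 15.2063, 0.1065, -0.6936],
        [-1.6947, 0.1065, 0.8915, -0.0065],
        [-0.0900, -0.6936, -0.0065, 0.8334],
    ]
)
_SIGMA2_E_DEFAULT = 13.2
_SIGMA2_HTD_DEFAULT = 2.2


def default_variance_components() -> VarianceComponents:
    """The frozen simulator truth (order 3)."""
    return VarianceComponents(
        G0=_G0_DEFAULT.copy(),
        P0=_P0_DEFAULT.copy(),
        sigma2_e=_SIGMA2_E_DEFAULT,
        sigma2_htd=_SIGMA2_HTD_DEFAULT,
    )


@dataclass
class SimConfig:
    n_herds: int = 8
    cows_per_herd_year: int = 6
    first_year: int = 2000
    last_year: int = 2007
    n_base_sires: int = 10
    n_base_dams: int = 150
    test_interval_days: int = 30  # informational; herds test once per calendar month
    order: int = 3
    dim_range: DimRange = field(default_factory=DimRange)
    varcomp: VarianceComponents | None = None
    # fixed curves
    hy_base_mean: float = 26.0      # kg/day, overall herd level
    hy_base_sd: float = 1.5         # spread between herds
    hy_trend: float = 0.30          # kg/day gained per calving year (management trend)
    hy_noise_sd: float = 0.5        # herd-year wobble around the trend
    age_peak_months: int = 27       # age-at-calving effect peaks here
    age_curvature: float = 0.010    # kg/day lost per (month - peak)^2
    wilmink_a: float = 5.0          # fixed DIM curve: a + b exp(-k j) + c j
    wilmink_b: float = -16.0
    wilmink_k: float = 0.08
    wilmink_c: float = -0.02
    seed: int = 20210712

    def __post_init__(self) -> None:
        if self.varcomp is None:
            self.varcomp = default_variance_components()
        if self.last_year - self.first_year < 7:
            raise ValueError(
                "calving years must span at least 7 years (>= 2 sequential evaluations)"
            )
        for name in ("n_herds", "cows_per_herd_year", "n_base_sires", "n_base_dams"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.varcomp.order != self.order:
            raise ValueError("varcomp order does not match basis order")

    @property
    def n_cows(self) -> int:
        return self.n_herds * self.cows_per_herd_year * (self.last_year - self.first_year + 1)

    @property
    def data_end(self) -> pd.Timestamp:
        return pd.Timestamp(year=self.last_year, month=12, day=31)


@dataclass
class TrueEffects:
    """Realized effects of one simulated population, in pedigree order."""

    a: np.ndarray                    # (n_animals, order+1) additive coefficients
    pe: dict                         # cow id -> (order+1,) permanent-environment vector
    htd: dict                        # (herd, test_date iso) -> scalar
    hy: dict                         # (herd, calving_year) -> scalar
    animals: list

    def total_genetic_value(self, dim_range: DimRange = DimRange()) -> np.ndarray:
        """True total (305-day) breeding values: sum_j z_j' a_m."""
        Z = basis_matrix(dim_range.days, self.a.shape[1] - 1, dim_range)
        return self.a @ Z.sum(axis=0)

    def to_json(self, path) -> None:
        payload = {
            "animals": list(self.animals),
            "a": np.asarray(self.a).tolist(),
            "pe": {c: v.tolist() for c, v in self.pe.items()},
            "htd": {f"{h}|{d}": v for (h, d), v in self.htd.items()},
            "hy": {f"{h}|{y}": v for (h, y), v in self.hy.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SimulatedData:
    records: pd.DataFrame
    pedigree: list
    kin: KinshipResult
    effects: TrueEffects
    cow_meta: pd.DataFrame
    config: SimConfig


def _herd_schedule(config: SimConfig) -> dict:
    """Monthly test dates per herd (herd-specific day of month), deterministic."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    offsets = rng.integers(1, 29, size=config.n_herds)
    end = config.data_end
    schedule = {}
    for h in range(config.n_herds):
        dates = []
        for year in range(config.first_year, config.last_year + 1):
            for month in range(1, 13):
                ts = pd.Timestamp(year=year, month=month, day=int(offsets[h]))
                if ts <= end:
                    dates.append(ts)
        schedule[f"H{h + 1:02d}"] = dates
    return schedule


def simulate_pedigree(config: SimConfig, seed: int | None = None):
    """Base sires/dams as founders plus recorded cows with known parents.

    Returns (entries, cow_meta): entries are parents-before-offspring; cow_meta
    has one row per recorded cow (herd, calving year/date, age at calving).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sires = [f"S{i + 1:03d}" for i in range(config.n_base_sires)]
    dams = [f"D{i + 1:03d}" for i in range(config.n_base_dams)]
    entries = [PedigreeEntry(s) for s in sires] + [PedigreeEntry(d) for d in dams]

    rows = []
    k = 0
    for year in range(config.first_year, config.last_year + 1):
        for h in range(config.n_herds):
            herd = f"H{h + 1:02d}"
            for _ in range(config.cows_per_herd_year):
                k += 1
                cow = f"C{k:05d}"
                sire = sires[rng.integers(config.n_base_sires)]
                dam = dams[rng.integers(config.n_base_dams)]
                entries.append(PedigreeEntry(cow, sire, dam))
                day_of_year = int(rng.integers(0, 365))
                calving = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(
                    days=day_of_year
                )
                age = 20 + int(np.floor(31 * rng.beta(2.0, 4.4)))
                rows.append(
                    {
                        "cow": cow,
                        "herd": herd,
                        "sire": sire,
                        "dam": dam,
                        "calving_year": year,
                        "calving_date": calving,
                        "age_months": min(age, 50),
                    }
                )
    return entries, pd.DataFrame(rows)


def simulate_true_effects(
    kin: KinshipResult, cow_meta: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> TrueEffects:
    """Draw every random effect from its model distribution.

    Founder additive vectors are N(0, G0); descendants get the parent average
    plus Mendelian sampling N(0, d * G0) with d = 1/2 - (F_s + F_d)/4, which
    realizes a ~ N(0, A otimes G0) exactly.  Permanent-environment vectors are
    N(0, P0) per recorded cow; herd-test-day effects N(0, sigma2_htd) per
    scheduled herd test date.
    """
    vc = config.varcomp
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    kdim = config.order + 1
    try:
        Lg = np.linalg.cholesky(vc.G0 + 1e-12 * np.eye(kdim))
    except np.linalg.LinAlgError as err:
        raise ValueError("G0 must be positive semidefinite") from err
    try:
        Lp = np.linalg.cholesky(vc.P0 + 1e-12 * np.eye(kdim))
    except np.linalg.LinAlgError as err:
        raise ValueError("P0 must be positive semidefinite") from err
    if np.allclose(vc.G0, 0.0):
        Lg = np.zeros_like(Lg)
    if np.allclose(vc.P0, 0.0):
        Lp = np.zeros_like(Lp)

    n = kin.n_animals
    a = np.zeros((n, kdim))
    idx = kin.index
    for i, e in enumerate(kin.entries):
        mean = np.zeros(kdim)
        if e.sire is not None:
            mean += 0.5 * a[idx[e.sire]]
        if e.dam is not None:
            mean += 0.5 * a[idx[e.dam]]
        d = kin.mendelian_d[i]
        a[i] = mean + np.sqrt(d) * (Lg @ rng.standard_normal(kdim))

    pe = {cow: Lp @ rng.standard_normal(kdim) for cow in cow_meta["cow"]}

    schedule = _herd_schedule(config)
    htd = {}
    for herd, dates in schedule.items():
        draws = rng.normal(0.0, np.sqrt(vc.sigma2_htd), size=len(dates))
        for date, v in zip(dates, draws):
            htd[(herd, date.date().isoformat())] = float(v)

    herds = sorted(cow_meta["herd"].unique())
    base = {h: config.hy_base_mean + rng.normal(0.0, config.hy_base_sd) for h in herds}
    hy = {}
    for h in herds:
        for year in range(config.first_year, config.last_year + 1):
            hy[(h, year)] = (
                base[h]
                + config.hy_trend * (year - config.first_year)
                + rng.normal(0.0, config.hy_noise_sd)
            )
    return TrueEffects(a=a, pe=pe, htd=htd, hy=hy, animals=kin.animals)


def dim_fixed_curve(dim, config: SimConfig):
    """Wilmink-type fixed lactation shape used by the generator."""
    dim = np.asarray(dim, dtype=float)
    return (
        config.wilmink_a
        + config.wilmink_b * np.exp(-config.wilmink_k * dim)
        + config.wilmink_c * dim
    )


def age_fixed_effect(age_months, config: SimConfig):
    age = np.asarray(age_months, dtype=float)
    return -config.age_curvature * (age - config.age_peak_months) ** 2


def simulate_testday_records(
    kin: KinshipResult,
    effects: TrueEffects,
    cow_meta: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble the test-day table: y = hy + dim + age + htd + z'a + z'pe + e."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    vc = config.varcomp
    schedule = _herd_schedule(config)
    lo, hi = config.dim_range.first_day, config.dim_range.last_day
    rows = []
    for cow, herd, year, calving, age in cow_meta[
        ["cow", "herd", "calving_year", "calving_date", "age_months"]
    ].itertuples(index=False):
        a_vec = effects.a[kin.index[cow]]
        pe_vec = effects.pe[cow]
        for test_date in schedule[herd]:
            dim = (test_date - calving).days
            if dim < lo or dim > hi or test_date > config.data_end:
                continue
            z = basis_matrix([dim], config.order, config.dim_range)[0]
            y = (
                effects.hy[(herd, year)]
                + dim_fixed_curve(dim, config)
                + age_fixed_effect(age, config)
                + effects.htd[(herd, test_date.date().isoformat())]
                + z @ a_vec
                + z @ pe_vec
                + rng.normal(0.0, np.sqrt(vc.sigma2_e))
            )
            rows.append(
                {
                    "cow": cow,
                    "herd": herd,
                    "calving_date": calving,
                    "test_date": test_date,
                    "age_months": age,
                    "milk_kg": float(y),
                    "milkings": 3,
                    "dim": dim,
                    "calving_year": year,
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Pedigree -> effects -> records, all seeded from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    s_ped, s_eff, s_rec = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    entries, cow_meta = simulate_pedigree(config, seed=s_ped)
    kin = kinship(entries)
    effects = simulate_true_effects(kin, cow_meta, config, seed=s_eff)
    records = simulate_testday_records(kin, effects, cow_meta, config, seed=s_rec)
    return SimulatedData(
        records=records,
        pedigree=entries,
        kin=kin,
        effects=effects,
        cow_meta=cow_meta,
        config=config,
    )
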