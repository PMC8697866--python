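"""Test-day record editing.

Raw milk-recording extracts carry implausible yields, out-of-window test
days, and thin herd/year cells that would leave fixed effects unestimable.
`apply_edits` applies the standard sequence of filters used for national
test-day evaluations, in a fixed order, and accounts for every removed
record exactly once (a record is attributed to the first rule that would
have removed it):

  1. daily milk yield within [5, 60] kg
  2. DIM within the modelled window (default [5, 305])
  3. number of milkings per day equal to the required value (default 3)
  4. cows must retain at least `min_records` test days (default 2)
  5. age at first calving within [20, 50] months
  6. herds and calving years must retain at least `herd_min` / `year_min`
     records (defaults 500 / 1000, configurable for small datasets)

Cow-level (4) and herd/year-level (6) counts change when other rules remove
records, so those two rules are re-applied until a fixed point: on exit no
rule would remove anything further, and re-running `apply_edits` on its own
output is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import pandas as pd

from .basis import DimRange

__all__ = ["EditConfig", "EditReport", "apply_edits", "read_records", "write_records"]

REQUIRED_COLUMNS = [
    "cow", "herd", "calving_date", "test_date", "age_months", "milk_kg", "milkings",
]

RULES = (
    "milk_range",
    "dim_range",
    "milkings",
    "min_records_per_cow",
    "age_at_calving",
    "herd_year_size",
)


@dataclass(frozen=True)
class EditConfig:
    milk_min: float = 5.0
    milk_max: float = 60.0
    dim_range: DimRange = DimRange()
    required_milkings: int = 3
    min_records: int = 2
    age_min: int = 20
    age_max: int = 50
    herd_min: int = 500
    year_min: int = 1000


@dataclass
class EditReport:
    """Per-rule attrition; removal counts sum to records_in - records_out."""

    records_in: int = 0
    records_out: int = 0
    rejected: int = 0  # unparseable rows (missing/non-numeric fields), kept aside
    removed: dict = field(default_factory=lambda: {r: 0 for r in RULES})
    cows_in: int = 0
    cows_out: int = 0
    herds_removed: int = 0
    years_removed: int = 0
    iterations: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _ensure_dim(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "dim" not in df.columns:
        cd = pd.to_datetime(df["calving_date"])
        td = pd.to_datetime(df["test_date"])
        df["dim"] = (td - cd).dt.days
    if "calving_year" not in df.columns:
        df["calving_year"] = pd.to_datetime(df["calving_date"]).dt.year
    return df


def apply_edits(records: pd.DataFrame, config: EditConfig = EditConfig()):
    """Filter a test-day table; returns (edited records, EditReport)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    df = _ensure_dim(records)
    report = EditReport(records_in=len(df), cows_in=df["cow"].nunique())

    # unparseable rows go to a rejects pile rather than aborting the edit
    for col in ("milk_kg", "dim", "age_months", "milkings"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    parseable = df[["cow", "herd", "milk_kg", "dim", "age_months", "milkings"]].notna().all(axis=1)
    report.rejected = int((~parseable).sum())
    df = df[parseable]

    keep = (df["milk_kg"] >= config.milk_min) & (df["milk_kg"] <= config.milk_max)
    report.removed["milk_range"] = int((~keep).sum())
    df = df[keep]

    keep = (df["dim"] >= config.dim_range.first_day) & (df["dim"] <= config.dim_range.last_day)
    report.removed["dim_range"] = int((~keep).sum())
    df = df[keep]

    keep = df["milkings"] == config.required_milkings
    report.removed["milkings"] = int((~keep).sum())
    df = df[keep]

    counts = df.groupby("cow")["milk_kg"].transform("size")
    keep = counts >= config.min_records
    report.removed["min_records_per_cow"] += int((~keep).sum())
    df = df[keep]

    keep = (df["age_months"] >= config.age_min) & (df["age_months"] <= config.age_max)
    report.removed["age_at_calving"] = int((~keep).sum())
    df = df[keep]

    # Cow-level and herd/year-level counts interact; iterate to a fixed point.
    herds_gone: set = set()
    years_gone: set = set()
    while True:
        report.iterations += 1
        n_before = len(df)

        counts = df.groupby("cow")["milk_kg"].transform("size")
        keep = counts >= config.min_records
        report.removed["min_records_per_cow"] += int((~keep).sum())
        df = df[keep]

        herd_counts = df.groupby("herd")["milk_kg"].transform("size")
        year_counts = df.groupby("calving_year")["milk_kg"].transform("size")
        keep = (herd_counts >= config.herd_min) & (year_counts >= config.year_min)
        df_small = df[~keep]
        report.removed["herd_year_size"] += len(df_small)
        herds_gone |= set(df_small["herd"].unique()) - set(df[keep]["herd"].unique())
        years_gone |= set(df_small["calving_year"].unique()) - set(
            df[keep]["calving_year"].unique()
        )
        df = df[keep]

        if len(df) == n_before:
            break

    report.records_out = len(df)
    report.cows_out = df["cow"].nunique()
    report.herds_removed = len(herds_gone)
    report.years_removed = len(years_gone)
    return df.reset_index(drop=True), report


def read_records(path) -> pd.DataFrame:
    """Read a test-day CSV (ISO-8601 dates) and derive DIM / calving year."""
    df = pd.read_csv(path, parse_dates=["calving_date", "test_date"])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing columns: {missing}")
    return _ensure_dim(df)


def write_records(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)
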