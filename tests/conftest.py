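import numpy as np
import pandas as pd
import pytest

from rrtdm.components import VarianceComponents
from rrtdm.pedigree import PedigreeEntry, kinship


def make_tiny_instance(
    seed: int,
    n_cows: int = 12,
    n_sires: int = 3,
    n_dams: int = 4,
    dims=(15, 75, 135, 195, 255),
    order: int = 3,
    sigma2_htd: float = 1.0,
):
    """Small random dataset with a coarse DIM grid (keeps fixed effects estimable).

    Returns (records, kin, varcomp).  Phenotypes are plain noise around a herd
    mean; for oracle-equivalence checks only the design structure matters.
    """
    rng = np.random.default_rng(seed)
    ped = [PedigreeEntry(f"S{i}") for i in range(1, n_sires + 1)]
    ped += [PedigreeEntry(f"D{i}") for i in range(1, n_dams + 1)]
    cows = []
    for i in range(n_cows):
        c = f"C{i + 1:03d}"
        ped.append(
            PedigreeEntry(c, f"S{1 + i % n_sires}", f"D{1 + i % n_dams}")
        )
        cows.append(c)
    kin = kinship(ped)

    rows = []
    for i, c in enumerate(cows):
        herd = f"H{1 + i % 2}"
        year = 2000 + (i // 2) % 2
        calv = pd.Timestamp(year, 1, 15)
        n_tests = rng.integers(2, len(dims) + 1)
        for dim in sorted(rng.choice(dims, size=n_tests, replace=False)):
            rows.append(
                dict(
                    cow=c,
                    herd=herd,
                    calving_date=calv,
                    test_date=calv + pd.Timedelta(days=int(dim)),
                    age_months=24 + i % 3,
                    milk_kg=float(rng.normal(25.0, 5.0)),
                    milkings=3,
                    dim=int(dim),
                    calving_year=year,
                )
            )
    records = pd.DataFrame(rows)

    k = order + 1
    A = rng.normal(size=(k, k))
    B = rng.normal(size=(k, k))
    vc = VarianceComponents(
        G0=A @ A.T + np.eye(k),
        P0=B @ B.T + np.eye(k),
        sigma2_e=float(rng.uniform(2.0, 5.0)),
        sigma2_htd=sigma2_htd,
    )
    return records, kin, vc


@pytest.fixture
def tiny_instance():
    return make_tiny_instance


def random_pedigree(rng: np.random.Generator, n: int):
    """Random acyclic pedigree with inbred loops (parents drawn from earlier animals)."""
    entries = []
    for i in range(n):
        name = f"A{i}"
        if i < 3 or rng.random() < 0.2:
            entries.append(PedigreeEntry(name))
            continue
        s = f"A{rng.integers(0, i)}"
        d = f"A{rng.integers(0, i)}"
        if s == d:
            d = None  # single known parent
        entries.append(PedigreeEntry(name, s, d))
    return entries
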