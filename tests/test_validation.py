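"""Partial-dataset slicing, E-L cohorts and the LR comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from rrtdm.validation import (
    PartialDataset,
    el_cohort,
    lr_statistics,
    m_significance,
    run_sequential_evaluations,
    sire_ebv_table,
    slice_partials,
    tmy_correlation,
)

RNG = np.random.default_rng(0)


def toy_records(calvings, tests):
    """calvings: cow -> (year, month); tests: cow -> list of DIM."""
    rows = []
    for cow, (year, month) in calvings.items():
        calv = pd.Timestamp(year, month, 1)
        for dim in tests[cow]:
            rows.append(
                dict(cow=cow, herd="H1", calving_date=calv,
                     test_date=calv + pd.Timedelta(days=int(dim)),
                     age_months=26, milk_kg=25.0, milkings=3,
                     dim=int(dim), calving_year=year)
            )
    return pd.DataFrame(rows)


class TestSlicePartials:
    def make_span(self, first, last):
        calvings = {f"C{y}": (y, 6) for y in range(first, last + 1)}
        tests = {c: [10, 40, 70] for c in calvings}
        return toy_records(calvings, tests)

    def test_long_span_count(self):
        partials = slice_partials(self.make_span(1990, 2015), 1995)
        assert len(partials) == 21
        assert partials[0].cutoff_year == 1995
        assert partials[-1].cutoff_year == 2015

    def test_eight_year_span_count(self):
        partials = slice_partials(self.make_span(2000, 2007), 2002)
        assert len(partials) == 6

    def test_partials_are_nested(self):
        partials = slice_partials(self.make_span(2000, 2007), 2002)
        for a, b in zip(partials[:-1], partials[1:]):
            ida = set(map(tuple, a.records[["cow", "test_date"]].itertuples(index=False)))
            idb = set(map(tuple, b.records[["cow", "test_date"]].itertuples(index=False)))
            assert ida <= idb

    def test_test_date_cutoff_truncates_lactations(self):
        # cow calves Nov 2000: later tests cross into 2001 and must be excluded
        rec = toy_records({"A": (2000, 11)}, {"A": [10, 40, 70, 100]})
        partials = slice_partials(rec, 2000)
        assert partials[0].records["dim"].max() == 40  # tests at 70/100 fall in 2001
        assert partials[-1].records["dim"].max() == 100

    def test_cut_beyond_data_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            slice_partials(self.make_span(2000, 2007), 2010)


class TestElCohort:
    def make_partials(self):
        prev = toy_records(
            {"EARLY": (2000, 10), "LATE": (2000, 5), "MID": (2000, 8)},
            {"EARLY": [35, 65], "LATE": [30, 60, 120, 180], "MID": [40, 120]},
        )
        nxt = toy_records(
            {"EARLY": (2000, 10), "LATE": (2000, 5), "MID": (2000, 8)},
            {"EARLY": [35, 65, 95, 155, 245], "LATE": [30, 60, 120, 180, 240, 300],
             "MID": [40, 120, 250, 290, 300]},
        )
        return (PartialDataset(1, 2000, prev), PartialDataset(2, 2001, nxt))

    def test_membership_by_max_dim_windows(self):
        prev, nxt = self.make_partials()
        cohort = el_cohort(prev, nxt, sire_of={}, min_daughters=1)
        assert cohort.cows == ["EARLY"]  # LATE/MID already past DIM 90 at cutoff

    def test_sire_qualification_by_recorded_daughters(self):
        prev, nxt = self.make_partials()
        sire_of = {"EARLY": "S1", "LATE": "S1", "MID": "S1"}
        cohort = el_cohort(prev, nxt, sire_of, min_daughters=3)
        assert cohort.qualifying_sires == ["S1"]
        cohort = el_cohort(prev, nxt, sire_of, min_daughters=4)
        assert cohort.qualifying_sires == []

    def test_empty_cohort_warns(self):
        prev, nxt = self.make_partials()
        empty_prev = PartialDataset(1, 2000, nxt.records)  # everyone already late
        with pytest.warns(UserWarning, match="empty"):
            cohort = el_cohort(empty_prev, nxt, sire_of={})
        assert len(cohort) == 0

    def test_mean_rule_differs_from_max(self):
        prev, nxt = self.make_partials()
        cohort = el_cohort(prev, nxt, sire_of={}, rule="mean")
        # MID: mean DIM 80 early, 200 late — in cohort under the mean rule only;
        # EARLY: mean DIM in the new partial is 119, not yet "late" on average
        assert "MID" in cohort.cows
        assert "EARLY" not in cohort.cows


class TestLrStatistics:
    def test_identity(self):
        u = pd.Series(RNG.normal(size=30))
        s = lr_statistics(u, u)
        assert (s.b, s.rho, s.M) == (1.0, 1.0, 0.0)

    def test_scaling(self):
        u = pd.Series(RNG.normal(size=30))
        s = lr_statistics(u, 2.0 * u)
        assert s.b == pytest.approx(2.0)
        assert s.rho == pytest.approx(1.0)
        assert s.M == pytest.approx(-u.mean())

    def test_shift(self):
        u = pd.Series(RNG.normal(size=30))
        s = lr_statistics(u, u + 3.0)
        assert s.b == pytest.approx(1.0)
        assert s.rho == pytest.approx(1.0)
        assert s.M == pytest.approx(-3.0)

    def test_relabeling_invariance(self):
        ids = [f"A{i}" for i in range(25)]
        u1 = pd.Series(RNG.normal(size=25), index=ids)
        u2 = pd.Series(RNG.normal(size=25), index=ids)
        s = lr_statistics(u1, u2)
        perm = RNG.permutation(25)
        relabel = {a: f"B{i}" for i, a in enumerate(np.array(ids)[perm])}
        s2 = lr_statistics(u1.rename(index=relabel), u2.rename(index=relabel))
        assert s2.b == pytest.approx(s.b)
        assert s2.rho == pytest.approx(s.rho)
        assert s2.M == pytest.approx(s.M)

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            lr_statistics(pd.Series([1.0]), pd.Series([1.0]))

    def test_zero_prev_variance_flagged(self):
        u = pd.Series(np.ones(10))
        with pytest.warns(UserWarning, match="zero variance"):
            s = lr_statistics(u, pd.Series(RNG.normal(size=10)))
        assert np.isnan(s.b)


class TestMSignificance:
    def test_identical_gives_p_one(self):
        u = pd.Series(RNG.normal(size=20))
        assert m_significance(u, u.copy()) == 1.0

    def test_large_shift_collapses_p(self):
        u = pd.Series(RNG.normal(size=40))
        p = m_significance(u, u + 100.0, n_boot=2000, seed=1)
        assert p <= 1.0 / 2000

    def test_deterministic_given_seed(self):
        u = pd.Series(RNG.normal(size=25))
        v = u + RNG.normal(size=25) * 0.5
        assert m_significance(u, v, seed=9) == m_significance(u, v, seed=9)

    def test_small_n_refused(self):
        u = pd.Series(RNG.normal(size=5))
        with pytest.raises(ValueError, match=">= 10"):
            m_significance(u, u)


class TestTmyCorrelation:
    def test_identical_is_one(self):
        t = pd.Series(RNG.normal(size=15))
        assert tmy_correlation(t, t.copy()) == pytest.approx(1.0)

    def test_anti_ordered_is_minus_one(self):
        t = pd.Series(np.arange(10.0))
        assert tmy_correlation(t, -t) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        n = 4000
        a = pd.Series(np.random.default_rng(1).normal(size=n))
        b = pd.Series(np.random.default_rng(2).normal(size=n))
        assert abs(tmy_correlation(a, b)) < 3 / np.sqrt(n)


class TestSequentialEvaluations:
    def test_identical_partials_give_degenerate_statistics(self, tiny_instance):
        records, kin, vc = tiny_instance(3, n_cows=14)
        partials = [
            PartialDataset(1, 2001, records),
            PartialDataset(2, 2002, records),
        ]
        evals = run_sequential_evaluations(partials, kin, varcomp=vc)
        cows = evals[0]["ebv"].dropna(subset=["tpe"])["animal"]
        u1 = evals[0]["ebv"].set_index("animal").loc[cows, "ebvt"]
        u2 = evals[1]["ebv"].set_index("animal").loc[cows, "ebvt"]
        s = lr_statistics(u1, u2)
        assert (s.b, s.rho, s.M) == (1.0, 1.0, 0.0)

    def test_later_partial_covers_more_animals(self, tiny_instance):
        records, kin, vc = tiny_instance(4, n_cows=14)
        half = records[records["calving_year"] == 2000]
        partials = [PartialDataset(1, 2000, half), PartialDataset(2, 2001, records)]
        evals = run_sequential_evaluations(partials, kin, varcomp=vc)
        rec1 = set(evals[0]["ebv"].dropna(subset=["tpe"])["animal"])
        rec2 = set(evals[1]["ebv"].dropna(subset=["tpe"])["animal"])
        assert rec1 < rec2


class TestSireTable:
    def test_single_shared_sire_gives_one_row(self):
        ebv_prev = pd.DataFrame({"animal": ["S1", "C1", "C2"], "ebvt": [1.0, 2.0, 3.0]})
        ebv_next = pd.DataFrame({"animal": ["S1", "C1", "C2"], "ebvt": [1.5, 2.5, 3.5]})
        cohort_cows = ["C1", "C2"]
        from rrtdm.validation import Cohort

        cohort = Cohort((1, 2), cohort_cows, {"S1": 2}, ["S1"])
        table = sire_ebv_table(ebv_prev, ebv_next, cohort)
        assert len(table) == 1
        assert table.iloc[0]["ebvt_prev"] == 1.0

    def test_unqualified_sire_absent(self):
        from rrtdm.validation import Cohort

        ebv = pd.DataFrame({"animal": ["S1", "S2"], "ebvt": [1.0, 2.0]})
        cohort = Cohort((1, 2), ["C1"], {"S1": 1, "S2": 1}, ["S2"])
        table = sire_ebv_table(ebv, ebv, cohort)
        assert list(table["sire"]) == ["S2"]
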