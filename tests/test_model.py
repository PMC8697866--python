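"""MME assembly/solving vs the dense GLS oracle, REML likelihood and LRT."""

import numpy as np
import pandas as pd
import pytest

from rrtdm.components import VarianceComponents
from rrtdm.model import (
    RemlFit,
    RemlOptions,
    assemble_mme,
    build_model_frame,
    dense_reml_log_likelihood,
    gls_blup_oracle,
    likelihood_ratio_test,
    reml_estimate,
    reml_log_likelihood,
    solve_mme,
)
from rrtdm.pedigree import PedigreeEntry, kinship

P = PedigreeEntry


def fixed_vector(sol):
    return np.concatenate(
        [
            np.array(list(sol.fixed["herd_year"].values())),
            np.array(list(sol.fixed["dim"].values())),
            np.array(list(sol.fixed["age"].values())),
        ]
    )


class TestModelFrame:
    def test_level_counts(self, tiny_instance):
        records, kin, _ = tiny_instance(0, n_cows=8)
        frame = build_model_frame(records, kin)
        assert len(frame.hy_levels) == 4  # 2 herds x 2 years
        assert len(frame.htd_levels) == records.groupby(["herd", "test_date"]).ngroups

    def test_same_htd_level_for_same_herd_and_date(self, tiny_instance):
        records, kin, _ = tiny_instance(1)
        frame = build_model_frame(records, kin)
        sub = records[["herd", "test_date"]].drop_duplicates()
        assert len(frame.htd_levels) == len(sub)

    def test_toy_frame_dimensions_by_hand(self):
        ped = [P("S"), P("D"), P("C1", "S", "D"), P("C2", "S", "D")]
        kin = kinship(ped)
        calv = pd.Timestamp(2001, 2, 1)
        rows = [
            dict(cow=c, herd="H1", calving_date=calv,
                 test_date=calv + pd.Timedelta(days=d), age_months=25,
                 milk_kg=20.0, milkings=3, dim=d, calving_year=2001)
            for c in ("C1", "C2") for d in (30, 90, 150)
        ]
        frame = build_model_frame(pd.DataFrame(rows), kin)
        # 1 hy + (3-1) dim + (1-1) age fixed columns; 3 htd; 4 animals x 4; 2 cows x 4
        assert frame.n_fixed == 1 + 2 + 0
        assert frame.block_offsets["total"] == 3 + 3 + 16 + 8

    def test_unknown_cow_rejected(self, tiny_instance):
        records, kin, _ = tiny_instance(2)
        records = pd.concat(
            [records, records.iloc[[0]].assign(cow="GHOST")], ignore_index=True
        )
        with pytest.raises(ValueError, match="GHOST"):
            build_model_frame(records, kin)


class TestAssemble:
    def test_one_record_order0_hand_built(self):
        kin = kinship([P("C1")])
        calv = pd.Timestamp(2000, 1, 1)
        rec = pd.DataFrame(
            [dict(cow="C1", herd="H1", calving_date=calv,
                  test_date=calv + pd.Timedelta(days=155), age_months=25,
                  milk_kg=30.0, milkings=3, dim=155, calving_year=2000)]
        )
        vc = VarianceComponents(np.eye(1), np.eye(1), 1.0, 1.0)
        frame = build_model_frame(rec, kin, order=0)
        C, rhs = assemble_mme(frame, vc, kin)
        z = np.sqrt(0.5)
        w = np.array([1.0, 1.0, z, z])
        expected = np.outer(w, w) + np.diag([0.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(C.toarray(), expected, atol=1e-12)
        np.testing.assert_allclose(rhs, w * 30.0)

    def test_lhs_exactly_symmetric(self, tiny_instance):
        records, kin, vc = tiny_instance(3)
        frame = build_model_frame(records, kin)
        C, _ = assemble_mme(frame, vc, kin)
        assert np.abs((C - C.T)).max() == 0.0

    def test_singular_g0_rejected(self, tiny_instance):
        records, kin, vc = tiny_instance(4)
        bad = VarianceComponents(np.zeros((4, 4)), vc.P0, vc.sigma2_e, vc.sigma2_htd)
        frame = build_model_frame(records, kin)
        with pytest.raises(np.linalg.LinAlgError, match="bend|singular"):
            assemble_mme(frame, bad, kin)


class TestSolveVsOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_gls_blup(self, tiny_instance, seed):
        records, kin, vc = tiny_instance(seed)
        frame = build_model_frame(records, kin)
        sol = solve_mme(frame, vc, kin)
        oracle = gls_blup_oracle(records, kin, vc)
        np.testing.assert_allclose(sol.a_hat, oracle.a_hat, atol=1e-6)
        np.testing.assert_allclose(sol.pe_hat, oracle.pe_hat, atol=1e-6)
        np.testing.assert_allclose(fixed_vector(sol), fixed_vector(oracle), atol=1e-6)

    def test_constant_shift_moves_only_fixed_effects(self, tiny_instance):
        records, kin, vc = tiny_instance(7)
        frame = build_model_frame(records, kin)
        sol0 = solve_mme(frame, vc, kin)
        shifted = records.assign(milk_kg=records["milk_kg"] + 10.0)
        frame1 = build_model_frame(shifted, kin)
        sol1 = solve_mme(frame1, vc, kin)
        np.testing.assert_allclose(sol1.a_hat, sol0.a_hat, atol=1e-8)
        np.testing.assert_allclose(sol1.pe_hat, sol0.pe_hat, atol=1e-8)
        hy0 = np.array(list(sol0.fixed["herd_year"].values()))
        hy1 = np.array(list(sol1.fixed["herd_year"].values()))
        np.testing.assert_allclose(hy1 - hy0, 10.0, atol=1e-8)

    def test_unrecorded_ancestor_gets_parent_average(self, tiny_instance):
        records, kin, vc = tiny_instance(8, n_cows=10)
        # add an unrecorded terminal offspring of two recorded cows
        entries = list(kin.entries) + [PedigreeEntry("X", "C001", "C002")]
        kin2 = kinship(entries)
        frame = build_model_frame(records, kin2)
        sol = solve_mme(frame, vc, kin2)
        np.testing.assert_allclose(
            sol.a_of("X"), 0.5 * (sol.a_of("C001") + sol.a_of("C002")), atol=1e-8
        )

    def test_ols_limit_of_oracle(self, tiny_instance):
        records, kin, _ = tiny_instance(9)
        vc0 = VarianceComponents(
            np.zeros((4, 4)), np.zeros((4, 4)), sigma2_e=2.0, sigma2_htd=0.0
        )
        oracle = gls_blup_oracle(records, kin, vc0)
        frame = build_model_frame(records, kin)
        X, y = frame.X.toarray(), frame.y
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        kept = np.concatenate(
            [
                [v for k, v in oracle.fixed["herd_year"].items()],
                [v for k, v in oracle.fixed["dim"].items() if k != frame.dropped["dim"]],
                [v for k, v in oracle.fixed["age"].items() if k != frame.dropped["age"]],
            ]
        )
        np.testing.assert_allclose(kept, beta, atol=1e-8)
        np.testing.assert_allclose(oracle.a_hat, 0.0, atol=1e-12)


class TestRemlLogLikelihood:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_formula(self, tiny_instance, seed):
        records, kin, vc = tiny_instance(20 + seed)
        frame = build_model_frame(records, kin)
        sparse_l = reml_log_likelihood(frame, vc, kin)
        dense_l = dense_reml_log_likelihood(records, kin, vc)
        assert sparse_l == pytest.approx(dense_l, abs=1e-6)

    def test_invariant_to_record_order(self, tiny_instance):
        records, kin, vc = tiny_instance(30)
        shuffled = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        l0 = reml_log_likelihood(build_model_frame(records, kin), vc, kin)
        l1 = reml_log_likelihood(build_model_frame(shuffled, kin), vc, kin)
        assert l0 == pytest.approx(l1, abs=1e-8)

    def test_decreases_for_inflated_residual_variance(self, tiny_instance):
        records, kin, vc = tiny_instance(31)
        frame = build_model_frame(records, kin)
        logls = []
        for s2e in (50.0, 150.0, 500.0, 2000.0):
            v = VarianceComponents(vc.G0, vc.P0, s2e, vc.sigma2_htd)
            logls.append(reml_log_likelihood(frame, v, kin))
        assert np.all(np.diff(logls) < 0)


class TestRemlEstimate:
    def test_trace_monotone_and_estimates_valid(self, tiny_instance):
        records, kin, vc = tiny_instance(40, n_cows=20)
        frame = build_model_frame(records, kin, order=1)
        fit = reml_estimate(frame, kin, options=RemlOptions(max_iter=25, tol=1e-4))
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7)
        assert np.linalg.eigvalsh(fit.varcomp.G0).min() >= 0
        assert np.linalg.eigvalsh(fit.varcomp.P0).min() >= 0
        assert fit.varcomp.sigma2_e > 0
        assert fit.param_cov.shape == (8, 8)

    def test_start_at_rich_likelihood_point_stays(self, tiny_instance):
        records, kin, vc = tiny_instance(41, n_cows=24)
        frame = build_model_frame(records, kin, order=0)
        fit = reml_estimate(frame, kin, options=RemlOptions(max_iter=40, tol=1e-5))
        refit = reml_estimate(
            frame, kin, start=fit.varcomp, options=RemlOptions(max_iter=5, tol=1e-5)
        )
        # restarting at the optimum must not move the likelihood materially
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-2)


class TestLikelihoodRatioTest:
    def make_fit(self, order, loglik, n_records=100):
        k = order + 1
        vc = VarianceComponents(np.eye(k), np.eye(k), 1.0, 0.1)
        n_par = vc.n_parameters
        return RemlFit(
            varcomp=vc, loglik=loglik, loglik_trace=[loglik], converged=True,
            n_iter=1, param_cov=np.eye(n_par), param_names=[""] * n_par,
            order=order, n_records=n_records, n_animals=10,
        )

    def test_identical_likelihoods_give_zero_statistic(self):
        stat, df, p = likelihood_ratio_test(self.make_fit(2, -50.0), self.make_fit(3, -50.0))
        assert stat == 0.0 and p == 1.0

    def test_df_counts_free_covariance_parameters(self):
        _, df, _ = likelihood_ratio_test(self.make_fit(2, -60.0), self.make_fit(3, -55.0))
        assert df == 2 * (10 - 6)
        _, df, _ = likelihood_ratio_test(self.make_fit(0, -60.0), self.make_fit(1, -55.0))
        assert df == 2 * (3 - 1)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(self.make_fit(3, -50.0), self.make_fit(2, -49.0))
        with pytest.raises(ValueError, match="same data"):
            likelihood_ratio_test(
                self.make_fit(2, -50.0), self.make_fit(3, -49.0, n_records=99)
            )

    def test_rejection_rate_not_anticonservative_under_null(self, tiny_instance):
        # order-0 truth; testing 0 vs 1 should reject ~ nominal level or less
        # (boundary effects make the chi-square reference conservative)
        rejections = 0
        n_rep = 8
        for seed in range(n_rep):
            records, kin, _ = tiny_instance(500 + seed, n_cows=16, sigma2_htd=0.5)
            frame0 = build_model_frame(records, kin, order=0)
            frame1 = build_model_frame(records, kin, order=1)
            opts = RemlOptions(max_iter=20, tol=1e-4)
            fit0 = reml_estimate(frame0, kin, options=opts)
            fit1 = reml_estimate(frame1, kin, options=opts)
            _, _, p = likelihood_ratio_test(fit0, fit1)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 3 * se
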