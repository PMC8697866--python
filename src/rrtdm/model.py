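"""Mixed model equations and REML for the random-regression test-day model.

The observation model for daily milk yield is

    y = hy(i) + dim(j) + age(k) + htd(l) + z_j' a_m + z_j' pe_m + e,

with herd-year, DIM-class and age-class fixed effects, a random herd-test-day
effect with variance sigma2_htd, animal-specific additive (a_m) and permanent
environmental (pe_m) regression-coefficient vectors on the Legendre basis,
and homogeneous residual variance sigma2_e.  Stacking the records as
y = X beta + Z_h h + Z_a a + Z_p p + e, Henderson's mixed model equations are

    [ W'W / s2e + diag(0, I/s2htd, Ainv x G0inv, I x P0inv) ] sol = W'y / s2e

with W = [X | Z_h | Z_a | Z_p] and x the Kronecker product (animal-major
ordering, so the additive prior block is kron(Ainv, G0inv)).

Variance components are estimated by average-information REML with an EM
fallback: the AI step uses exact first derivatives and the average of the
observed and expected information; whenever it leaves the parameter space or
decreases the restricted likelihood, the update is stepped back towards the
EM update, which can only increase it.  All trace terms are computed exactly
from a dense inverse of the coefficient matrix, which is affordable at the
scale this package targets (coefficient matrices up to ~10k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri
from scipy.sparse.linalg import splu
from scipy.stats import chi2

from .basis import DimRange, basis_matrix
from .components import VarianceComponents, nearest_psd
from .pedigree import KinshipResult, relationship_matrix_tabular

__all__ = [
    "ModelFrame",
    "SolutionSet",
    "RemlFit",
    "RemlOptions",
    "build_model_frame",
    "assemble_mme",
    "solve_mme",
    "gls_blup_oracle",
    "reml_log_likelihood",
    "reml_estimate",
    "likelihood_ratio_test",
    "start_values",
]

_ORACLE_MAX_RECORDS = 300
_ORACLE_MAX_ANIMALS = 100


def _sym_splu(C):
    """Sparse LU with a fill-reducing ordering suited to symmetric matrices."""
    return splu(C, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))


# ---------------------------------------------------------------------------
# model frame


@dataclass
class ModelFrame:
    """Design matrices and level maps for one dataset."""

    X: sparse.csr_matrix
    Zh: sparse.csr_matrix
    Za: sparse.csr_matrix
    Zp: sparse.csr_matrix
    y: np.ndarray
    hy_levels: list
    dim_levels: list
    age_levels: list
    htd_levels: list
    dropped: dict
    animals: list
    recorded_cows: list
    order: int
    dim_range: DimRange
    _W: sparse.csr_matrix = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return self.order + 1

    @property
    def W(self) -> sparse.csr_matrix:
        if self._W is None:
            self._W = sparse.hstack([self.X, self.Zh, self.Za, self.Zp]).tocsr()
        return self._W

    @property
    def block_offsets(self) -> dict:
        nf, nh = self.n_fixed, len(self.htd_levels)
        na, nq, k = len(self.animals), len(self.recorded_cows), self.k
        o_h = nf
        o_a = o_h + nh
        o_p = o_a + na * k
        return {"fixed": 0, "htd": o_h, "a": o_a, "pe": o_p, "total": o_p + nq * k}


def _one_hot(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def build_model_frame(
    records: pd.DataFrame,
    kin: KinshipResult,
    order: int = 3,
    dim_range: DimRange = DimRange(),
    dim_class_width: int = 1,
) -> ModelFrame:
    """Map records onto factor levels and covariates.

    Fixed factors: herd-year (full), DIM class (reference level = the class
    containing day 305 or the largest observed, set to zero) and age class
    (reference = 50 months or the largest observed, set to zero).  By default
    every integer DIM is its own class (a step function free at every day);
    `dim_class_width > 1` pools adjacent days, which small datasets need to
    keep the step function estimable.  Every record must cite a cow present
    in the pedigree.
    """
    df = records
    missing = sorted(set(df["cow"]) - set(kin.index))
    if missing:
        raise ValueError(f"records cite animals absent from pedigree: {missing[:10]}")

    if "dim" not in df.columns or "calving_year" not in df.columns:
        df = df.copy()
        cd, td = pd.to_datetime(df["calving_date"]), pd.to_datetime(df["test_date"])
        df["dim"] = (td - cd).dt.days
        df["calving_year"] = cd.dt.year

    hy = list(zip(df["herd"], df["calving_year"]))
    htd = list(zip(df["herd"], pd.to_datetime(df["test_date"])))
    hy_levels = sorted(set(hy))
    htd_levels = sorted(set(htd))
    if dim_class_width < 1:
        raise ValueError("dim_class_width must be >= 1")
    lo = dim_range.first_day
    dim_class = (lo + ((df["dim"] - lo) // dim_class_width) * dim_class_width).astype(int)
    dim_levels = sorted(dim_class.unique())
    age_levels = sorted(df["age_months"].unique())
    ref_dim = lo + ((dim_range.last_day - lo) // dim_class_width) * dim_class_width
    drop_dim = ref_dim if ref_dim in dim_levels else dim_levels[-1]
    drop_age = 50 if 50 in age_levels else age_levels[-1]

    hy_code = {v: i for i, v in enumerate(hy_levels)}
    htd_code = {v: i for i, v in enumerate(htd_levels)}
    dim_kept = [d for d in dim_levels if d != drop_dim]
    age_kept = [a for a in age_levels if a != drop_age]
    dim_code = {v: i for i, v in enumerate(dim_kept)}
    age_code = {v: i for i, v in enumerate(age_kept)}

    n = len(df)
    X_hy = _one_hot(np.array([hy_code[v] for v in hy]), len(hy_levels))
    rows, cols = [], []
    for r, d in enumerate(dim_class):
        if d in dim_code:
            rows.append(r)
            cols.append(dim_code[d])
    X_dim = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(dim_kept))
    )
    rows, cols = [], []
    for r, a in enumerate(df["age_months"]):
        if a in age_code:
            rows.append(r)
            cols.append(age_code[a])
    X_age = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(age_kept))
    )
    X = sparse.hstack([X_hy, X_dim, X_age]).tocsr()
    Zh = _one_hot(np.array([htd_code[v] for v in htd]), len(htd_levels))

    k = order + 1
    Z = basis_matrix(df["dim"].to_numpy(), order, dim_range)
    na = kin.n_animals
    cow_idx = df["cow"].map(kin.index).to_numpy()
    rows = np.repeat(np.arange(n), k)
    cols = (cow_idx[:, None] * k + np.arange(k)[None, :]).ravel()
    Za = sparse.csr_matrix((Z.ravel(), (rows, cols)), shape=(n, na * k))

    recorded = sorted(df["cow"].unique(), key=lambda c: kin.index[c])
    pe_code = {c: i for i, c in enumerate(recorded)}
    pe_idx = df["cow"].map(pe_code).to_numpy()
    cols = (pe_idx[:, None] * k + np.arange(k)[None, :]).ravel()
    Zp = sparse.csr_matrix((Z.ravel(), (rows, cols)), shape=(n, len(recorded) * k))

    return ModelFrame(
        X=X,
        Zh=Zh,
        Za=Za,
        Zp=Zp,
        y=df["milk_kg"].to_numpy(dtype=float),
        hy_levels=hy_levels,
        dim_levels=dim_levels,
        age_levels=age_levels,
        htd_levels=htd_levels,
        dropped={"dim": drop_dim, "age": drop_age},
        animals=list(kin.animals),
        recorded_cows=recorded,
        order=order,
        dim_range=dim_range,
    )


# ---------------------------------------------------------------------------
# MME assembly and solving


def _prior_blocks(frame: ModelFrame, vc: VarianceComponents, kin: KinshipResult):
    k = frame.k
    for name, K in (("G0", vc.G0), ("P0", vc.P0)):
        if np.linalg.cond(K) > 1e12:
            raise np.linalg.LinAlgError(
                f"{name} is singular or nearly so; bend it towards positive "
                "definiteness or reduce the polynomial order"
            )
    G0inv = np.linalg.inv(vc.G0)
    P0inv = np.linalg.inv(vc.P0)
    G0inv = 0.5 * (G0inv + G0inv.T)  # exact symmetry for an exactly symmetric LHS
    P0inv = 0.5 * (P0inv + P0inv.T)
    nh, nq = len(frame.htd_levels), len(frame.recorded_cows)
    if vc.sigma2_htd <= 0 and nh > 0:
        raise ValueError("sigma2_htd must be > 0 when herd-test-day levels are present")
    blocks = [
        sparse.csr_matrix((frame.n_fixed, frame.n_fixed)),
        sparse.identity(nh, format="csr") / vc.sigma2_htd if nh else sparse.csr_matrix((0, 0)),
        sparse.kron(kin.a_inv, G0inv, format="csr"),
        sparse.kron(sparse.identity(nq), P0inv, format="csr"),
    ]
    return sparse.block_diag(blocks, format="csr")


def assemble_mme(frame: ModelFrame, vc: VarianceComponents, kin: KinshipResult):
    """Sparse symmetric (LHS, RHS) of Henderson's equations."""
    W = frame.W
    C = (W.T @ W) / vc.sigma2_e + _prior_blocks(frame, vc, kin)
    C = 0.5 * (C + C.T)  # enforce exact symmetry against sparse-product roundoff
    rhs = W.T @ frame.y / vc.sigma2_e
    return C.tocsc(), rhs


@dataclass
class SolutionSet:
    """MME solutions: fixed-effect levels, htd, and per-animal coefficient vectors."""

    fixed: dict                      # factor -> {level: solution}; dropped levels at 0.0
    htd: dict                        # (herd, test_date) -> solution
    a_hat: np.ndarray                # (n_animals, order+1)
    pe_hat: np.ndarray               # (n_recorded, order+1)
    animals: list
    recorded_cows: list
    order: int
    residual_norm: float = np.nan

    def a_of(self, animal) -> np.ndarray:
        return self.a_hat[self.animals.index(animal)]


def _unpack_solution(frame: ModelFrame, sol: np.ndarray, residual_norm=np.nan) -> SolutionSet:
    off = frame.block_offsets
    nf_hy = len(frame.hy_levels)
    kept_dim = [d for d in frame.dim_levels if d != frame.dropped["dim"]]
    kept_age = [a for a in frame.age_levels if a != frame.dropped["age"]]
    fixed = {
        "herd_year": dict(zip(frame.hy_levels, sol[:nf_hy])),
        "dim": dict(zip(kept_dim, sol[nf_hy : nf_hy + len(kept_dim)])),
        "age": dict(
            zip(kept_age, sol[nf_hy + len(kept_dim) : nf_hy + len(kept_dim) + len(kept_age)])
        ),
    }
    fixed["dim"][frame.dropped["dim"]] = 0.0
    fixed["age"][frame.dropped["age"]] = 0.0
    htd = dict(zip(frame.htd_levels, sol[off["htd"] : off["a"]]))
    k = frame.k
    a_hat = sol[off["a"] : off["pe"]].reshape(-1, k)
    pe_hat = sol[off["pe"] :].reshape(-1, k)
    return SolutionSet(
        fixed=fixed,
        htd=htd,
        a_hat=a_hat,
        pe_hat=pe_hat,
        animals=list(frame.animals),
        recorded_cows=list(frame.recorded_cows),
        order=frame.order,
        residual_norm=residual_norm,
    )


def solve_mme(
    frame: ModelFrame,
    vc: VarianceComponents,
    kin: KinshipResult,
    rtol: float = 1e-8,
) -> SolutionSet:
    """Solve the sparse MME by LU factorization; verifies the residual."""
    C, rhs = assemble_mme(frame, vc, kin)
    try:
        lu = _sym_splu(C)
    except RuntimeError as err:
        raise np.linalg.LinAlgError(
            "MME factorization failed (rank-deficient fixed effects?): " + str(err)
        ) from err
    sol = lu.solve(rhs)
    resid = np.linalg.norm(C @ sol - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if not np.isfinite(resid) or resid > rtol * scale * 1e4:
        raise np.linalg.LinAlgError(
            f"MME solution did not converge: residual {resid:.3e} vs rhs norm {scale:.3e}"
        )
    return _unpack_solution(frame, sol, residual_norm=float(resid))


def gls_blup_oracle(
    records: pd.DataFrame,
    kin: KinshipResult,
    vc: VarianceComponents,
    order: int = 3,
    dim_range: DimRange = DimRange(),
) -> SolutionSet:
    """Dense generalized-least-squares BLUE/BLUP (test oracle, tiny data only).

    Builds V = Za (A x G0) Za' + Zp (I x P0) Zp' + Zh Zh' s2htd + I s2e
    explicitly and solves by textbook GLS; sized for <= 300 records.
    """
    frame = build_model_frame(records, kin, order=order, dim_range=dim_range)
    if frame.n_records > _ORACLE_MAX_RECORDS or kin.n_animals > _ORACLE_MAX_ANIMALS:
        raise ValueError("gls_blup_oracle is limited to tiny instances")
    A = relationship_matrix_tabular(kin.entries)
    k = frame.k
    Ga = np.kron(A, vc.G0)
    Gp = np.kron(np.eye(len(frame.recorded_cows)), vc.P0)
    Za, Zp, Zh = frame.Za.toarray(), frame.Zp.toarray(), frame.Zh.toarray()
    X, y = frame.X.toarray(), frame.y
    V = (
        Za @ Ga @ Za.T
        + Zp @ Gp @ Zp.T
        + vc.sigma2_htd * Zh @ Zh.T
        + vc.sigma2_e * np.eye(frame.n_records)
    )
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    r = y - X @ beta
    h = vc.sigma2_htd * Zh.T @ (Vinv @ r)
    a = Ga @ Za.T @ (Vinv @ r)
    p = Gp @ Zp.T @ (Vinv @ r)
    sol = np.concatenate([beta, h, a, p])
    return _unpack_solution(frame, sol)


def dense_reml_log_likelihood(
    records: pd.DataFrame,
    kin: KinshipResult,
    vc: VarianceComponents,
    order: int = 3,
    dim_range: DimRange = DimRange(),
) -> float:
    """Textbook REML log-likelihood from dense V (test oracle, tiny data only)."""
    frame = build_model_frame(records, kin, order=order, dim_range=dim_range)
    if frame.n_records > _ORACLE_MAX_RECORDS or kin.n_animals > _ORACLE_MAX_ANIMALS:
        raise ValueError("dense REML oracle is limited to tiny instances")
    A = relationship_matrix_tabular(kin.entries)
    Za, Zp, Zh = frame.Za.toarray(), frame.Zp.toarray(), frame.Zh.toarray()
    X, y = frame.X.toarray(), frame.y
    V = (
        Za @ np.kron(A, vc.G0) @ Za.T
        + Zp @ np.kron(np.eye(len(frame.recorded_cows)), vc.P0) @ Zp.T
        + vc.sigma2_htd * Zh @ Zh.T
        + vc.sigma2_e * np.eye(frame.n_records)
    )
    n, p = frame.n_records, X.shape[1]
    sign, logdet_v = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vinv @ y)
    r = y - X @ beta
    ypy = r @ Vinv @ r
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_x + ypy)


def reml_log_likelihood(
    frame: ModelFrame, vc: VarianceComponents, kin: KinshipResult
) -> float:
    """Restricted log-likelihood from the sparse MME factorization.

    -2 logL = (n-p) log 2pi + log|R| + log|G| + log|C| + y'Py, using
    |V| = |R| |G| |C_uu| and |X'Vinv X| = |C| / |C_uu|.
    """
    C, rhs = assemble_mme(frame, vc, kin)
    lu = _sym_splu(C)
    sol = lu.solve(rhs)
    logdet_c = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    return _logl_from_parts(frame, vc, kin, logdet_c, sol, rhs)


def _logl_from_parts(frame, vc, kin, logdet_c, sol, rhs) -> float:
    n, p = frame.n_records, frame.n_fixed
    k = frame.k
    na, nq, nh = len(frame.animals), len(frame.recorded_cows), len(frame.htd_levels)
    ypy = frame.y @ frame.y / vc.sigma2_e - sol @ rhs
    logdet_g = (
        (nh * np.log(vc.sigma2_htd) if nh else 0.0)
        + k * kin.log_det_a
        + na * np.linalg.slogdet(vc.G0)[1]
        + nq * np.linalg.slogdet(vc.P0)[1]
    )
    m2l = (
        (n - p) * np.log(2 * np.pi)
        + n * np.log(vc.sigma2_e)
        + logdet_g
        + logdet_c
        + ypy
    )
    return -0.5 * float(m2l)


# ---------------------------------------------------------------------------
# AI-REML

@dataclass
class RemlOptions:
    max_iter: int = 100
    tol: float = 1e-6          # max relative parameter change
    logl_tol: float = 1e-8
    verbose: bool = False


@dataclass
class RemlFit:
    varcomp: VarianceComponents
    loglik: float
    loglik_trace: list
    converged: bool
    n_iter: int
    param_cov: np.ndarray      # asymptotic covariance (inverse AI) of parameters
    param_names: list
    order: int
    n_records: int
    n_animals: int

    def to_dict(self) -> dict:
        return {
            "varcomp": self.varcomp.to_dict(),
            "loglik": self.loglik,
            "loglik_trace": list(self.loglik_trace),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "param_cov": self.param_cov.tolist(),
            "param_names": self.param_names,
            "order": self.order,
            "n_records": self.n_records,
            "n_animals": self.n_animals,
        }


def _param_names(k: int) -> list:
    names = [f"G0[{s},{t}]" for s in range(k) for t in range(s, k)]
    names += [f"P0[{s},{t}]" for s in range(k) for t in range(s, k)]
    return names + ["sigma2_htd", "sigma2_e"]


def _pack(vc: VarianceComponents) -> np.ndarray:
    k = vc.G0.shape[0]
    iu = np.triu_indices(k)
    return np.concatenate([vc.G0[iu], vc.P0[iu], [vc.sigma2_htd, vc.sigma2_e]])


def _unpack(theta: np.ndarray, k: int, bend: bool = True):
    m = k * (k + 1) // 2
    iu = np.triu_indices(k)
    G0 = np.zeros((k, k))
    G0[iu] = theta[:m]
    G0 = G0 + G0.T - np.diag(np.diag(G0))
    P0 = np.zeros((k, k))
    P0[iu] = theta[m : 2 * m]
    P0 = P0 + P0.T - np.diag(np.diag(P0))
    s2h, s2e = theta[2 * m], theta[2 * m + 1]
    if bend:
        G0 = nearest_psd(G0)
        P0 = nearest_psd(P0)
        s2h = max(s2h, 1e-10)
        s2e = max(s2e, 1e-10)
    return G0, P0, float(s2h), float(s2e)


def start_values(frame: ModelFrame) -> VarianceComponents:
    """Default REML starting point from the raw phenotypic variance."""
    k = frame.k
    vary = float(np.var(frame.y, ddof=1))
    return VarianceComponents(
        G0=0.1 * vary * np.eye(k),
        P0=0.1 * vary * np.eye(k),
        sigma2_e=0.5 * vary,
        sigma2_htd=0.05 * vary,
    )


class _RemlEngine:
    """One dataset, shared structure across iterations."""

    def __init__(self, frame: ModelFrame, kin: KinshipResult):
        self.frame = frame
        self.kin = kin
        self.W = frame.W.tocsr()
        self.WtW = (self.W.T @ self.W).tocoo()
        self.Wty = self.W.T @ frame.y
        self.off = frame.block_offsets
        self.k = frame.k
        self.na = len(frame.animals)
        self.nq = len(frame.recorded_cows)
        self.nh = len(frame.htd_levels)
        self.n = frame.n_records
        ainv_coo = kin.a_inv.tocoo()
        self.ai_r, self.ai_c, self.ai_v = ainv_coo.row, ainv_coo.col, ainv_coo.data

    def factor(self, vc: VarianceComponents):
        """Dense Cholesky of C; None when the parameter point is infeasible."""
        try:
            C, rhs = assemble_mme(self.frame, vc, self.kin)
        except (np.linalg.LinAlgError, ValueError):
            return None
        Cd = np.asarray(C.todense())
        try:
            chol = cho_factor(Cd, lower=True, overwrite_a=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        sol = cho_solve(chol, rhs, check_finite=False)
        logl = _logl_from_parts(self.frame, vc, self.kin, logdet_c, sol, rhs)
        return {"chol": chol, "sol": sol, "rhs": rhs, "logl": logl, "vc": vc}

    def statistics(self, state):
        """Conditional sufficient statistics needed for EM, score and AI."""
        frame, k, off = self.frame, self.k, self.off
        vc = state["vc"]
        sol = state["sol"]
        Ci, info = dpotri(state["chol"][0], lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        # dpotri fills only the lower triangle; mirror it (upper holds factor junk)
        Ci = np.tril(Ci) + np.tril(Ci, -1).T

        a_hat = sol[off["a"] : off["pe"]].reshape(self.na, k)
        pe_hat = sol[off["pe"] :].reshape(self.nq, k)
        h_hat = sol[off["htd"] : off["a"]]

        # additive block: U_a = Ahat' Ainv Ahat, S_a = sum Ainv_mm' Ci[m block, m' block]
        U_a = a_hat.T @ (self.kin.a_inv @ a_hat)
        S_a = np.empty((k, k))
        ra = off["a"] + self.ai_r * k
        ca = off["a"] + self.ai_c * k
        for s in range(k):
            for t in range(k):
                S_a[s, t] = np.dot(self.ai_v, Ci[ra + s, ca + t])
        U_p = pe_hat.T @ pe_hat
        S_p = np.empty((k, k))
        rp = off["pe"] + np.arange(self.nq) * k
        for s in range(k):
            for t in range(k):
                S_p[s, t] = Ci[rp + s, rp + t].sum()
        tr_h = float(np.trace(Ci[off["htd"] : off["a"], off["htd"] : off["a"]]))
        uh2 = float(h_hat @ h_hat)
        tw = float(np.dot(self.WtW.data, Ci[self.WtW.row, self.WtW.col]))
        r = self.frame.y - self.W @ sol
        rss = float(r @ r)
        return {
            "Ci": Ci,
            "a_hat": a_hat,
            "pe_hat": pe_hat,
            "h_hat": h_hat,
            "U_a": U_a,
            "S_a": S_a,
            "U_p": U_p,
            "S_p": S_p,
            "tr_h": tr_h,
            "uh2": uh2,
            "tw": tw,
            "r": r,
            "rss": rss,
        }

    def em_update(self, vc, st) -> VarianceComponents:
        G0 = nearest_psd((st["U_a"] + st["S_a"]) / self.na)
        P0 = nearest_psd((st["U_p"] + st["S_p"]) / self.nq)
        s2h = (st["uh2"] + st["tr_h"]) / self.nh if self.nh else vc.sigma2_htd
        s2e = (st["rss"] + st["tw"]) / self.n
        return VarianceComponents(G0, P0, s2e, s2h)

    def score_and_ai(self, vc, st):
        """Exact gradient and average-information matrix for all parameters."""
        k = self.k
        m = k * (k + 1) // 2
        npar = 2 * m + 2
        G0inv = np.linalg.inv(vc.G0)
        P0inv = np.linalg.inv(vc.P0)
        score = np.empty(npar)

        def mat_scores(Kinv, S, U, q, base):
            i = base
            for s in range(k):
                for t in range(s, k):
                    D = np.zeros((k, k))
                    D[s, t] = D[t, s] = 1.0
                    M = Kinv @ D @ Kinv
                    tr_prior = q * np.trace(D @ Kinv)
                    score[i] = -0.5 * (tr_prior - np.trace(M @ S) - np.trace(M @ U))
                    i += 1

        mat_scores(G0inv, st["S_a"], st["U_a"], self.na, 0)
        mat_scores(P0inv, st["S_p"], st["U_p"], self.nq, m)
        s2h, s2e = vc.sigma2_htd, vc.sigma2_e
        if self.nh:
            score[2 * m] = -0.5 * (self.nh / s2h - (st["tr_h"] + st["uh2"]) / s2h**2)
        else:
            score[2 * m] = 0.0
        score[2 * m + 1] = -0.5 * (
            self.n / s2e - st["tw"] / s2e**2 - st["rss"] / s2e**2
        )

        # AI matrix: AI_kl = 1/2 f_k' P f_l with f_k = (dV/dtheta_k) P y
        Py = st["r"] / s2e
        F = np.empty((self.n, npar))
        t_a = (self.frame.Za.T @ Py).reshape(self.na, k)
        t_p = (self.frame.Zp.T @ Py).reshape(self.nq, k)
        i = 0
        for s in range(k):
            for t in range(s, k):
                D = np.zeros((k, k))
                D[s, t] = D[t, s] = 1.0
                F[:, i] = self.frame.Za @ self.kin.multiply_by_a(t_a @ D).ravel()
                i += 1
        for s in range(k):
            for t in range(s, k):
                D = np.zeros((k, k))
                D[s, t] = D[t, s] = 1.0
                F[:, i] = self.frame.Zp @ (t_p @ D).ravel()
                i += 1
        F[:, 2 * m] = self.frame.Zh @ (self.frame.Zh.T @ Py) if self.nh else 0.0
        F[:, 2 * m + 1] = Py

        Q = self.W.T @ F / s2e
        CiQ = st["Ci"] @ Q
        ai = 0.5 * (F.T @ F / s2e - Q.T @ CiQ)
        return score, 0.5 * (ai + ai.T)


def reml_estimate(
    frame: ModelFrame,
    kin: KinshipResult,
    start: VarianceComponents | None = None,
    options: RemlOptions = RemlOptions(),
) -> RemlFit:
    """AI-REML with EM fallback.

    Accepts an AI step only if it stays in the parameter space (after bending
    indefinite G0/P0 updates) and does not decrease the restricted likelihood;
    otherwise halves the step towards the current point and finally takes the
    EM update, which is an ascent direction.  Convergence: maximum relative
    parameter change below `options.tol` or likelihood change below
    `options.logl_tol`.
    """
    vc = (start or start_values(frame)).copy()
    engine = _RemlEngine(frame, kin)
    k = frame.k
    state = engine.factor(vc)
    if state is None:
        raise np.linalg.LinAlgError("coefficient matrix not positive definite at start")
    trace = [state["logl"]]
    converged = False
    ai_matrix = np.eye(2 * (k * (k + 1) // 2) + 2)
    it = 0
    for it in range(1, options.max_iter + 1):
        st = engine.statistics(state)
        vc_em = engine.em_update(vc, st)
        score, ai_matrix = engine.score_and_ai(vc, st)

        theta = _pack(vc)
        try:
            delta = np.linalg.solve(
                ai_matrix + 1e-10 * np.eye(len(theta)) * max(1.0, np.trace(ai_matrix)),
                score,
            )
        except np.linalg.LinAlgError:
            delta = None

        # Try the AI step, then blends halved towards the EM update (which is
        # an ascent step itself), then pure EM.
        accepted = None
        theta_em = _pack(vc_em)
        if delta is not None:
            theta_ai = theta + delta
            for alpha in (1.0, 0.5, 0.25):
                cand = VarianceComponents(
                    *_rearrange(_unpack(theta_em + alpha * (theta_ai - theta_em), k))
                )
                cand_state = engine.factor(cand)
                if cand_state is not None and cand_state["logl"] >= state["logl"] - 1e-9:
                    accepted = (cand, cand_state)
                    break
        if accepted is None:
            cand_state = engine.factor(vc_em)
            if cand_state is None:
                raise np.linalg.LinAlgError("EM update produced an infeasible system")
            accepted = (vc_em, cand_state)

        new_vc, new_state = accepted
        d_logl = new_state["logl"] - state["logl"]
        rel = np.max(
            np.abs(_pack(new_vc) - _pack(vc)) / (np.abs(_pack(vc)) + 1e-8)
        )
        if options.verbose:
            print(f"iter {it}: logL={new_state['logl']:.6f} dlogL={d_logl:.2e} rel={rel:.2e}")
        vc, state = new_vc, new_state
        trace.append(state["logl"])
        if rel < options.tol or abs(d_logl) < options.logl_tol:
            converged = True
            break

    # asymptotic covariance from the AI matrix at the last evaluated point
    try:
        param_cov = np.linalg.inv(ai_matrix)
    except np.linalg.LinAlgError:
        param_cov = np.linalg.pinv(ai_matrix)
    return RemlFit(
        varcomp=vc,
        loglik=state["logl"],
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        param_cov=param_cov,
        param_names=_param_names(k),
        order=frame.order,
        n_records=frame.n_records,
        n_animals=len(frame.animals),
    )


def _rearrange(parts):
    G0, P0, s2h, s2e = parts
    return G0, P0, s2e, s2h  # VarianceComponents(G0, P0, sigma2_e, sigma2_htd)


def likelihood_ratio_test(fit_reduced: RemlFit, fit_full: RemlFit):
    """LRT for nested polynomial orders; df = change in free covariance parameters.

    Returns (statistic, df, p).  The fits must be on the same records with
    reduced order < full order.
    """
    if fit_reduced.n_records != fit_full.n_records:
        raise ValueError("fits are not on the same data")
    if fit_reduced.order >= fit_full.order:
        raise ValueError("models are not nested: reduced order must be smaller")
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    stat = max(stat, 0.0)

    def n_cov(order):
        kk = order + 1
        return kk * (kk + 1) // 2

    df = 2 * (n_cov(fit_full.order) - n_cov(fit_reduced.order))
    if df == 0:
        return stat, 0, 1.0
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), int(df), p
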