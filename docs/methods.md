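# Methods

This note documents the model, the numerical choices, and the synthetic-data
conditions under which the package's statistical tests run, in enough detail
for a maintainer to judge what a passing test suite does and does not show.

## Model and estimation

The observation model, random-effect distributions and derived quantities are
stated in the README.  Implementation specifics:

**Basis.** Orthonormal Legendre polynomials `φ_t(x) = sqrt((2t+1)/2) P_t(x)`
on DIM standardized affinely onto [−1, 1] over the modelled window (default
days 5–305, inclusive; 301 days).  Orthonormality is a pure convention — any
fixed invertible transform of the basis rescales G0/P0 without changing daily
variances — but it must be shared between the generative and estimation
sides, so it is fixed package-wide.  Default order 3 (4 coefficients);
order selection is supported through REML likelihood-ratio tests with
`df = 2·Δ[(k+1)(k+2)/2]` (both covariance matrices change order together).

**Identifiability.** The one-hot blocks of herd-year, DIM class and age class
share exactly two sum-to-one redundancies, so the frame keeps herd-year full
and drops one reference level from each of the other two factors: the DIM
class containing day 305 and the 50-month age class are set to zero (the
largest observed level if those are absent).  No herd-year level is absorbed;
the intercept lives in the herd-year block.

**DIM step function at small scale.** The DIM curve is a free step function
with one class per day by default.  That requires many records per day; small
datasets (pipeline smoke runs) may set `dim_class_width > 1` to pool adjacent
days.  All desk-scale statistical tests use daily classes.

**MME solving.** Sparse LU (SuperLU) with a minimum-degree ordering in
symmetric mode; the additive prior block is `kron(A⁻¹, G0⁻¹)` in animal-major
ordering, with A⁻¹ assembled by Henderson's rules including inbreeding
(Meuwissen–Luo coefficients; exact for inbred loops).  Unknown parents are
base-population founders; there are no unknown-parent groups.  The assembled
LHS is symmetrized exactly to guard against sparse-product roundoff.

**REML.** Average-information REML on the 22 free parameters (vech G0,
vech P0, σ²_htd, σ²_e).  Per iteration the dense Cholesky of the coefficient
matrix C yields the restricted likelihood
`−2ℓ = (n−p)log 2π + log|R| + log|G| + log|C| + y'Py`
and its full inverse yields the exact conditional (co)variance statistics
needed for the score, the EM update, and the AI matrix
`AI = ½ F'PF` with `F_k = (∂V/∂θ_k) P y` (the A-multiplications use the
factored form `A = T D T'`, two sparse triangular solves).  Step control:
try the AI step; if it leaves the parameter space or lowers the likelihood,
halve towards the EM update (candidates `θ_EM + α(θ_AI − θ_EM)`,
α ∈ {1, ½, ¼}), finally take pure EM, which cannot decrease the restricted
likelihood.  Indefinite G0/P0 candidates are bent by eigenvalue clipping at
`1e−6 · trace` — the floor is set by numerical conditioning of log|C|, and is
far below any statistically meaningful eigenvalue.  Convergence: maximum
relative parameter change < `tol` (default 1e−6) or likelihood change
< 1e−8; the asymptotic parameter covariance is the inverse AI matrix at the
last evaluated point.  Starting values: `G0 = P0 = 0.1·var(y)·I`,
`σ²_e = 0.5·var(y)`, `σ²_htd = 0.05·var(y)`.

At desk scale (≈380 cows, ≈3600 records, coefficient matrix ≈4800) one
iteration costs a few seconds; the parameter-recovery tests cap the fit at
12 iterations with `tol = 1e−3`, which is past the point where the remaining
parameter drift is far inside the sampling noise (estimates move along a
likelihood ridge of weakly identified high-order covariances).

**Curve standard errors** are parametric-sampling SEs: ≥1000 draws from
`N(θ̂, AI⁻¹)`, each projected back to the parameter space (PSD bending,
positive variances), the per-day SD of the recomputed curve reported.  This
is a Monte-Carlo delta method; it inherits the asymptotic-normal
approximation of the AI covariance.

**Phenotypic variance convention.** `σ²_P(j) = σ²_a(j) + σ²_pe(j) + σ²_e`
— the herd-test-day variance is *excluded* from the heritability and
repeatability denominators (it describes shared management environment, not
the cow); `include_htd=True` adds it for sensitivity analysis.

## Editing rules

Filters are applied in a fixed order (milk 5–60 kg; DIM 5–305; 3 milkings per
day; ≥2 records per cow; age at first calving 20–50 months; herd/year minimum
record counts, defaults 500/1000), with the cow-level and herd/year-level
rules iterated to a fixed point because they interact.  Each removed record
is attributed to the first rule that removed it, so per-rule attrition plus
survivors reconciles exactly with the input count; the herd/year minimum
counts *records* (not cows), which is one reading of the usual phrasing.
Synthetic desk-scale runs set the herd/year minima to 0.

## The synthetic-data generator

The generator draws every effect from the model's own distributions, so that
estimators can be validated against known truth:

* **Population**: 8 herds × 8 calving years (2000–2007) × 6 cows per
  herd-year ≈ 380 recorded cows; 10 base sires and 150 base dams as
  founders, parents drawn uniformly (progeny groups of ≈38 daughters).
  Descendant additive vectors are parent-average plus Mendelian sampling
  `N(0, d·G0)` with `d = ½ − (F_s + F_d)/4`, which realizes
  `a ~ N(0, A ⊗ G0)` exactly.
* **Recording**: each herd tests *all* its cows on one day per month
  (herd-specific day-of-month), so herd-test-day groups hold several cows —
  with per-cow test dates σ²_htd would be confounded with σ²_e — and a cow's
  first test falls at DIM ≈5–35.  Records stop at DIM 305 or the data end
  (Dec 31 of the last calving year), leaving lactations in progress
  truncated, which is what forward validation feeds on.
* **Fixed curves**: a Wilmink-type lactation shape
  `a + b·exp(−k·DIM) + c·DIM` peaking around weeks 6–8 (deliberately *not* a
  step function, to test the step function's ability to track an arbitrary
  curve); an age-at-calving parabola peaking at 27 months; herd-year levels
  with a positive linear trend over years plus noise.  Calving dates uniform
  within year; ages drawn with mode ≈27 months on [20, 50].
* **Variance components** (frozen defaults, kg², orthonormal order-3 basis):
  tuned once by least squares so that the implied daily curves match target
  quadratics, then fixed as constants.  They give h²(j) ∈ [0.143, 0.179]
  peaking at DIM ≈145, repeatability ∈ [0.664, 0.795] with its minimum at
  DIM ≈142 and maximum at DIM 305, adjacent-day genetic correlations >0.999,
  σ²_e = 13.2 and σ²_htd = 2.2 (≈5% of phenotypic variance).

What the generator does **not** emulate: selection (mating is random, so
genetic variance is stationary across years), multiple parities, seasonal
calving patterns, heterogeneous residual variance across lactation, missing
or erroneous calving dates, and herd sizes in the thousands.  Passing
recovery tests therefore demonstrate correctness of the estimation machinery
under the model's own assumptions, not robustness to real-data violations.

## Forward validation

The whole (edited) dataset is sliced at successive calendar-year cutoffs —
calving year ≤ cutoff AND test date within the cutoff year — so late tests
of earlier calvers are excluded from earlier partials; slicing continues
until every record is included.  Editing happens once on the full data;
per-partial re-editing applies record-level rules only (`min_records=1`),
because the 2-record rule would delete exactly the lactations in progress
that form the E-L cohort.  Cohort membership uses the cow's *maximum*
observed DIM in each partial (a `mean` rule is available), matching the
lactation-in-progress semantics.  Sire statistics use the sires' own
animal-model EBVs, restricted to sires of cohort cows with ≥5 recorded
daughters in the older partial — cohort-internal daughter counts would leave
the sire group empty at desk scale.  Variance components are estimated once
(or supplied, e.g. the simulator's truth in calibration experiments) and
reused across partials, as production systems do; `reml_each_partial`
re-estimates inside every evaluation.  The significance of the bias M is a
two-sided paired bootstrap over animals (default 2000 resamples, seeded).

Under these conditions the E-L cohort holds ≈10–15 cows per comparison
(cows calving in the ~3 months before the cutoff), so single-replicate LR
statistics are noisy; the acceptance checks therefore average b and M over
20 simulated replicates and compare to their theoretical expectations (1
and 0), which hold because consecutive BLUP evaluations form a martingale
when the model is correctly specified.

## Known limitations

* The dense-inverse AI-REML engine is comfortable to coefficient matrices of
  ~10⁴; national-scale data needs sparse selected-inverse machinery that is
  out of scope here.
* Likelihood-ratio order selection uses the naive chi-square reference; with
  variance parameters on the boundary it is conservative.
* No reliability/accuracy per animal from the inverse coefficient matrix,
  no genomic terms, no unknown-parent groups, no multi-parity models.
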