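# rrtdm — random-regression test-day model for dairy genetic evaluation

`rrtdm` implements the full analysis chain behind a national-style dairy
genetic evaluation for first-lactation daily milk yield, at a scale that runs
on a desk machine: Legendre-polynomial random-regression modelling of the
lactation curve, pedigree BLUP via Henderson's mixed model equations,
variance-component estimation by average-information REML, daily heritability
and repeatability curves, 305-day breeding values, and forward ("LR method")
cross-validation of sequential yearly evaluations for early sire selection.
It is aimed at quantitative geneticists and students who want a transparent,
fully testable implementation of this model class — every stage can be
exercised against a synthetic-data generator that shares the model's exact
generative structure.

## The model

A test-day record of cow *m* at days in milk (DIM) *j* is modelled as

    y = hy_i + dim_j + age_k + htd_l + z_j' a_m + z_j' pe_m + e

* `hy`, `dim`, `age` — fixed herd-year, DIM-class and age-at-calving class
  effects (the lactation and age curves are free step functions);
* `htd ~ N(0, σ²_htd)` — random herd-test-day environment;
* `a ~ N(0, A ⊗ G0)` — additive-genetic random-regression coefficients, with
  A the pedigree numerator relationship matrix;
* `pe ~ N(0, I ⊗ P0)` — permanent-environmental coefficients per recorded cow;
* `e ~ N(0, σ²_e)` — homogeneous residual;
* `z_j` — orthonormal Legendre polynomials (order 3 by default) evaluated at
  DIM standardized onto [−1, 1] over days 5–305.

Derived quantities: daily variances `σ²_a(j) = z_j' G0 z_j` (likewise for pe),
heritability `h²(j) = σ²_a(j)/σ²_P(j)`, repeatability
`r(j) = (σ²_a(j)+σ²_pe(j))/σ²_P(j)`, daily EBV `z_j' â_m`, total EBV
`EBVT = Σ_{j=5}^{305} z_j' â_m`, and `TMY = EBVT + TPe`.

Forward validation emulates yearly evaluation runs by slicing the data at
successive calendar-year cutoffs and comparing consecutive evaluations on the
E-L cohort (cows in early lactation, max DIM 5–90, at the older cutoff that
reach late lactation, 181–305, by the newer one) through

    b   = cov(û_i, û_{i-1}) / var(û_{i-1})   (dispersion, expectation 1)
    ρ   = corr(û_i, û_{i-1})                 (population accuracy)
    M   = mean(û_{i-1}) − mean(û_i)          (bias, expectation 0)

## Worked example

```python
from rrtdm import (SimConfig, simulate_dataset, apply_edits, EditConfig,
                   build_model_frame, reml_estimate, RemlOptions,
                   heritability_curve, solve_mme, ebv_table)

cfg = SimConfig(seed=3)                      # 8 herds, 2000-2007, ~380 cows
data = simulate_dataset(cfg)
edited, report = apply_edits(data.records, EditConfig(herd_min=0, year_min=0))
print(report.records_in, "->", report.records_out)

frame = build_model_frame(edited, data.kin)                # order-3 Legendre
fit = reml_estimate(frame, data.kin, options=RemlOptions(max_iter=12, tol=1e-3))
print(round(fit.varcomp.sigma2_e, 2), "kg^2 residual")

h2 = heritability_curve(fit.varcomp)
mid = list(h2.dim).index(155)
print("h2 at DIM 155:", round(h2.values[mid], 3))

sols = solve_mme(frame, fit.varcomp, data.kin)
print(ebv_table(sols).sort_values("ebvt", ascending=False).head(3))
```

prints

```
3583 -> 3574
13.32 kg^2 residual
h2 at DIM 155: 0.114
     animal        ebvt          tpe          tmy
170  C00077  851.013917   338.433701  1189.447617
171  C00112  698.001921  2067.556475  2765.558396
259  C00195  676.342185  1034.195810  1710.537995
```

The fit recovers the generator's residual variance closely (13.32 vs a true
13.2 kg²); daily heritabilities from a *single* replicate of ~380 cows carry
sampling errors of several points (true h² at DIM 155 is 0.179 — the
recovery tests average ten replicates), and the EBV table lists each
animal's total 305-day breeding value in kg, the permanent-environment
total for recorded cows, and their sum (TMY).

A complete reproducible run (simulate → edit → REML → curves → EBV →
forward validation, with a checksummed manifest) is available from the CLI:

```bash
rrtdm all --config run.yaml --out-dir runs/demo
```

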