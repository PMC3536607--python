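# dgvcal

Accuracy of **direct genomic breeding values** (DGV) for nationally
evaluated traits in pedigreed beef cattle populations — estimated the way
breed associations need it for blending genomic and traditional
evaluations: as the **genetic correlation between a trait and its DGV**,
obtained from relatedness-clustered cross-validation and a weighted
bivariate animal model.

The package is for quantitative geneticists and breeding-program analysts
who work with national-evaluation output (expected progeny differences and
BIF accuracies), SNP genotypes, and pedigrees — and for anyone who wants a
transparent, fully tested re-implementation of this validation design to
study on simulated herds.

## What it computes

Given genotypes (B-allele dosages), a pedigree, and EPD with BIF
accuracies for animals and their parents:

1. **Marker QC**: call rate ≥ 0.95, MAF ≥ 0.005, Hardy–Weinberg χ²
   p > 1e−30; mean imputation of missing calls.
2. **Deregression**: EBV = 2·EPD and R² = 1 − (1 − BIF)²
   are deregressed to parent-average-free DEBV with information weights
   w = (1 − h²) / [(c + (1 − r²)/r²) h²], c = 0.40.
3. **Cross-validation groups**: the numerator relationship matrix **A** is
   built by the tabular method; animals are split into K = 5 groups by
   Hartigan–Wong K-means on the rows of max(A) − A, maximizing within- and
   minimizing between-group relatedness (diagnosed by a_max means ± SD).
4. **Weighted BayesC**: per fold, marker effects u_j are sampled by Gibbs
   from y_i = μ + Σ_j z_ij u_j + e_i with u_j = 0 w.p. π = 0.95, else
   N(0, σ²_u), and Var(e_i) = σ²_e / w_i; the held-out group's
   DGV_i = Σ_j z_ij û_j uses posterior-mean effects.
5. **Bivariate REML** on (DEBV, DGV) with genetic covariance Σ₀ ⊗ G, where
   G zeroes relationships between cross-validation groups, yielding
   r_g(T, DGV), h²_DGV, and standard errors (average-information REML with
   EM safeguards).
6. **Selection efficiency**: Efficiency = r_g(T, DGV) / √(R²_PA) against
   parent-average reliability R²_PA = (r²_sire + r²_dam)/4, per trait and
   per animal.

A first-class synthetic-herd generator (`dgvcal.simdata`) produces
pedigrees with lineage/half-sib family structure, gene-dropped genotypes,
traits with known architecture, and emulated evaluation output with
assigned reliabilities — so the whole pipeline runs and is tested without
any proprietary data.

## Worked example

Simulate a herd and run the full pipeline (also available as
`dgvcal run --config pipeline.yaml --seed 7 --out-dir out/`):

```python
from dgvcal import bayesc, crossval, simdata

cfg = simdata.SimulationConfig(
    n_founders=100, n_generations=4, n_markers=500, n_qtl=40, seed=7
)
result = crossval.run_pipeline(
    cfg,
    bayes_config=bayesc.BayesCConfig(chain_length=2000, burn_in=400),
    restarts=10,
)
est = result.estimates
print(f"r_g = {est.r_g:.2f} +/- {est.r_g_se:.2f}; h2_dgv = {est.h2_dgv:.2f}")
print(result.quality.per_group.round(3).to_string(index=False))
```

Output (seed 7; 407 animals, 500 markers, 5 folds):

```
r_g = 0.83 +/- 0.05; h2_dgv = 1.00
 group   n  a_max_within_mean  a_max_within_sd  a_max_between_mean  a_max_between_sd
     1  82              0.583            0.104               0.228             0.180
     2  19              0.632            0.128               0.145             0.120
     3 201              0.425            0.220               0.132             0.175
     4  73              0.599            0.080               0.279             0.171
     5  32              0.535            0.057               0.246             0.219
```

Reading the numbers: clustering worked — every group's animals are much
more related to their own group (mean a_max within 0.43–0.63) than to the
other groups (0.13–0.28), so each fold's DGV are predicted mostly from
less-related animals and the accuracy estimate is conservative.  The
cross-validated DGV correlate 0.68 with the (here known) true breeding
values; the bivariate fit estimates a trait–DGV genetic correlation of
0.83 ± 0.05, and the DGV — a linear function of genotypes — behaves as a
perfectly heritable trait (h²_DGV = 1.00), so r_g² ≈ 0.69 of the genetic
variance is captured by the markers.  With the cohort-mean parent-average
reliability of 0.20, selecting on DGV is 0.83/√0.20 ≈ 1.85 times as
responsive as selecting on parent average.

The published variance-component, correlation, and efficiency tables for
US Limousin and Simmental ship as fixtures
(`dgvcal.report.load_table`), and `dgvcal.report.verify_table_algebra()`
replays their internal arithmetic (r_g from (co)variances, efficiency from
r_g and R²_PA), classifying each row as consistent, rounding-sensitive, or
inconsistent at the printed precision.

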