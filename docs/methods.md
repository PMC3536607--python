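# Methods

`dgvcal` estimates the accuracy of direct genomic breeding values (DGV) for
pedigreed livestock populations the way national beef evaluations frame it:
as the genetic correlation between a trait and its DGV, estimated by a
weighted bivariate animal model on cross-validated predictions.  This note
documents the models, the synthetic data that exercises them, the numerical
choices, and what the bundled tests do and do not demonstrate.

## Pipeline overview

1. **Inputs.** Per-animal B-allele dosages (0/1/2 with missing calls), a
   parentage pedigree, and national-evaluation output: expected progeny
   differences (EPD) with Beef Improvement Federation (BIF) accuracies for
   the genotyped animals *and their parents*.
2. **Marker QC** (`genotype_qc`): keep markers with call rate >= 0.95,
   minor allele frequency >= 0.005 and Hardy-Weinberg chi-square p > 1e-30;
   mean-impute surviving missing calls.
3. **Deregression** (`deregression`): EBV = 2 * EPD, reliability
   R^2 = 1 - (1 - BIF)^2; remove shrinkage and the parent-average
   contribution to obtain DEBV with reliabilities reflecting only own and
   descendant information, plus information weights
   w = (1 - h^2) / [(c + (1 - r^2)/r^2) h^2] with c = 0.40.
4. **Cross-validation design** (`pedigree`, `clustering`): build the
   numerator relationship matrix A (tabular method) over the genotyped
   animals and their ancestors, form the difference matrix max(A) - A, and
   partition animals into K = 5 groups by Hartigan-Wong K-means on its
   rows, so relatedness is high within and low between groups.  Group-wise
   mean +/- SD of each animal's maximum relationship (a_max) within and
   between groups quantifies the separation.
5. **Marker effects and DGV** (`bayesc`, `crossval`): for each fold, fit
   weighted BayesC (pi = 0.95) by single-site Gibbs sampling to the DEBV of
   the other four groups and predict DGV_i = sum_j z_ij * uhat_j for the
   held-out group, so no animal's own DEBV informs its DGV.
6. **Accuracy** (`bivariate`): fit a bivariate animal model to (DEBV, DGV)
   with genetic covariance Sigma0 (x) G, where G is A with between-group
   covariances zeroed; report the genetic correlation r_g(T, DGV), the DGV
   heritability, and standard errors.
7. **Selection efficiency** (`efficiency`): r_g / sqrt(R^2_PA) against the
   parent-average reliability R^2_PA = (r^2_sire + r^2_dam) / 4, per trait
   and per animal.

## Deregression

The parent-average-removing deregression treats the published EBV as the
solution of a 2x2 mixed-model system in the parent-average effect g_PA
(Var = sigma_g^2 / 2) and the animal's additive effect g_i, with additive
inverse-covariance lambda [[4, -2], [-2, 2]], lambda = (1 - h^2)/h^2.  The
effective information contents Z'Z_PA and Z'Z_i are chosen so the system's
prediction-error variances reproduce the published reliabilities
(r^2_PA on the animal scale, r^2 for the EBV); they have the closed forms

    alpha  = 1 / (0.5 - r^2_PA)
    delta  = (0.5 - r^2_PA) / (1 - r^2)
    Z'Z_PA = lambda (0.5 alpha - 4) + 0.5 lambda sqrt(alpha^2 + 16/delta)
    Z'Z_i  = delta Z'Z_PA + 2 lambda (2 delta - 1)

and the deregressed record is y_i / Z'Z_i with y_i = -2 lambda EBV_PA +
(Z'Z_i + 2 lambda) EBV_i and reliability 1 - lambda / (Z'Z_i + lambda).
The test suite validates the closed forms against an independent numerical
solve of the prediction-error-variance system.  Records whose EBV
reliability does not exceed their parent-average reliability carry no own
information and are dropped, which is why per-trait training counts vary.
With both parents unknown (r^2_PA = 0) the parent-average effect is vacuous
and simple deregression (EBV / r^2) applies; the 2x2 system is not
continuous at that point (it would imply negative parent-average
information), so the unknown-parents case is handled explicitly.

## Weighted BayesC

Marker effects are zero with prior probability pi = 0.95 and otherwise
N(0, sigma_u^2); sigma_u^2 and the residual scale sigma_e^2 carry
scaled-inverse-chi-square priors with 4 degrees of freedom, their scales set
by a preliminary whole-data fit (`initialize_priors`), with the per-marker
genetic scale divided by (1 - pi) sum_j 2 p_j (1 - p_j) (floor 1e-6 on
1 - pi).  Record i's residual variance is sigma_e^2 / w_i.  The sampler is
single-site Gibbs: per sweep, each marker's inclusion indicator is drawn
from its marginalized conditional odds and its effect from the Gaussian
full conditional; then the intercept and, unless fixed, the two variances.
Chains are deterministic given the seed.  Reference chain lengths are
41 000 sweeps with 1 000 burn-in; the bundled pipeline and tests use
reduced chains (a few thousand sweeps and less), with posterior-mean
assertions written to be Monte-Carlo-error aware.  With pi = 0, fixed
variances and equal weights the posterior mean is the SNP-BLUP/ridge
solution, which the tests verify against a direct linear solve.

Dosages enter raw (0-2, not centered) and the intercept is excluded from
DGV; both choices only shift DGV by constants within a fold, which the
bivariate model's group fixed effects absorb.

## K-means on relationship profiles

Each animal is embedded as its row of D = max(A) - A (diagonal zeroed; the
matrix maximum rather than 1 keeps entries non-negative under inbreeding).
K-means minimizes within-cluster sums of squared Euclidean distances over
these rows: animals with similar relationship profiles cluster together.
The implementation runs a Lloyd pass then Hartigan-Wong optimal-transfer
sweeps using the exact n/(n-1), n/(n+1) single-point transfer costs until
no move improves the objective, so the result is 1-swap optimal; the best
of 50 seeded restarts (default) is kept, ties to the first found.  Empty
clusters are repaired by reassigning the farthest point.  Exhaustive
partition enumeration at n <= 8 verifies global optimality in tests.

## Bivariate REML

The two response vectors are the trait DEBV (intercept only) and the
cross-validated DGV (one fixed class effect per group).  Genetic effects
have covariance Sigma0 (x) G with G block-diagonal: within-group blocks are
copied from A (computed on the full pedigree before zeroing, so ancestors
still inform them) and between-group covariances are zero, which makes the
restricted likelihood a pooled sum of per-group contributions — an
invariant the tests check numerically.  Residuals are independent between
traits; the DEBV residual is weighted per record, Var(e1_i) =
sigma_e1^2 / w_i, with the DGV residual homogeneous.  The printed model of
the source material attaches the weights to the DGV residual instead; that
reading is inconsistent with the training model (the weights are defined by
DEBV reliabilities) and is available behind `weight_side="dgv"` for
comparison.

Because G and the residuals are block-diagonal by group, the phenotypic
covariance matrix separates by group; all likelihood, score, and
average-information (AI) quantities are accumulated per group and coupled
only through the shared parameters and the p x p fixed-effects system.
Estimation takes a few EM-REML steps, then Newton steps with the AI matrix
on an unconstrained parameterization (log-Cholesky of Sigma0, log residual
variances) with per-coordinate step clipping and step-halving; each
iteration also evaluates the plain EM candidate and explicit boundary
probes (a residual variance jumped to near its floor of 1e-8 times the
phenotypic scale) and keeps whichever candidate attains the highest
restricted likelihood.  The EM/probe safeguards matter in two real regimes:
likelihood ridges where the genetic correlation estimate sits on the
|r_g| = 1 cone boundary, and the h2_DGV -> 1 boundary where the DGV
residual vanishes.  Convergence is a relative log-likelihood change below
1e-8; a small number of deterministic restarts from spread variance
partitions (default 2) guards against local optima at small n.  Standard
errors come from the inverse AI matrix; r_g = sigma_a12 / sqrt(sigma_a1^2
sigma_a2^2) (clamped to [-1, 1] with a warning) and h2_DGV = sigma_a2^2 /
(sigma_a2^2 + sigma_e2^2) carry delta-method standard errors.

## Synthetic herds

No real genotype or evaluation data accompany the pipeline, so `simdata`
generates herds with known truth:

* **Pedigree**: founders are split into 5 lineages (herd lines); each
  generation, up to 8 sires per lineage serve all lineage dams (5%
  cross-lineage matings), with 1 + Poisson(1) offspring per mating.  Sire
  reuse creates large paternal half-sib families and the lineages keep
  between-family relatedness low — the structure relatedness clustering
  needs, mirroring breed populations assembled from distinct seed-stock
  lines.  Without lineage structure every cluster pair stays substantially
  related and zeroing between-group covariances is badly misspecified,
  visibly depressing h2_DGV estimates.
* **Genotypes**: unlinked biallelic SNPs gene-dropped from Hardy-Weinberg
  founders at frequencies uniform on (0.05, 0.95).  Linkage is deliberately
  absent: none of the estimation machinery uses a genetic map, so
  independent loci exercise every stage.
* **Trait**: 50 of 1000 markers (defaults) carry N(0,1) effects;
  TBV = centered sum of dosage-weighted effects; the residual variance is
  set from the realized TBV variance to hit the target heritability
  (default 0.4, the magnitude of growth-trait heritabilities in national
  beef evaluations).
* **Evaluation**: each animal gets a target reliability from a
  high/low mixture (0.85 AI-sire-like vs 0.40 natural-mating-like, mean
  nudged to 0.55) — reproducing the bimodal parent-average reliability
  pattern of field data — and an EBV built recursively as
  EBV_i = PA_EBV_i + beta_i (m_i + delta_i): the parents' emulated EBV
  average plus a shrunken noisy estimate of the Mendelian-sampling
  deviation, with beta_i set so the achieved reliability equals the target
  where attainable.  The recursion makes an animal's EBV *contain* its
  parents' EBV — exactly the component deregression removes.  A flat
  "TBV times r^2 plus independent noise" construction was rejected: it has
  the right EBV-TBV correlation but no embedded parent average, so
  deregression adds family-correlated noise instead of cancelling it and
  the downstream variance components become incoherent.  No mixed-model
  evaluation is run.  EPD = EBV/2 and BIF accuracy = 1 - sqrt(1 - r^2)
  are back-derived.

What the synthetic herds do **not** emulate: linkage disequilibrium and
marker-QTL co-segregation (accuracies here come from relationship capture
plus direct marker-QTL identity, not LD), genotyping errors, strand/allele
harmonization issues across array versions, selection (no Bulmer effect),
multi-breed admixture, and the correlation structure of real multi-trait
evaluations.  Passing tests therefore demonstrate the estimation machinery
is correct and internally consistent, not that a particular field accuracy
would be achieved.

## Numerical choices and degenerate inputs

* Relationship matrices are built by the tabular method over the ancestor
  closure of the requested animals; double precision throughout; unknown
  parents are unrelated founders (no unknown-parent groups).
* a_max uses off-diagonal entries only; members of singleton groups report
  a missing within-group a_max and are excluded from that group mean.
* Hardy-Weinberg: Pearson 1-df chi-square at the observed allele frequency,
  no continuity correction; monomorphic markers get p = 1 and fail on MAF
  instead.  QC statistics are computed on the analysis dataset itself.
* All-missing markers fail QC and cannot be imputed (error if attempted).
* Weights and reliabilities are validated into open/closed intervals as
  appropriate; r^2_PA is capped just below 0.5 (its theoretical supremum)
  before deregression.
* K-means ties between equal-objective restarts resolve to the first found
  under the seeded restart order.
* Every stochastic stage derives independent substreams from a single
  master seed (string-hashed for simulation stages, SeedSequence-derived
  per cross-validation fold), so runs are bit-reproducible and folds can be
  recomputed in isolation.

## Problem sizes

Default test and pipeline sizes are chosen for a single desk CPU: herds of
a few hundred animals for unit tests; ~430-animal herds with 5000 markers
(averaged over 5 replicates) for the DGV-heritability boundary computation;
20 replicates at ~700 animals for genetic-correlation recovery; and one
~2100-animal x 2000-marker run of the full pipeline with reduced chains.
Reference-scale chain lengths and panel densities are documented above and
configurable.

## Known limitations

* The emulated evaluation matches reliabilities only approximately for
  animals whose parents are themselves related or inbred (the achieved-
  reliability algebra assumes unrelated, non-inbred parents).
* With sparse marker panels the realized covariance of a linear genotype
  function deviates from pedigree expectation by O(1/sqrt(k)); DGV
  heritability estimates at a few hundred markers can dip a few points
  below 1 even for noiseless DGV.
* The AI-REML fit returns boundary-flagged estimates rather than standard
  errors of boundary parameters' true sampling distribution; SEs near
  |r_g| = 1 or h2 = 1 should be read qualitatively.
* Efficiency calculations assume equal selection intensity and generation
  interval between DGV- and parent-average-based selection, and use
  current (progeny-inflated) parental reliabilities where a real selection
  decision would face lower ones.
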