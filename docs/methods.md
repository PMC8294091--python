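# Methods

## The model

For one environmentally adjusted trait with exactly one record per tree,
all five fitted models are special cases of

    y = 1·β + Σ_k u_k + ε,   u_k ~ N(0, σ²_k K_k),   ε ~ N(0, σ²_e I),

with mutually independent random effects and identity incidence
matrices (the adjustment to one record per tree happens upstream; the
only fixed effect is the overall mean β). The kernels K_k are:

| model     | kernels |
|-----------|------------------------------------------|
| PBLUP-A   | A |
| PBLUP-AD  | A, D |
| GBLUP-A   | G_A |
| GBLUP-AD  | G_A, G_D |
| GBLUP-ADE | G_A, G_D, G_AA, G_AD, G_DD |

Pedigree kernels come from the tabular method (A) and the classical
parental-product formula (D, diagonal forced to 1). The dominance
formula assumes non-inbred pairs; it is applied as printed even on
inbred pedigrees, with a warning — the partial-diallel designs this
package targets have non-inbred founders, so the case is marginal.

Genomic kernels use in-sample allele frequencies of the alternative
allele (the frequencies are re-estimated from exactly the individuals
entering the kernel; whether founders are included is controlled by the
id list passed in, defaulting to the phenotyped progeny). Monomorphic
loci are excluded before construction: their design columns are zero
and would only deflate the denominators. Epistatic kernels are Hadamard
products rescaled so the trace equals n, which puts all five genomic
kernels on the same "average self-relationship 1" scale and makes the
σ²_k directly comparable as variance components.

Rank-deficient kernels (always the case when m < n, and generically for
the all-ones limit) are made invertible by a diagonal ridge, starting
at 1e-6 and escalating tenfold to at most 1e-2 until the smallest
eigenvalue clears 1e-8. The adjustment is flagged on the matrix and
logged. A ridge was preferred to blending with A or I because it is the
smallest perturbation that restores invertibility and keeps the kernel's
own structure intact.

## REML

Variance components maximize the restricted likelihood by
average-information (AI) updates with safeguards:

* a coordinate whose AI proposal leaves the parameter space decays
  geometrically (×0.1) toward the zero boundary instead;
* if the AI step does not improve the restricted log-likelihood after
  step halving, an EM-style per-component update is taken;
* a component falling below 1e-6 × var(y) is fixed at exactly 0,
  flagged as a boundary estimate, and removed from further updates.
  (A much smaller threshold lets a dying component hover just above the
  floor, where it makes the AI matrix near-singular and stalls the
  whole fit; 1e-6 of the phenotypic variance is far below anything
  interpretable as a variance component.)
* convergence is declared when |ΔlogL| < 1e-8 and the largest relative
  parameter change is < 1e-6, or when |ΔlogL| < 1e-8 holds for three
  consecutive iterations. The second clause matters for GBLUP-ADE: the
  (ad, dd, e) directions form a near-flat ridge of the restricted
  likelihood along which parameters can drift indefinitely at a
  stationary logL (see "Identifiability" below).

Standard errors of the components come from the inverse AI matrix at
the optimum and are approximate (curvature-based); boundary-fixed
components are reported with SE 0. AIC = −2 logL + 2t with t the number
of variance parameters **not** fixed at a boundary, residual included
and fixed effects excluded (REML). The alternative convention counting
all parameters is available (`aic_count="all"`).

BLUPs, the fixed-effect mean, and prediction error variances come from
the inverse coefficient matrix of Henderson's mixed-model equations at
the converged components; boundary-fixed effects are dropped from the
system (their BLUPs are identically 0). SEP(EBV) is the square root of
the additive PEV diagonal; SEP(EGV) sums all genetic blocks of the
inverse including the 2× cross-effect covariances. EGV is the sum of
all fitted genetic effects, so EGV ≡ EBV for additive-only models.

## Heritability and derived statistics

h² = σ²_a/σ²_p and H² = σ²_g/σ²_p with σ²_g the sum of exactly the
genetic components the model fits and σ²_p = σ²_g + σ²_e (no
fixed-effect contribution). Variance fractions are components over σ²_p
in percent and sum to 100 including the residual share. Full precision
is kept internally; two-decimal rounding is applied only in reports.

Cross-validation re-estimates the variance components inside every
training fold (the plug-in alternative is available via
`reestimate=False`). Validation trees' phenotypes are masked; their
genetic effects are predicted through the (validation × training)
kernel blocks, u_val = σ²_k K_k[val,train] P y_train, which uses no
validation phenotype. Predictive ability r1 is the per-fold Pearson
correlation between those predictions and the masked phenotypes;
reported dispersion is the SD across all replicate × fold cells.
Predictive accuracy divides r1 by √h² (additive predictions) or √H²
(total genetic), with the heritability taken from the full-data fit of
the same model. Fold assignment is a uniform random partition per
replicate (sizes differing by ≤ 1), reproducible from the seed;
family-stratified folds are not implemented.

Selection statistics: intensity i = φ(z)/p is the exact
infinite-population truncation value (i(0.01) = 2.67). Selection
response takes the top fraction by EGV (or EBV), expressed as a percent
of the population mean; because BLUPs are centered near zero, values
are first put back on the phenotype scale by adding the estimated mean —
a documented interpretation, required for "% of the population average"
to be well defined. Per-year responses divide by the cycle length
(defaults: 11 years with genomic selection, 23 with phenotypic).
Expected gain uses the breeder's equation as a percent of the mean,
ΔG% = 100·i·h²·σ_p/ȳ, with H² replacing h² for total-genetic (clonal)
deployment; this dimensionally consistent form is the package's reading
of the per-cent gain formula.

## Synthetic data generator

The generator emulates a Scots pine progeny-trial design after
imputation: 40 founders, 184 distinct full-sib families sampled from the
half-diallel without replacement, 695 progeny allocated as evenly as
possible across families (the real trial's family-size distribution is
not public; balanced allocation is an assumption), 6,344 unlinked
biallelic SNPs by default. Founder allele frequencies are uniform on
[0.05, 0.95]; founders draw two alleles per locus independently and each
progeny receives one uniformly chosen allele per parent per locus (gene
drop). MAF filtering at 1% mirrors the study's marker panel.

Phenotypes are model-based by default: genetic values are drawn from
the kernel-defined multivariate normals (σ²_a G_A, …, σ²_dd G_DD,
mutually independent) built from the simulated progeny genotypes, plus
i.i.d. residuals, so the REML model is correctly specified and
parameter recovery is a well-posed check. Default variance targets
(σ²_a, σ²_aa, σ²_e) = (300, 140, 1360) give a growth-trait-like
decomposition (h² ≈ 0.17, H² ≈ 0.24) on a trait with mean 100. A
secondary marker-effect generator (explicit per-locus additive and
dominance effects, random locus-pair products for epistasis) is
provided for robustness runs; with finite loci the kernel model is then
only approximately correct, so only realized components are meaningful
there.

What the generator does **not** emulate: linkage disequilibrium beyond
the pedigree, genotyping error and missingness, GBS depth, spatial
field structure, and multi-trait correlation. Passing tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to those real-data features.

## Identifiability and known limitations

With ~4 progeny per family, the dominance-derived kernels are close to
identity in correlation structure (full-sib dominance relatedness 0.25,
additive×dominance ≈ 0.125, dominance×dominance ≈ 0.0625, everything
else ≈ 0), so σ²_ad and σ²_dd are barely separable from σ²_e. Monte
Carlo runs at the default design (30 phenotype replicates on one
simulated trial, GBLUP-ADE) show the consequence: the additive and
additive×additive components are recovered essentially without bias,
and a true-zero dominance component is boundary-flagged in about
two-thirds of replicates, but the ad/dd estimates — truncated at zero
below yet free to wander upward — carry positive mass that REML
compensates by under-estimating σ²_e. The affected sums (σ²_ad + σ²_dd
+ σ²_e and σ²_p) are recovered well. This is a property of
boundary-constrained REML under weak identifiability, not of the
optimizer: constrained refits with ad = dd = 0 have strictly lower
restricted likelihood. Interpret individual nonadditive components from
this design with caution; their sums and the heritabilities are the
stable quantities.

Test-suite problem sizes: the recovery study runs at n = 695 progeny
with m = 2,000 SNPs (kernel structure is stable well below the full
panel since kernels average over loci); the acceptance script's
synthetic run uses m = 1,000. Oracle-equivalence checks run at n ≤ 60
(pedigree), n ≤ 20 (kernels) and n ≤ 15 (REML grid search), where
exhaustive or closed-form references are feasible.

Other limitations: single-trait models only; no spatial residual
structures; no Bayesian whole-genome regression; approximate (AI-based)
variance-component SEs; the exact SEs and AIC of other REML software
can differ in their parameter-counting and boundary conventions.
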