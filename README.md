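# forestblup

Pedigree- and genomic-based BLUP with nonadditive genetic effects for
forest tree breeding evaluation.

Conifer breeding programs that test full-sib families face a classic
problem: the resemblance between sibs mixes additive variance (which a
seed orchard can capture) with dominance and epistatic variance (which
only clonal deployment can). `forestblup` implements the full evaluation
chain used to disentangle them in a Scots pine (*Pinus sylvestris* L.)
partial-diallel progeny trial — and a synthetic-data generator that
reproduces that study design, so the whole pipeline runs and is tested
without any external data.

## What it computes

**Relationship matrices** for individuals `i, j`:

* pedigree additive `A` (tabular method): `A_ii = 1 + A_gh/2`,
  `A_ij = (A_jg + A_jh)/2` with `g, h` the parents of `i`;
* pedigree dominance `D`: `D_ij = (A_gk A_hl + A_gl A_hk)/4`, `D_ii = 1`;
* genomic additive `G_A = ZZ' / 2Σp_i q_i` (VanRaden), `Z = M − 2p`;
* genomic dominance `G_D = WW' / Σ4p_i²q_i²` (Vitezica coding);
* first-order epistatic kernels by trace-normalized Hadamard products:
  `G_AA = G_A⊙G_A / (tr(G_A⊙G_A)/n)`, similarly `G_AD`, `G_DD`.

**Mixed models** `y = 1β + Σ_k u_k + ε` with `u_k ~ N(0, σ²_k K_k)`,
fitted by average-information REML (EM fallback, zero-boundary handling):
PBLUP-A/AD, GBLUP-A/AD/ADE. Results carry variance components with
approximate SEs and boundary flags, log-likelihood, AIC, BLUPs of every
effect (EBV = additive; EGV = total genetic), and SEPs from the inverse
mixed-model-equation coefficient matrix.

**Derived statistics**: narrow/broad-sense heritability
`h² = σ²_a/σ²_p`, `H² = σ²_g/σ²_p`; per-component variance fractions;
k-fold cross-validated predictive ability `r1 = corr(prediction, y)` and
accuracy `r2 = r1/√heritability`; Spearman rank concordance between
models; truncation-selection intensity `i = φ(z)/p`; selection response
as % of the population mean (per cycle and per year); expected genetic
gain `ΔG% = 100·i·h²·σ_p/ȳ` (or `H²` for clonal deployment).

## Worked example

```python
import forestblup as fb

# a partial diallel: 40 parents, 184 full-sib families, 695 progeny,
# additive 300 + additive-x-additive 140 + residual 1360 (trait units^2)
sim = fb.simulate(fb.SimulationConfig(n_loci=1000, seed=1))

kernels = sim.kernels  # genomic kernels for the phenotyped progeny
y = sim.traits.trait("trait")

model = fb.KernelMixedModel(y, kernels, spec="GBLUP-AD")
res = model.fit()
print(res.summary())
```

```
Kernel mixed model (GBLUP-AD), REML
n = 695, iterations = 8, logL = -3568.1346, AIC = 7142.27

   component     estimate         SE  flag
    sigma2_a     243.4941    85.0387
    sigma2_d      67.6484    91.5371
    sigma2_e    1439.9020   124.1651

h2 = 0.14   H2 = 0.18
```

No dominance was simulated: the small σ²_d estimate is within one SE of
zero, while part of the simulated additive×additive signal spills into
it and the residual because this model omits the epistatic kernels.
Fitting `spec="GBLUP-ADE"` adds them;
`res.predict()` returns per-tree EBV, EGV and SEPs,
`fb.heritability(res)` the heritability decomposition, and
`fb.cross_validate(...)` the replicated k-fold predictive ability.

A command-line interface mirrors the pipeline
(`forestblup simulate | kinship | fit | cv | select | report`); every
subcommand also accepts a YAML `--config`.

## Bundled reference estimates

`forestblup.datasets` ships the printed variance-component and
predictive-ability tables of a published Swedish Scots pine progeny
trial (the design emulated by the generator: 40 parents, 184 families,
695 progeny, 6,344 SNPs, traits Ht1/Ht2/DBH1/DBH2/MFA/MOEs/DEN/MOEd).
They serve as worked-example inputs: recomputing heritabilities,
variance fractions and predictive accuracies from those printed
components checks the formulas end to end.

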