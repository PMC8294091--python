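"""Synthetic partial-diallel data generator.

Emulates the post-imputation state of a conifer progeny trial: founder
parents crossed in a partial diallel, full-sib progeny genotyped at
unlinked biallelic SNPs (gene drop from founder allele frequencies), and
one adjusted phenotype per tree assembled from additive, dominance and
first-order epistatic genetic values plus i.i.d. residual noise.

The primary phenotype generator is model-based: the genetic-value vectors
are drawn from zero-mean multivariate normals whose covariances are the
marker-derived kernels themselves (sigma2_a * G_A, sigma2_d * G_D, ...),
so the downstream REML model is correctly specified and parameter
recovery is a well-posed check. A secondary marker-effect generator
(explicit per-locus effects) is provided for robustness experiments; for
it only realized variance components are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import KernelSet, build_kernels
from .pedigree import Pedigree
from .phenotypes import TraitTable

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_phenotypes_marker_effects",
    "simulate",
]

#: kernel kind backing each genetic component
COMPONENT_KERNELS = {
    "a": "G_A", "d": "G_D", "aa": "G_AA", "ad": "G_AD", "dd": "G_DD",
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror the trial layout this package targets: 40 founder
    parents, 184 full-sib families from a partial diallel, 695 progeny,
    6,344 SNPs retained at MAF >= 1%. Variance targets default to a
    growth-trait-like decomposition (additive 300, additive x additive
    140, residual 1360, trait units squared) with a trait mean of 100.
    """

    n_parents: int = 40
    n_families: int = 184
    n_progeny: int = 695
    n_loci: int = 6344
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    maf_floor: float = 0.01
    variance_targets: dict = field(
        default_factory=lambda: {
            "a": 300.0, "d": 0.0, "aa": 140.0, "ad": 0.0, "dd": 0.0, "e": 1360.0,
        }
    )
    trait_mean: float = 100.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self):
        max_fam = self.n_parents * (self.n_parents - 1) // 2
        if self.n_families > max_fam:
            raise ValueError(
                f"n_families={self.n_families} exceeds the "
                f"{max_fam} distinct pairs of {self.n_parents} parents"
            )
        if self.n_families < 1 or self.n_progeny < self.n_families:
            raise ValueError("need at least one progeny per family")
        missing = set(self.variance_targets) - {"a", "d", "aa", "ad", "dd", "e"}
        if missing:
            raise ValueError(f"unknown variance component(s): {sorted(missing)}")
        if any(v < 0 for v in self.variance_targets.values()):
            raise ValueError("variance targets must be non-negative")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder_freq_range must lie inside (0, 1)")


@dataclass
class TruthRecord:
    """True per-individual genetic values and realized variances.

    Invariant: phenotype = trait_mean + a + d + e_aa + e_ad + e_dd +
    residual, exactly.
    """

    values: pd.DataFrame  # columns a, d, e_aa, e_ad, e_dd, residual
    trait_mean: float
    target_variances: dict
    realized_variances: dict

    @property
    def total_genetic(self) -> pd.Series:
        cols = ["a", "d", "e_aa", "e_ad", "e_dd"]
        return self.values[cols].sum(axis=1)


def simulate_pedigree(config: SimulationConfig, rng=None) -> Pedigree:
    """Partial-diallel pedigree: distinct unordered parent pairs, progeny
    counts per family as equal as possible."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    np_, nf, npr = config.n_parents, config.n_families, config.n_progeny
    parents = [f"P{i + 1:03d}" for i in range(np_)]
    pairs = [(i, j) for i in range(np_) for j in range(i + 1, np_)]
    chosen = rng.choice(len(pairs), size=nf, replace=False)
    base, extra = divmod(npr, nf)
    sizes = np.full(nf, base)
    sizes[rng.choice(nf, size=extra, replace=False)] += 1
    records = [(p, None, None) for p in parents]
    prog = 0
    for fam, k in enumerate(chosen):
        i, j = pairs[k]
        for _ in range(sizes[fam]):
            prog += 1
            records.append((f"F{prog:04d}", parents[i], parents[j]))
    return Pedigree.from_records(records)


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, rng=None
) -> GenotypeMatrix:
    """Gene drop through the pedigree at unlinked biallelic loci.

    Founders get two independent alleles per locus at a frequency drawn
    uniformly from ``founder_freq_range``; each offspring receives one
    allele from each parent, the transmitted allele chosen uniformly per
    parent per locus.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, m = pedigree.n, config.n_loci
    lo, hi = config.founder_freq_range
    p = rng.uniform(lo, hi, size=m)
    calls = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if s < 0:
            calls[i] = rng.binomial(2, p)
        else:
            for parent in (s, d):
                g = calls[parent]
                allele = np.where(
                    g == 2, 1, np.where(g == 0, 0, rng.integers(0, 2, size=m))
                )
                calls[i] += allele.astype(np.int8)
    return GenotypeMatrix(
        individual_ids=list(pedigree.ids),
        locus_ids=[f"snp{j + 1:05d}" for j in range(m)],
        calls=calls,
    )


def _chol_draw(rng, K: np.ndarray, var: float) -> np.ndarray:
    """Draw N(0, var*K) via Cholesky (tiny jitter escalation if needed)."""
    n = K.shape[0]
    jitter = 0.0
    for _ in range(8):
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 10
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("kernel not positive definite")
    return np.sqrt(var) * (L @ rng.standard_normal(n))


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimulationConfig,
    rng=None,
    kernels: KernelSet | None = None,
    progeny_only: bool = True,
) -> tuple[TraitTable, TruthRecord, KernelSet]:
    """Model-based phenotypes for the phenotyped individuals.

    Genetic components are drawn jointly from the kernel-defined
    multivariate normal laws (mutually independent across components);
    residuals are i.i.d. normal. Kernels are built from the simulated
    genotypes after MAF filtering at ``maf_floor``, for the progeny set
    only by default (founders in the trial carry no phenotype records).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if progeny_only:
        ids = [i for i, f in zip(pedigree.ids, pedigree.is_founder) if not f]
    else:
        ids = list(pedigree.ids)
    if kernels is None:
        gm = genotypes.subset(ids).filter_maf(config.maf_floor)
        # build the full genomic kernel set so any downstream model spec
        # can be fitted to the simulated data without re-deriving kernels
        kernels = build_kernels(
            ["G_A", "G_D", "G_AA", "G_AD", "G_DD"], genotypes=gm
        )
    n = len(ids)
    comps = {}
    for comp, kind in COMPONENT_KERNELS.items():
        var = config.variance_targets.get(comp, 0.0)
        if var > 0:
            comps[comp] = _chol_draw(rng, kernels[kind].values, var)
        else:
            comps[comp] = np.zeros(n)
    resid = rng.normal(0.0, np.sqrt(config.variance_targets.get("e", 0.0)), n)
    values = pd.DataFrame(
        {
            "a": comps["a"], "d": comps["d"], "e_aa": comps["aa"],
            "e_ad": comps["ad"], "e_dd": comps["dd"], "residual": resid,
        },
        index=ids,
    )
    y = config.trait_mean + values.sum(axis=1)
    truth = TruthRecord(
        values=values,
        trait_mean=config.trait_mean,
        target_variances=dict(config.variance_targets),
        realized_variances={c: float(values[col].var(ddof=1))
                            for c, col in zip(("a", "d", "aa", "ad", "dd", "e"),
                                              values.columns)},
    )
    traits = TraitTable(data=pd.DataFrame({config.trait_name: y}))
    return traits, truth, kernels


def simulate_phenotypes_marker_effects(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimulationConfig,
    rng=None,
    n_epistatic_pairs: int = 500,
    progeny_only: bool = True,
) -> tuple[TraitTable, TruthRecord]:
    """Marker-effect-based phenotypes (robustness generator).

    Per-locus additive effects and dominance deviations, plus random
    locus-pair products for epistasis, each component rescaled to hit its
    target variance in realized terms at the simulated sample. Because the
    genetic architecture is finite-locus, the fitted kernel model is only
    approximately correct here; report realized, not target, components.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if progeny_only:
        ids = [i for i, f in zip(pedigree.ids, pedigree.is_founder) if not f]
    else:
        ids = list(pedigree.ids)
    gm = genotypes.subset(ids).filter_maf(config.maf_floor)
    M = gm.calls.astype(float)
    p = gm.allele_freq
    Z = M - 2 * p
    het = (M == 1).astype(float)
    Wd = het - 2 * p * (1 - p)  # centered heterozygosity indicator
    n, m = M.shape

    def scaled(base: np.ndarray, target: float) -> np.ndarray:
        v = base.var(ddof=1)
        if target <= 0 or v <= 0:
            return np.zeros(n)
        return base * np.sqrt(target / v)

    tv = config.variance_targets
    a = scaled(Z @ rng.standard_normal(m), tv.get("a", 0.0))
    d = scaled(Wd @ rng.standard_normal(m), tv.get("d", 0.0))
    pairs = rng.integers(0, m, size=(n_epistatic_pairs, 2))
    aa = scaled(
        (Z[:, pairs[:, 0]] * Z[:, pairs[:, 1]]) @ rng.standard_normal(n_epistatic_pairs),
        tv.get("aa", 0.0),
    )
    ad = scaled(
        (Z[:, pairs[:, 0]] * Wd[:, pairs[:, 1]]) @ rng.standard_normal(n_epistatic_pairs),
        tv.get("ad", 0.0),
    )
    dd = scaled(
        (Wd[:, pairs[:, 0]] * Wd[:, pairs[:, 1]]) @ rng.standard_normal(n_epistatic_pairs),
        tv.get("dd", 0.0),
    )
    resid = rng.normal(0.0, np.sqrt(tv.get("e", 0.0)), n)
    values = pd.DataFrame(
        {"a": a, "d": d, "e_aa": aa, "e_ad": ad, "e_dd": dd, "residual": resid},
        index=ids,
    )
    y = config.trait_mean + values.sum(axis=1)
    truth = TruthRecord(
        values=values,
        trait_mean=config.trait_mean,
        target_variances=dict(tv),
        realized_variances={c: float(values[col].var(ddof=1))
                            for c, col in zip(("a", "d", "aa", "ad", "dd", "e"),
                                              values.columns)},
    )
    return TraitTable(data=pd.DataFrame({config.trait_name: y})), truth


@dataclass
class SimulationResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    traits: TraitTable
    truth: TruthRecord
    kernels: KernelSet  # genomic kernels on the phenotyped set


def simulate(config: SimulationConfig | None = None, **kwargs) -> SimulationResult:
    """One-call generator: pedigree -> gene drop -> phenotypes.

    With a fixed ``seed`` in the config every output is bit-reproducible.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    traits, truth, kernels = simulate_phenotypes(geno, ped, config)
    return SimulationResult(ped, geno, traits, truth, kernels)
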