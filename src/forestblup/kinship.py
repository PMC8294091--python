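"""Additive, dominance and epistatic relationship matrices.

Pedigree-based:

* ``A`` — numerator relationship matrix by the tabular method:
  ``A_ii = 1 + A_gh/2`` (g, h the parents of i), ``A_ij = (A_jg + A_jh)/2``.
* ``D`` — dominance relationships ``D_ij = (A_gk A_hl + A_gl A_hk)/4``
  (g,h parents of i; k,l parents of j), diagonal fixed at 1. The classical
  formula assumes non-inbred pairs; a warning is emitted if the pedigree
  carries inbreeding.

Marker-based (n individuals x m loci, p_i = alternative-allele frequency):

* ``G_A = Z Z' / (2 * sum_i p_i q_i)`` with ``Z = M - 2p`` (VanRaden-type
  realized relationship matrix).
* ``G_D = W W' / sum_i 4 p_i^2 q_i^2`` with W coding -2q_i^2 / 2 p_i q_i /
  -2p_i^2 for alternative homozygote / heterozygote / reference homozygote.
* First-order epistatic kernels by Hadamard products rescaled so their
  trace equals n: ``G_AA = G_A (.) G_A / (tr(G_A (.) G_A)/n)`` and the
  analogous ``G_AD``, ``G_DD``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "RelationshipMatrix",
    "KernelSet",
    "KINDS",
    "pedigree_additive",
    "pedigree_dominance",
    "genomic_additive",
    "genomic_dominance",
    "epistatic_kernels",
    "ensure_psd",
    "build_kernels",
    "write_matrix",
    "read_matrix",
]

KINDS = ("A", "D", "G_A", "G_D", "G_AA", "G_AD", "G_DD")


@dataclass
class RelationshipMatrix:
    """Symmetric covariance-structure kernel tagged by kind."""

    kind: str
    ids: list[str]
    values: np.ndarray
    psd_adjusted: bool = False
    scaling: float | None = None  # denominator used in construction

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError(f"{self.kind} matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {g: i for i, g in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids not in {self.kind} matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(
            self.kind, list(ids), self.values[np.ix_(idx, idx)],
            psd_adjusted=self.psd_adjusted, scaling=self.scaling,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


class KernelSet:
    """Mapping kind -> RelationshipMatrix with a shared id ordering."""

    def __init__(self, matrices: dict[str, RelationshipMatrix], provenance: str = ""):
        kinds = list(matrices)
        if not kinds:
            raise ValueError("empty kernel set")
        ids0 = matrices[kinds[0]].ids
        for k in kinds[1:]:
            if matrices[k].ids != ids0:
                raise ValueError(f"kernel {k} has a different id ordering")
        self.matrices = dict(matrices)
        self.provenance = provenance

    @property
    def ids(self) -> list[str]:
        return list(next(iter(self.matrices.values())).ids)

    @property
    def kinds(self) -> list[str]:
        return list(self.matrices)

    def __getitem__(self, kind: str) -> RelationshipMatrix:
        return self.matrices[kind]

    def __contains__(self, kind: str) -> bool:
        return kind in self.matrices

    def subset(self, ids: list[str]) -> "KernelSet":
        return KernelSet(
            {k: m.subset(ids) for k, m in self.matrices.items()},
            provenance=self.provenance,
        )

    def ensure_psd(self, ridge: float = 1e-6) -> "KernelSet":
        return KernelSet(
            {k: ensure_psd(m, ridge=ridge) for k, m in self.matrices.items()},
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# pedigree-based kernels


def pedigree_additive(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method."""
    n = pedigree.n
    s, d = pedigree.sire_idx, pedigree.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        if s[i] >= 0:
            A[i, :i] = 0.5 * (A[:i, s[i]] + A[:i, d[i]])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[s[i], d[i]]
        else:
            A[i, i] = 1.0
    return RelationshipMatrix("A", list(pedigree.ids), A)


def pedigree_dominance(
    pedigree: Pedigree, A: RelationshipMatrix | None = None
) -> RelationshipMatrix:
    """Dominance relationship matrix D from parental A entries.

    ``D_ij = (A_gk A_hl + A_gl A_hk) / 4`` where (g, h) are i's parents and
    (k, l) are j's parents; pairs involving a founder get 0; ``D_ii = 1``.
    """
    if A is None:
        A = pedigree_additive(pedigree)
    if A.ids != pedigree.ids:
        raise ValueError("A matrix ids do not match pedigree")
    Av = A.values
    if np.any(np.diag(Av) > 1.0 + 1e-12):
        warnings.warn(
            "pedigree contains inbreeding; the classical dominance formula "
            "assumes non-inbred pairs and is applied as-is",
            stacklevel=2,
        )
    n = pedigree.n
    D = np.zeros((n, n))
    has_par = ~pedigree.is_founder
    idx = np.where(has_par)[0]
    if idx.size:
        g = pedigree.sire_idx[idx]
        h = pedigree.dam_idx[idx]
        Dsub = 0.25 * (
            Av[np.ix_(g, g)] * Av[np.ix_(h, h)] + Av[np.ix_(g, h)] * Av[np.ix_(h, g)]
        )
        D[np.ix_(idx, idx)] = Dsub
    np.fill_diagonal(D, 1.0)
    D = (D + D.T) / 2.0
    return RelationshipMatrix("D", list(pedigree.ids), D)


# ---------------------------------------------------------------------------
# marker-based kernels


def _polymorphic(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    p = gm.allele_freq
    keep = (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("all loci are monomorphic; genomic kernel undefined")
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} monomorphic locus/loci from "
            "genomic kernel construction",
            stacklevel=3,
        )
    return gm.calls[:, keep].astype(np.float64), p[keep]


def genomic_additive(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Realized additive relationship matrix G_A = ZZ' / (2 sum p q)."""
    M, p = _polymorphic(gm)
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix("G_A", list(gm.individual_ids), G, scaling=denom)


def genomic_dominance(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Dominance relationship matrix G_D = WW' / sum 4 p^2 q^2."""
    M, p = _polymorphic(gm)
    q = 1.0 - p
    # per-locus dominance coding by genotype class
    W = np.where(M == 2, -2.0 * q**2, np.where(M == 1, 2.0 * p * q, -2.0 * p**2))
    denom = np.sum(4.0 * p**2 * q**2)
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix("G_D", list(gm.individual_ids), G, scaling=denom)


def epistatic_kernels(
    G_A: RelationshipMatrix, G_D: RelationshipMatrix
) -> tuple[RelationshipMatrix, RelationshipMatrix, RelationshipMatrix]:
    """First-order epistatic kernels from Hadamard products.

    Each product is rescaled by trace/n so the output trace equals n.
    """
    if G_A.ids != G_D.ids:
        raise ValueError("G_A and G_D must share the same id ordering")
    n = G_A.n
    out = []
    for kind, left, right in (
        ("G_AA", G_A.values, G_A.values),
        ("G_AD", G_A.values, G_D.values),
        ("G_DD", G_D.values, G_D.values),
    ):
        H = left * right
        tr = np.trace(H)
        if tr <= 0:
            raise ValueError(f"zero trace in Hadamard product for {kind}")
        scale = tr / n
        out.append(
            RelationshipMatrix(kind, list(G_A.ids), H / scale, scaling=scale)
        )
    return tuple(out)


def ensure_psd(
    rm: RelationshipMatrix,
    ridge: float = 1e-6,
    min_eig: float = 1e-8,
    max_ridge: float = 1e-2,
) -> RelationshipMatrix:
    """Return an invertible copy, adding a diagonal ridge if needed.

    The ridge starts at ``ridge`` and escalates tenfold until the smallest
    eigenvalue exceeds ``min_eig`` (or ``max_ridge`` is reached). The
    adjustment is flagged on the result and logged as a warning.
    """
    w = np.linalg.eigvalsh(rm.values)
    if w[0] > min_eig:
        return rm
    r = ridge
    values = rm.values
    while True:
        adjusted = values + r * np.eye(rm.n)
        if np.linalg.eigvalsh(adjusted)[0] > min_eig or r >= max_ridge:
            break
        r *= 10.0
    warnings.warn(
        f"{rm.kind} kernel adjusted with diagonal ridge {r:g} "
        f"(smallest eigenvalue was {w[0]:.3e})",
        stacklevel=2,
    )
    return RelationshipMatrix(
        rm.kind, list(rm.ids), adjusted, psd_adjusted=True, scaling=rm.scaling
    )


def build_kernels(
    kinds: list[str],
    pedigree: Pedigree | None = None,
    genotypes: GenotypeMatrix | None = None,
    ids: list[str] | None = None,
    ridge: float = 1e-6,
    make_invertible: bool = True,
) -> KernelSet:
    """Construct the requested relationship matrices in one call.

    Pedigree kernels (A, D) are computed on the full pedigree then cut down
    to ``ids``; genomic kernels use exactly the genotyped individuals in
    ``ids`` (allele frequencies estimated from that same set).
    """
    matrices: dict[str, RelationshipMatrix] = {}
    need_ped = [k for k in kinds if k in ("A", "D")]
    need_gen = [k for k in kinds if k.startswith("G_")]
    if need_ped:
        if pedigree is None:
            raise ValueError("pedigree required for kinds A/D")
        A = pedigree_additive(pedigree)
        if "A" in kinds:
            matrices["A"] = A
        if "D" in kinds:
            matrices["D"] = pedigree_dominance(pedigree, A)
    if need_gen:
        if genotypes is None:
            raise ValueError("genotypes required for genomic kinds")
        gm = genotypes.subset(ids) if ids is not None else genotypes
        GA = genomic_additive(gm)
        GD = genomic_dominance(gm) if set(need_gen) - {"G_A"} else None
        if "G_A" in kinds:
            matrices["G_A"] = GA
        if "G_D" in kinds:
            matrices["G_D"] = GD
        if {"G_AA", "G_AD", "G_DD"} & set(kinds):
            GAA, GAD, GDD = epistatic_kernels(GA, GD)
            for k, m in (("G_AA", GAA), ("G_AD", GAD), ("G_DD", GDD)):
                if k in kinds:
                    matrices[k] = m
    if ids is not None:
        matrices = {k: m.subset(ids) if m.ids != list(ids) else m
                    for k, m in matrices.items()}
    if make_invertible:
        matrices = {k: ensure_psd(m, ridge=ridge) for k, m in matrices.items()}
    provenance = "+".join(
        p for p, used in (("pedigree", need_ped), ("genomic", need_gen)) if used
    )
    return KernelSet(matrices, provenance=provenance)


# ---------------------------------------------------------------------------
# persistence: full-precision tabular round-trip


def write_matrix(rm: RelationshipMatrix, path) -> None:
    """Write a relationship matrix to CSV with a metadata header line.

    Values are stored in hex float notation for an exact round-trip.
    """
    with open(path, "w") as fh:
        fh.write(f"#kind={rm.kind},psd_adjusted={int(rm.psd_adjusted)}\n")
        fh.write("id," + ",".join(rm.ids) + "\n")
        for i, row in zip(rm.ids, rm.values):
            fh.write(i + "," + ",".join(v.hex() for v in row) + "\n")


def read_matrix(path, expect_ids: list[str] | None = None) -> RelationshipMatrix:
    """Read a matrix written by :func:`write_matrix` (lossless)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#kind="):
            raise ValueError("not a forestblup matrix file (missing #kind header)")
        meta = dict(kv.split("=") for kv in header[1:].split(","))
        ids = fh.readline().strip().split(",")[1:]
        rows = []
        for line in fh:
            parts = line.strip().split(",")
            rows.append([float.fromhex(v) for v in parts[1:]])
    if expect_ids is not None and ids != list(expect_ids):
        raise ValueError("id mismatch reading matrix file")
    return RelationshipMatrix(
        kind=meta["kind"],
        ids=ids,
        values=np.array(rows),
        psd_adjusted=bool(int(meta.get("psd_adjusted", "0"))),
    )
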