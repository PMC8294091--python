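"""Genotype matrix container and readers (CSV, PLINK .raw, VCF).

Genotypes are coded 0/1/2 as counts of the ALTERNATIVE allele; the
per-locus allele frequency ``p`` always refers to the alternative allele
and is estimated in-sample from the individuals actually loaded.
Missing calls are an error — imputation happens upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotypes", "GenotypeError"]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Complete n-individual x m-locus matrix of alternative-allele counts."""

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray  # (n, m) int8, values in {0, 1, 2}

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        n, m = self.calls.shape
        if n != len(self.individual_ids) or m != len(self.locus_ids):
            raise GenotypeError("calls shape does not match id lists")
        if np.isnan(self.calls.astype(float)).any():
            i, j = np.argwhere(np.isnan(self.calls.astype(float)))[0]
            raise GenotypeError(
                f"missing call for individual {self.individual_ids[i]!r} "
                f"at locus {self.locus_ids[j]!r}"
            )
        bad = ~np.isin(self.calls, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"call {self.calls[i, j]!r} not in {{0,1,2}} for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_ids[j]!r}"
            )
        self.calls = self.calls.astype(np.int8)

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def m(self) -> int:
        return self.calls.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternative-allele frequency per locus, p_i = colsum / 2n."""
        return self.calls.sum(axis=0, dtype=np.float64) / (2.0 * self.n)

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, threshold: float) -> "GenotypeMatrix":
        """Drop loci with minor allele frequency below ``threshold``."""
        keep = self.maf >= threshold
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=[l for l, k in zip(self.locus_ids, keep) if k],
            calls=self.calls[:, keep],
        )

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise GenotypeError(f"ids not in genotype matrix: {missing[:5]}")
        idx = [pos[i] for i in ids]
        return GenotypeMatrix(list(ids), list(self.locus_ids), self.calls[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.individual_ids, columns=self.locus_ids
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="individual")


def _read_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        ind = df.index[df.isna().any(axis=1)][0]
        loc = df.columns[df.isna().any(axis=0)][0]
        raise GenotypeError(f"missing call for individual {ind!r} at locus {loc!r}")
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        locus_ids=[str(c) for c in df.columns],
        calls=df.to_numpy(),
    )


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    loci = [c for c in df.columns if c not in meta]
    sub = df[loci]
    if sub.isna().any().any():
        ind = df["IID"][sub.isna().any(axis=1)].iloc[0]
        loc = sub.columns[sub.isna().any(axis=0)][0]
        raise GenotypeError(f"missing call for individual {ind!r} at locus {loc!r}")
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df["IID"]],
        locus_ids=loci,
        calls=sub.to_numpy(),
    )


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from e
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    locus_ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping non-biallelic record {var.CHROM}:{var.POS}", stacklevel=2
            )
            continue
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=missing(UNKNOWN), 3=hom-alt
        if (gts == 2).any():
            i = int(np.where(gts == 2)[0][0])
            raise GenotypeError(
                f"missing call for individual {ids[i]!r} at locus "
                f"{var.CHROM}:{var.POS}"
            )
        calls = np.where(gts == 3, 2, gts)
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(name)
        rows.append(calls)
    return GenotypeMatrix(ids, locus_ids, np.array(rows).T)


def read_genotypes(path, format: str = "csv", maf_threshold: float = 0.0) -> GenotypeMatrix:
    """Read a complete genotype matrix and apply a MAF filter.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"csv", "plink_raw", "vcf"}
        ``csv``: rows = individuals, columns = loci, first column = id.
        ``plink_raw``: PLINK ``--recode A`` output (additive 0/1/2 coding).
        ``vcf``: biallelic records, GT field, read via cyvcf2
        (non-biallelic records are skipped with a warning).
    maf_threshold : float
        Loci with min(p, 1-p) below this are dropped after loading.

    Raises
    ------
    GenotypeError
        On any missing call, naming the individual and locus.
    """
    readers = {"csv": _read_csv, "plink_raw": _read_plink_raw, "vcf": _read_vcf}
    if format not in readers:
        raise ValueError(f"format must be one of {sorted(readers)}, got {format!r}")
    gm = readers[format](path)
    if maf_threshold > 0:
        gm = gm.filter_maf(maf_threshold)
    return gm
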