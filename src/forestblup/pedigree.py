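"""Pedigree container with validation and topological ordering.

A pedigree is an ordered list of (individual, sire, dam) triplets. Parents
are either both known or both unknown: the partial-diallel designs this
package targets produce full-sib families only, and rejecting half-known
parentage keeps the dominance relationship matrix well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "read_pedigree", "PedigreeError"]

#: parent codes treated as "unknown"
UNKNOWN = {"", "0", "NA", "na", ".", "nan", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates,
    single known parents, parents missing from the individual list)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    ids : list of str
        Individual identifiers in topological order (parents before
        offspring).
    sire_idx, dam_idx : ndarray of int
        Positional index of each individual's sire/dam in ``ids``;
        ``-1`` for unknown (founder).
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    generation: np.ndarray = field(default=None)

    def __post_init__(self):
        self.sire_idx = np.asarray(self.sire_idx, dtype=np.int64)
        self.dam_idx = np.asarray(self.dam_idx, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(
                f"duplicate individual id(s): {list(dup[dup > 1].index)}"
            )
        if self.sire_idx.shape != (n,) or self.dam_idx.shape != (n,):
            raise PedigreeError("parent index arrays must match ids length")
        single = (self.sire_idx < 0) ^ (self.dam_idx < 0)
        if single.any():
            bad = [self.ids[i] for i in np.where(single)[0]]
            raise PedigreeError(f"individual(s) with a single known parent: {bad}")
        # topological order: parents strictly before offspring
        pos = np.arange(n)
        for p in (self.sire_idx, self.dam_idx):
            known = p >= 0
            if (p[known] >= pos[known]).any():
                raise PedigreeError("pedigree is not topologically ordered")
        if self.generation is None:
            gen = np.zeros(n, dtype=np.int64)
            for i in range(n):
                if self.sire_idx[i] >= 0:
                    gen[i] = 1 + max(gen[self.sire_idx[i]], gen[self.dam_idx[i]])
            self.generation = gen

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return self.sire_idx < 0

    @property
    def founders(self) -> list[str]:
        return [i for i, f in zip(self.ids, self.is_founder) if f]

    def parents_of(self, individual: str) -> tuple[str, str] | None:
        i = self.ids.index(individual)
        if self.sire_idx[i] < 0:
            return None
        return self.ids[self.sire_idx[i]], self.ids[self.dam_idx[i]]

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build a pedigree from (individual, sire, dam) triplets.

        The records are re-sorted topologically if needed; a cycle or a
        parent never listed as an individual raises :class:`PedigreeError`.
        Unknown parents may be given as ``None``, ``""`` or ``"0"``.
        """

        def norm(x) -> str | None:
            if x is None or (isinstance(x, float) and np.isnan(x)):
                return None
            s = str(x).strip()
            return None if s in UNKNOWN else s

        rows = [(str(i).strip(), norm(s), norm(d)) for i, s, d in records]
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise PedigreeError(
                f"duplicate individual id(s): {list(dup[dup > 1].index)}"
            )
        known = set(ids)
        for ind, s, d in rows:
            for p in (s, d):
                if p is not None and p not in known:
                    raise PedigreeError(
                        f"parent {p!r} of {ind!r} never appears as an individual"
                    )
        # Kahn-style topological sort, stable w.r.t. input order
        parent_of = {ind: (s, d) for ind, s, d in rows}
        placed: dict[str, int] = {}
        order: list[str] = []
        pending = list(ids)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                s, d = parent_of[ind]
                if all(p is None or p in placed for p in (s, d)):
                    placed[ind] = len(order)
                    order.append(ind)
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:
                raise PedigreeError(f"cycle detected involving: {remaining}")
            pending = remaining
        sire = np.array(
            [placed[parent_of[i][0]] if parent_of[i][0] is not None else -1 for i in order]
        )
        dam = np.array(
            [placed[parent_of[i][1]] if parent_of[i][1] is not None else -1 for i in order]
        )
        return cls(ids=order, sire_idx=sire, dam_idx=dam)

    def to_frame(self) -> pd.DataFrame:
        sire = [self.ids[i] if i >= 0 else "0" for i in self.sire_idx]
        dam = [self.ids[i] if i >= 0 else "0" for i in self.dam_idx]
        return pd.DataFrame(
            {"individual": self.ids, "sire": sire, "dam": dam}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """Read a 3-column pedigree file (CSV or TSV, header row).

    Expected columns: ``individual``, ``sire``, ``dam`` (case-insensitive);
    unknown parents encoded as empty, ``0`` or ``NA``. Rows are re-sorted
    topologically; validation errors raise :class:`PedigreeError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"individual", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    records = list(df[["individual", "sire", "dam"]].itertuples(index=False, name=None))
    return Pedigree.from_records(records)
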