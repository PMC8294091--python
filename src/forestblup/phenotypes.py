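"""Adjusted-phenotype table: one record per individual per trait.

Phenotypes entering the mixed models are assumed already adjusted for
trial design / spatial effects, so the only fixed effect downstream is
the overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TraitTable", "read_phenotypes"]


@dataclass
class TraitTable:
    """Wrapper around a DataFrame indexed by individual id, one numeric
    column per trait; NaN marks a trait missing for that individual."""

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate individual id(s) in phenotypes: {dup}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def trait(self, name: str, ids: list[str] | None = None) -> pd.Series:
        """Return one trait as a Series, optionally aligned to ``ids``
        (dropping individuals with a missing record)."""
        s = self.data[name]
        if ids is not None:
            s = s.reindex(ids)
        return s.dropna().astype(float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="individual")


def read_phenotypes(path) -> TraitTable:
    """Read an adjusted phenotype CSV (first column = individual id)."""
    df = pd.read_csv(path, index_col=0)
    return TraitTable(data=df.apply(pd.to_numeric, errors="coerce"))
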