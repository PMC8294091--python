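"""Response to selection and expected genetic gain.

Truncation selection on a normal trait: intensity i = phi(z)/p at
selected proportion p (z the upper-p standard-normal quantile). The
realized response is reported as a percentage of the population mean,
so breeding values must be put back on the phenotype scale (mean added)
before the percentage is taken. Per-year responses divide by the breeding
cycle length (genomic selection 11 years vs phenotypic selection 23 years
by default). Expected gain from the breeder's equation, as a percent of
the trait mean: dG% = 100 * i * h2 * sigma_p / mean (narrow variant) or
with H2 (broad variant, total-genetic deployment).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = [
    "selection_intensity",
    "response_percent",
    "response_per_year",
    "expected_gain",
    "GS_CYCLE_YEARS",
    "PS_CYCLE_YEARS",
]

#: default breeding-cycle lengths (years): genomic vs phenotypic selection
GS_CYCLE_YEARS = 11.0
PS_CYCLE_YEARS = 23.0


def selection_intensity(p: float) -> float:
    """Truncation-selection intensity i = phi(z)/p for proportion p.

    p = 1 returns 0 (no selection); p must lie in (0, 1].
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"selected proportion must be in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    z = norm.ppf(1.0 - p)
    return float(norm.pdf(z) / p)


def response_percent(values, proportion: float) -> float:
    """Selection response as percent of the population average.

    ``values`` are per-individual EGVs (or EBVs for additive-only models)
    expressed on the phenotype scale — i.e., the trait mean added to the
    BLUPs so the denominator is the population average, not ~0. The top
    ``proportion`` by those same values is selected.
    """
    v = np.asarray(values, dtype=float)
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must be in (0, 1]")
    mean0 = v.mean()
    if mean0 == 0:
        raise ValueError("population mean is zero; percentage undefined")
    k = max(1, int(round(proportion * len(v))))
    sel = np.sort(v)[-k:]
    return float(100.0 * (sel.mean() - mean0) / mean0)


def response_per_year(response: float, cycle_years: float) -> float:
    """Scale a per-cycle response (%) to percent per year."""
    if cycle_years <= 0:
        raise ValueError("cycle_years must be positive")
    return response / cycle_years


def expected_gain(
    heritability: float, i: float, sigma_p: float, mean: float,
    variant: str = "narrow",
) -> float:
    """Expected genetic gain, percent of the trait mean.

    dG% = 100 * i * heritability * sigma_p / mean, with sigma_p the
    phenotypic standard deviation. Use h2 with ``variant="narrow"``
    (additive deployment via seed orchard) or H2 with ``variant="broad"``
    (total-genetic deployment via clonal propagation).
    """
    if variant not in ("narrow", "broad"):
        raise ValueError("variant must be 'narrow' or 'broad'")
    if mean == 0:
        raise ValueError("trait mean is zero; percentage undefined")
    if not 0.0 <= heritability <= 1.0:
        raise ValueError("heritability must be in [0, 1]")
    return float(100.0 * i * heritability * sigma_p / mean)
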