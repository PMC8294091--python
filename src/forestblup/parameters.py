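"""Heritabilities and variance-fraction summaries.

Narrow-sense heritability h2 = sigma2_a / sigma2_p; broad-sense
H2 = sigma2_g / sigma2_p where sigma2_g sums exactly the genetic
components the model fits (a; a+d; or a+d+aa+ad+dd) and
sigma2_p = sigma2_g + sigma2_e. Fractions are each component divided by
sigma2_p, in percent; they sum to 100 over fitted components including
the residual. Full precision is kept internally; report rounding is two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["HeritabilityReport", "heritability", "variance_fractions",
           "heritability_from_components"]

#: genetic components in canonical order
GENETIC = ("a", "d", "aa", "ad", "dd")


@dataclass
class HeritabilityReport:
    h2: float
    H2: float
    sigma2_g: float
    sigma2_p: float
    fractions: pd.Series  # percent of sigma2_p per component, residual included

    def rounded(self, ndigits: int = 2) -> "HeritabilityReport":
        return HeritabilityReport(
            h2=round(self.h2, ndigits),
            H2=round(self.H2, ndigits),
            sigma2_g=self.sigma2_g,
            sigma2_p=self.sigma2_p,
            fractions=self.fractions.round(ndigits),
        )


def _components_of(obj) -> dict[str, float]:
    """Extract {component: variance} from results, Series or mapping."""
    if hasattr(obj, "varcomp"):  # MixedModelResults
        vc = obj.varcomp
    elif isinstance(obj, pd.Series):
        vc = obj
    else:
        vc = pd.Series(dict(obj))
    out = {}
    for key, val in vc.items():
        name = str(key)
        if name.startswith("sigma2_"):
            name = name[len("sigma2_"):]
        if pd.isna(val):
            continue
        out[name] = float(val)
    return out


def heritability_from_components(components) -> HeritabilityReport:
    """Heritabilities from a plain {component: variance} mapping.

    Keys: any subset of ``a, d, aa, ad, dd`` plus ``e`` (residual).
    Useful for recomputing published tables from their printed variance
    components without refitting anything.
    """
    comps = _components_of(components)
    if "e" not in comps:
        raise ValueError("residual component 'e' is required")
    sigma2_g = sum(comps[c] for c in GENETIC if c in comps)
    sigma2_p = sigma2_g + comps["e"]
    if sigma2_p <= 0:
        raise ValueError("phenotypic variance is zero")
    fractions = pd.Series(
        {c: 100.0 * comps[c] / sigma2_p for c in (*GENETIC, "e") if c in comps}
    )
    return HeritabilityReport(
        h2=comps.get("a", 0.0) / sigma2_p,
        H2=sigma2_g / sigma2_p,
        sigma2_g=sigma2_g,
        sigma2_p=sigma2_p,
        fractions=fractions,
    )


def heritability(results) -> HeritabilityReport:
    """Heritability report for a fitted model (or variance Series)."""
    return heritability_from_components(results)


def variance_fractions(results) -> pd.Series:
    """Percent of phenotypic variance per fitted component (residual
    included); sums to 100."""
    return heritability_from_components(results).fractions
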