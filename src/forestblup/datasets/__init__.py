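"""Bundled reference estimates from a published Swedish Scots pine
full-sib progeny trial (40 founder parents, 184 full-sib families, 695
progeny, 6,344 SNPs after imputation and MAF >= 1% filtering).

Two tables of printed point estimates are shipped:

* variance components, heritabilities and AIC per trait x model
  (PBLUP-A/AD, GBLUP-A/AD/ADE); the ``boundary`` column lists components
  the original REML fit fixed at the zero boundary (reported as null).
* cross-validated predictive ability (r1) and accuracy (r2) per trait x
  model, separately for additive (A_VP) and total genetic (G_VP)
  predictions.

These are inputs for worked-example recomputations (heritabilities,
variance fractions, r2 from r1), not outputs of this package.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_variance_components", "load_predictive_ability"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_variance_components() -> pd.DataFrame:
    """Trait x model variance components, heritabilities, AIC.

    ``boundary`` holds a ``;``-separated list of components fixed at the
    zero boundary in the original fit (NaN when none).
    """
    return _read("pine_trial_variance_components.csv")


def load_predictive_ability() -> pd.DataFrame:
    """Trait x model predictive ability r1 and accuracy r2 (10-fold CV,
    10 replicates, means over folds)."""
    return _read("pine_trial_predictive_ability.csv")
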