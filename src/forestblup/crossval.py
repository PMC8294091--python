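"""Cross-validated predictive ability and accuracy.

k-fold cross-validation with replicates: within each training fold the
variance components are re-estimated by REML, validation phenotypes are
masked, and validation individuals' additive (A_VP) and total genetic
(G_VP) values are predicted through the relationship-matrix links to the
training set. Predictive ability r1 is the per-fold Pearson correlation
between predictions and the masked phenotypes; predictive accuracy
r2 = r1 / sqrt(heritability) with the matching narrow/broad heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .kinship import KernelSet
from .reml import ConvergenceError, KernelMixedModel, _as_spec

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_folds",
    "cross_validate",
    "predictive_accuracy",
    "spearman_concordance",
]


@dataclass
class FoldPlan:
    """Replicate x individual fold assignment."""

    k: int
    replicates: int
    seed: int
    ids: list[str]
    assignment: np.ndarray  # (replicates, n) of fold indices in [0, k)

    def fold_indices(self, replicate: int, fold: int) -> np.ndarray:
        return np.where(self.assignment[replicate] == fold)[0]


def make_folds(ids, k: int = 10, replicates: int = 10, seed: int = 0) -> FoldPlan:
    """Uniform random partition of ``ids`` into ``k`` folds, repeated
    ``replicates`` times; fold sizes differ by at most one. Deterministic
    given ``seed``."""
    ids = [str(i) for i in ids]
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} individuals")
    assignment = np.empty((replicates, n), dtype=np.int64)
    for rep in range(replicates):
        state = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,)).generate_state(1)[0]
            % (2**32 - 1)
        )
        kf = KFold(n_splits=k, shuffle=True, random_state=state)
        for fold, (_, val) in enumerate(kf.split(np.arange(n))):
            assignment[rep, val] = fold
    return FoldPlan(k=k, replicates=replicates, seed=seed, ids=ids,
                    assignment=assignment)


@dataclass
class CVResult:
    per_fold: pd.DataFrame  # replicate, fold, n_val, r1_additive, r1_total
    predictions: pd.DataFrame  # per replicate x individual cross-validated values
    n_failed: int

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD of r1 across all replicate x fold cells."""
        out = {}
        for col in ("r1_additive", "r1_total"):
            vals = self.per_fold[col].dropna()
            out[col] = {"mean": vals.mean(), "sd": vals.std(ddof=1),
                        "n_cells": len(vals)}
        return pd.DataFrame(out).T


def cross_validate(
    y: pd.Series,
    spec,
    kernels: KernelSet,
    plan: FoldPlan,
    reestimate: bool = True,
    full_fit=None,
    **fit_kwargs,
) -> CVResult:
    """Run the cross-validation scheme for one model and one trait.

    Parameters
    ----------
    y : Series
        Adjusted phenotypes indexed by individual id (must match plan.ids).
    spec : str or ModelSpec
        Model to fit within each training fold.
    kernels : KernelSet
        Full-data relationship matrices covering the spec's kinds.
    plan : FoldPlan
        From :func:`make_folds`.
    reestimate : bool
        Re-estimate variance components within each training fold
        (default). If False, plug in the components of ``full_fit``.
    full_fit : MixedModelResults, optional
        Required when ``reestimate=False``.

    Notes
    -----
    Validation phenotypes never enter the training fit: the training
    model sees only the training rows of y and of each kernel, and
    validation predictions use only the (validation x training) kernel
    blocks.
    """
    spec = _as_spec(spec)
    ids = plan.ids
    y = y.reindex(ids).astype(float)
    if y.isna().any():
        raise ValueError("phenotype missing for some individuals in the plan")
    yv = y.to_numpy()
    rows = []
    n_failed = 0
    preds_a = np.full((plan.replicates, len(ids)), np.nan)
    preds_g = np.full((plan.replicates, len(ids)), np.nan)
    id_arr = np.array(ids)
    for rep in range(plan.replicates):
        for fold in range(plan.k):
            val = plan.fold_indices(rep, fold)
            tr = np.where(plan.assignment[rep] != fold)[0]
            tr_ids = list(id_arr[tr])
            sub = kernels.subset(tr_ids)
            model = KernelMixedModel(
                pd.Series(yv[tr], index=tr_ids), sub, spec=spec
            )
            if reestimate:
                try:
                    res = model.fit(**fit_kwargs)
                except ConvergenceError as e:
                    n_failed += 1
                    warnings.warn(
                        f"training fit failed (rep {rep}, fold {fold}): {e}",
                        stacklevel=2,
                    )
                    continue
            else:
                if full_fit is None:
                    raise ValueError("full_fit required when reestimate=False")
                res = model.results_at(full_fit.theta)
            eff = res.predict_effects_at(kernels, list(id_arr[val]))
            a_vp = eff["EBV"].to_numpy()
            g_vp = eff["EGV"].to_numpy()
            preds_a[rep, val] = a_vp
            preds_g[rep, val] = g_vp
            r1a = _safe_corr(a_vp, yv[val])
            r1g = _safe_corr(g_vp, yv[val]) if not spec.is_additive_only else r1a
            rows.append(
                {"replicate": rep, "fold": fold, "n_val": len(val),
                 "r1_additive": r1a, "r1_total": r1g}
            )
    per_fold = pd.DataFrame(rows)
    predictions = pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(plan.replicates), len(ids)),
            "individual": np.tile(id_arr, plan.replicates),
            "A_VP": preds_a.ravel(),
            "G_VP": preds_g.ravel(),
        }
    )
    return CVResult(per_fold=per_fold, predictions=predictions, n_failed=n_failed)


def _safe_corr(x, y) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def predictive_accuracy(r1: float, heritability: float, variant: str = "narrow") -> float:
    """Predictive accuracy r2 = r1 / sqrt(h2) (narrow) or r1 / sqrt(H2)
    (broad). ``variant`` is documentation only; pass the matching
    heritability."""
    if variant not in ("narrow", "broad"):
        raise ValueError("variant must be 'narrow' or 'broad'")
    if not heritability > 0:
        raise ValueError("heritability must be positive")
    return float(r1) / float(np.sqrt(heritability))


def spearman_concordance(predictions: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between models' rankings.

    ``predictions`` maps model label -> per-individual values (EBVs or
    EGVs on a shared index). Returns a symmetric rho table.
    """
    labels = list(predictions)
    if len(labels) < 2:
        raise ValueError("need at least two models to compare")
    idx = predictions[labels[0]].index
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            xa = predictions[a].reindex(idx).to_numpy()
            xb = predictions[b].reindex(idx).to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                raise ValueError("constant predictions cannot be ranked")
            rho = stats.spearmanr(xa, xb).statistic
            mat.loc[a, b] = mat.loc[b, a] = float(rho)
    return mat
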