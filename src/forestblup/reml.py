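"""Multi-kernel linear mixed models fitted by average-information REML.

The model for one adjusted trait y (one record per tree) is

    y = 1*beta + sum_k u_k + e,     u_k ~ N(0, sigma2_k K_k),
                                    e   ~ N(0, sigma2_e I),

where each K_k is a relationship matrix (pedigree- or marker-based) and
all random-effect incidence matrices are identity. Five named model
specifications are provided:

    PBLUP-A    : A
    PBLUP-AD   : A, D
    GBLUP-A    : G_A
    GBLUP-AD   : G_A, G_D
    GBLUP-ADE  : G_A, G_D, G_AA, G_AD, G_DD

Estimation is average-information (AI) REML with EM fallback steps when
an AI update leaves the parameter space. A variance component driven to
the zero boundary is fixed at 0, flagged, and excluded from further
updates — it is reported as null, and by default does not count as a
parameter in the AIC.

BLUPs, prediction error variances (PEV) and SEPs come from the inverse
coefficient matrix of the mixed-model equations at the converged
variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import KernelSet, RelationshipMatrix

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "KernelMixedModel",
    "MixedModelResults",
    "fit_reml",
    "goodness_of_fit",
    "model_comparison",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class ModelSpec:
    """Named list of (effect name, kernel kind) pairs; fixed part is the
    overall mean only."""

    label: str
    effects: tuple  # of (name, kind)

    @property
    def kinds(self) -> list[str]:
        return [k for _, k in self.effects]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.effects]

    @property
    def is_additive_only(self) -> bool:
        return len(self.effects) == 1


MODEL_SPECS = {
    "PBLUP-A": ModelSpec("PBLUP-A", (("a", "A"),)),
    "PBLUP-AD": ModelSpec("PBLUP-AD", (("a", "A"), ("d", "D"))),
    "GBLUP-A": ModelSpec("GBLUP-A", (("a", "G_A"),)),
    "GBLUP-AD": ModelSpec("GBLUP-AD", (("a", "G_A"), ("d", "G_D"))),
    "GBLUP-ADE": ModelSpec(
        "GBLUP-ADE",
        (("a", "G_A"), ("d", "G_D"), ("aa", "G_AA"), ("ad", "G_AD"), ("dd", "G_DD")),
    ),
}


def _as_spec(spec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    key = str(spec).upper().replace("_", "-")
    if key not in MODEL_SPECS:
        raise ValueError(f"unknown model {spec!r}; choose from {list(MODEL_SPECS)}")
    return MODEL_SPECS[key]


class KernelMixedModel:
    """Univariate mixed model with kernel-structured random effects.

    Parameters
    ----------
    endog : Series or array
        Adjusted phenotypes, one record per individual. If a Series, its
        index provides individual ids.
    kernels : KernelSet or mapping kind -> RelationshipMatrix/ndarray
        Must cover every kernel kind of ``spec``; kernels are aligned to
        the phenotyped ids.
    spec : str or ModelSpec
        One of the named models, e.g. ``"GBLUP-ADE"``.
    ids : list of str, optional
        Individual ids when ``endog`` is a bare array.
    intercept : bool
        Fit an overall mean (default). Disable only for zero-mean data.
    """

    def __init__(self, endog, kernels, spec="GBLUP-A", ids=None, intercept=True):
        self.spec = _as_spec(spec)
        if isinstance(endog, pd.Series):
            ids = [str(i) for i in endog.index] if ids is None else list(ids)
            y = endog.to_numpy(dtype=float)
        else:
            y = np.asarray(endog, dtype=float)
            ids = [str(i) for i in range(len(y))] if ids is None else list(ids)
        if y.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if np.isnan(y).any():
            raise ValueError("endog contains missing values")
        if np.ptp(y) == 0:
            raise ValueError("endog is constant; variance components undefined")
        self.y = y
        self.ids = ids
        self.n = len(y)
        self.intercept = intercept
        self.K: list[np.ndarray] = []
        for name, kind in self.spec.effects:
            k = kernels[kind]
            if isinstance(k, RelationshipMatrix):
                if k.ids != ids:
                    k = k.subset(ids)
                mat = k.values
            else:
                mat = np.asarray(k, dtype=float)
                if mat.shape != (self.n, self.n):
                    raise ValueError(f"kernel {kind} has wrong shape")
            self.K.append(mat)
            # near-identity kernel: sigma2_k confounded with sigma2_e
            off = mat - np.eye(self.n)
            if np.linalg.norm(off) / np.sqrt(self.n) < 1e-2:
                warnings.warn(
                    f"kernel {kind} is (near-)identity: its variance is not "
                    "identifiable separately from the residual variance",
                    stacklevel=2,
                )

    # -- restricted likelihood machinery ------------------------------

    def _vinv_proj(self, theta: np.ndarray):
        """Return (P, Py, logdetV, logdetXtVinvX) at variance vector theta.

        theta has one entry per genetic effect plus the residual (last).
        """
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, Kk in zip(theta[:-1], self.K):
            if t > 0:
                V += t * Kk
        L = np.linalg.cholesky(V)
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        Vinv = (Vinv + Vinv.T) / 2
        if self.intercept:
            v1 = Vinv.sum(axis=1)  # Vinv @ 1
            s = v1.sum()  # 1' Vinv 1
            P = Vinv - np.outer(v1, v1) / s
            logdetX = np.log(s)
        else:
            P = Vinv
            logdetX = 0.0
        return P, P @ self.y, logdetV, logdetX

    def loglike(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood at the variance vector ``theta``
        (genetic components in spec order, residual last)."""
        from scipy.linalg import cho_factor, cho_solve

        theta = np.asarray(theta, dtype=float)
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, Kk in zip(theta[:-1], self.K):
            if t > 0:
                V += t * Kk
        c, low = cho_factor(V, lower=True)
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        viy = cho_solve((c, low), self.y)
        if self.intercept:
            vi1 = cho_solve((c, low), np.ones(n))
            s = vi1.sum()
            yPy = self.y @ viy - (viy.sum()) ** 2 / s
            logdetX = np.log(s)
            p = 1
        else:
            yPy = self.y @ viy
            logdetX = 0.0
            p = 0
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX + yPy)

    def results_at(self, theta, aic_count: str = "free") -> "MixedModelResults":
        """Results object at FIXED variance components (no estimation).

        Useful for plugging in externally estimated components (e.g.
        cross-validation without per-fold re-estimation) or for evaluating
        predictions at known truth.
        """
        theta = np.asarray(theta, dtype=float).copy()
        if theta.shape != (len(self.K) + 1,):
            raise ValueError("theta must have one entry per effect + residual")
        P, Py, _, _ = self._vinv_proj(theta)
        Kall = self.K + [np.eye(self.n)]
        grad = np.array(
            [-0.5 * (np.sum(P * Kk) - Py @ Kk @ Py) for Kk in Kall]
        )
        ll = self.loglike(theta)
        free = theta > 0
        n_par = {"free": int(free.sum()), "all": len(theta)}[aic_count]
        return MixedModelResults(
            model=self, theta=theta, se=np.full_like(theta, np.nan),
            boundary=~free, loglik=float(ll), aic=float(-2 * ll + 2 * n_par),
            n_params=n_par, n_iter=0, converged=True, gradient=grad,
            _P=P, _Py=Py,
        )

    def fit(
        self,
        start=None,
        tol_logl: float = 1e-8,
        tol_param: float = 1e-6,
        max_iter: int = 500,
        boundary_tol: float = 1e-6,
        aic_count: str = "free",
        verbose: bool = False,
    ) -> "MixedModelResults":
        """Maximize the restricted likelihood by AI-REML.

        ``boundary_tol`` is relative to the phenotypic variance: a
        component falling below ``boundary_tol * var(y)`` is fixed at 0
        (components at that level are indistinguishable from zero and
        leave the average-information matrix near-singular).
        ``aic_count`` chooses the AIC parameter count: "free" counts only
        components not fixed at a boundary (residual included), "all"
        counts every component of the spec.
        """
        nk = len(self.K)
        vary = float(np.var(self.y, ddof=1))
        floor = boundary_tol * vary
        if start is None:
            theta = np.full(nk + 1, vary / (nk + 1))
        else:
            theta = np.asarray(start, dtype=float).copy()
        free = np.ones(nk + 1, dtype=bool)
        Kall = self.K + [np.eye(self.n)]
        ll = self.loglike(theta)
        trajectory = [ll]
        converged = False
        it = 0
        n_flat = 0  # consecutive iterations with stationary logL
        for it in range(1, max_iter + 1):
            P, Py, _, _ = self._vinv_proj(theta)
            KPy = [Kk @ Py for Kk in Kall]
            PKPy = [P @ v for v in KPy]
            grad = np.array(
                [
                    -0.5 * (np.sum(P * Kk) - Py @ Kk @ Py)
                    for Kk in Kall
                ]
            )
            fidx = np.where(free)[0]
            AI = 0.5 * np.array(
                [[KPy[i] @ PKPy[j] for j in fidx] for i in fidx]
            )
            # AI (Newton-type) proposal on the free coordinates
            try:
                delta = np.linalg.solve(
                    AI + 1e-12 * np.eye(len(fidx)) * np.trace(AI), grad[fidx]
                )
            except np.linalg.LinAlgError:
                delta = np.linalg.pinv(AI) @ grad[fidx]

            def _proposal(step: float) -> np.ndarray:
                cand = theta.copy()
                cand[fidx] = theta[fidx] + step * delta
                # a coordinate pushed out of the parameter space decays
                # geometrically toward the zero boundary instead
                neg = fidx[cand[fidx] <= 0]
                cand[neg] = theta[neg] * 0.1
                return cand

            accepted = False
            step = 1.0
            for _ in range(10):
                cand = _proposal(step)
                ll_cand = self.loglike(cand)
                if ll_cand >= ll - 1e-10:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # EM fallback: slower but stable update per component
                cand = theta.copy()
                for i in fidx:
                    upd = theta[i] + theta[i] ** 2 * (
                        Py @ Kall[i] @ Py - np.sum(P * Kall[i])
                    ) / self.n
                    cand[i] = upd if upd > 0 else theta[i] * 0.1
                ll_cand = self.loglike(cand)
            rel_change = np.max(
                np.abs(cand[fidx] - theta[fidx]) / np.maximum(theta[fidx], floor)
            ) if len(fidx) else 0.0
            dll = ll_cand - ll
            theta, ll = cand, ll_cand
            trajectory.append(ll)
            # boundary handling: fix tiny genetic components at exactly 0
            hit = free.copy()
            hit[-1] = False  # residual never fixed
            hit &= theta < floor
            if hit.any():
                theta[hit] = 0.0
                free[hit] = False
                ll = self.loglike(theta)
                trajectory.append(ll)
                continue
            if verbose:
                print(f"iter {it}: logL={ll:.8f} theta={theta}")
            if abs(dll) < tol_logl:
                n_flat += 1
            else:
                n_flat = 0
            # converged when logL and parameters are both stationary, or
            # when logL has been stationary repeatedly (flat ridge in a
            # weakly identified direction: parameters may drift there
            # without changing the restricted likelihood)
            if (abs(dll) < tol_logl and rel_change < tol_param) or n_flat >= 3:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"AI-REML did not converge in {max_iter} iterations "
                f"(last |dlogL|={abs(dll):.3e})",
                trajectory=trajectory,
            )
        # gradient and curvature at the optimum (free coordinates)
        P, Py, _, _ = self._vinv_proj(theta)
        grad = np.array(
            [-0.5 * (np.sum(P * Kk) - Py @ Kk @ Py) for Kk in Kall]
        )
        fidx = np.where(free)[0]
        KPy = [Kk @ Py for Kk in Kall]
        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array([[KPy[i] @ PKPy[j] for j in fidx] for i in fidx])
        se = np.zeros(nk + 1)
        try:
            cov = np.linalg.inv(AI)
            se[fidx] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            se[:] = np.nan
        n_par = {"free": int(free.sum()), "all": nk + 1}[aic_count]
        aic = -2.0 * ll + 2.0 * n_par
        return MixedModelResults(
            model=self,
            theta=theta,
            se=se,
            boundary=~free,
            loglik=float(ll),
            aic=float(aic),
            n_params=n_par,
            n_iter=it,
            converged=True,
            gradient=grad,
            _P=P,
            _Py=Py,
        )


@dataclass
class MixedModelResults:
    """REML estimates plus BLUP predictions for a KernelMixedModel."""

    model: KernelMixedModel
    theta: np.ndarray  # genetic components in spec order, residual last
    se: np.ndarray
    boundary: np.ndarray
    loglik: float
    aic: float
    n_params: int
    n_iter: int
    converged: bool
    gradient: np.ndarray
    _P: np.ndarray = field(repr=False, default=None)
    _Py: np.ndarray = field(repr=False, default=None)
    _pred: pd.DataFrame = field(repr=False, default=None)
    _beta: float = field(repr=False, default=None)
    _effects: pd.DataFrame = field(repr=False, default=None)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def varcomp(self) -> pd.Series:
        names = [f"sigma2_{n}" for n in self.spec.names] + ["sigma2_e"]
        return pd.Series(self.theta, index=names)

    @property
    def varcomp_se(self) -> pd.Series:
        names = [f"sigma2_{n}" for n in self.spec.names] + ["sigma2_e"]
        return pd.Series(self.se, index=names)

    @property
    def boundary_flags(self) -> pd.Series:
        names = [f"sigma2_{n}" for n in self.spec.names] + ["sigma2_e"]
        return pd.Series(self.boundary, index=names)

    @property
    def sigma2_p(self) -> float:
        """Phenotypic variance: sum of all fitted variance components."""
        return float(self.theta.sum())

    # -- BLUP / PEV via the mixed-model equations ----------------------

    def _solve_mme(self):
        if self._pred is not None:
            return
        m = self.model
        n = m.n
        names = self.spec.names
        active = [
            i for i in range(len(names)) if self.theta[i] > 0
        ]
        s2e = self.theta[-1]
        p = 1 if m.intercept else 0
        nb = p + len(active) * n
        C = np.zeros((nb, nb))
        rhs = np.zeros(nb)
        if p:
            C[0, 0] = n / s2e
            rhs[0] = m.y.sum() / s2e
        for bi, i in enumerate(active):
            r0 = p + bi * n
            Kinv = np.linalg.inv(m.K[i])
            Kinv = (Kinv + Kinv.T) / 2
            if p:
                C[0, r0:r0 + n] = 1.0 / s2e
                C[r0:r0 + n, 0] = 1.0 / s2e
            for bj, _ in enumerate(active):
                c0 = p + bj * n
                blk = np.eye(n) / s2e
                if bj == bi:
                    blk = blk + Kinv / self.theta[i]
                C[r0:r0 + n, c0:c0 + n] = blk
            rhs[r0:r0 + n] = m.y / s2e
        sol = np.linalg.solve(C, rhs)
        Cinv = np.linalg.inv(C)
        self._beta = float(sol[0]) if p else 0.0
        eff = {}
        pev_sum = np.zeros(n)
        for bi, i in enumerate(active):
            r0 = p + bi * n
            eff[names[i]] = sol[r0:r0 + n]
        for name in names:
            if name not in eff:
                eff[name] = np.zeros(n)
        self._effects = pd.DataFrame(eff, index=m.ids)
        # PEV: additive block diagonal; EGV PEV sums blocks + 2x cross blocks
        try:
            ia = active.index(0)  # position of the additive effect
            r0 = p + ia * n
            pev_a = np.diag(Cinv)[r0:r0 + n].copy()
        except ValueError:
            pev_a = np.zeros(n)
        for bi in range(len(active)):
            r0 = p + bi * n
            for bj in range(len(active)):
                c0 = p + bj * n
                pev_sum += np.diag(Cinv[r0:r0 + n, c0:c0 + n])
        ebv = self._effects[names[0]]
        egv = self._effects[names].sum(axis=1)
        self._pred = pd.DataFrame(
            {
                "EBV": ebv,
                "EGV": egv,
                "SEP_EBV": np.sqrt(np.maximum(pev_a, 0.0)),
                "SEP_EGV": np.sqrt(np.maximum(pev_sum, 0.0)),
            },
            index=m.ids,
        )

    @property
    def fe_mean(self) -> float:
        """Estimated overall mean (the only fixed effect)."""
        self._solve_mme()
        return self._beta

    @property
    def effects(self) -> pd.DataFrame:
        """BLUPs of each random genetic effect, one column per effect."""
        self._solve_mme()
        return self._effects

    def predict(self) -> pd.DataFrame:
        """Per-individual EBV, EGV and their SEPs (prediction standard
        errors from the inverse MME coefficient matrix)."""
        self._solve_mme()
        return self._pred

    def predict_effects_at(self, kernels, ids) -> pd.DataFrame:
        """Conditional-mean BLUPs for individuals OUTSIDE the fit.

        For each genetic effect k, the BLUP of u_k at new individuals is
        sigma2_k * K_k[new, train] @ P @ y_train, using the full-data
        relationship matrices restricted to the (new, train) block. Used
        for cross-validation: the new individuals' phenotypes never enter.
        """
        train = self.model.ids
        cols = {}
        for i, (name, kind) in enumerate(self.spec.effects):
            k = kernels[kind]
            kv = k.to_frame() if isinstance(k, RelationshipMatrix) else k
            block = kv.loc[list(ids), train].to_numpy()
            cols[name] = self.theta[i] * (block @ self._Py)
        eff = pd.DataFrame(cols, index=list(ids))
        eff["EBV"] = eff[self.spec.names[0]]
        eff["EGV"] = eff[list(self.spec.names)].sum(axis=1)
        return eff

    def summary(self) -> str:
        lines = [
            f"Kernel mixed model ({self.spec.label}), REML",
            f"n = {self.model.n}, iterations = {self.n_iter}, "
            f"logL = {self.loglik:.4f}, AIC = {self.aic:.2f}",
            "",
            f"{'component':>12} {'estimate':>12} {'SE':>10}  flag",
        ]
        for name, est, se, b in zip(
            self.varcomp.index, self.theta, self.se, self.boundary
        ):
            flag = "boundary" if b else ""
            lines.append(f"{name:>12} {est:>12.4f} {se:>10.4f}  {flag}")
        h2 = self.theta[0] / self.sigma2_p
        H2 = self.theta[:-1].sum() / self.sigma2_p
        lines += ["", f"h2 = {h2:.2f}   H2 = {H2:.2f}"]
        return "\n".join(lines)


def fit_reml(y, spec, kernels, tol: float = 1e-8, max_iter: int = 500, **kwargs):
    """Functional wrapper: build a KernelMixedModel and fit it."""
    return KernelMixedModel(y, kernels, spec=spec).fit(
        tol_logl=tol, max_iter=max_iter, **kwargs
    )


@dataclass
class GoodnessOfFit:
    r_additive: float
    r_total: float
    t_additive: float
    t_total: float
    p_additive: float
    p_total: float
    n: int


def _corr_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, np.inf * np.sign(r), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(t), float(p)


def goodness_of_fit(results: MixedModelResults, y=None) -> GoodnessOfFit:
    """Full-data goodness of fit: Pearson correlations of EBV and EGV with
    the adjusted phenotypes, with t-tests (t = r sqrt(n-2)/sqrt(1-r^2))."""
    yv = results.model.y if y is None else np.asarray(y, dtype=float)
    pred = results.predict()
    ra, ta, pa = _corr_t(pred["EBV"].to_numpy(), yv)
    rg, tg, pg = _corr_t(pred["EGV"].to_numpy(), yv)
    return GoodnessOfFit(ra, rg, ta, tg, pa, pg, len(yv))


def model_comparison(results_list) -> pd.DataFrame:
    """Rank fitted models by AIC (same trait, same individuals)."""
    rows = [
        {
            "model": r.spec.label,
            "logL": r.loglik,
            "n_params": r.n_params,
            "AIC": r.aic,
        }
        for r in results_list
    ]
    df = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df
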