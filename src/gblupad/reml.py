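"""REML fitting of multi-kernel linear mixed models for genomic prediction.

The model is

    y = X beta + sum_k Z u_k + e,   u_k ~ N(0, K_k sigma2_k),  e ~ N(0, I sigma2_e)

with y the stacked multi-year phenotype records, X the year incidence matrix
in cell-means form (one column per observed year, no intercept), Z the
record-to-individual incidence matrix shared by all genetic terms, and K_k a
relationship kernel (identity, additive G, or dominance D).  Repeated records
of an individual share one genetic effect per term; there is no separate
permanent-environment term.

Variance components maximize the restricted log-likelihood

    l(sigma2) = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (n - p) log 2 pi ],

with V = sum_k sigma2_k Z K_k Z' + sigma2_e I and P the REML projection
matrix.  The constant convention (including the (n - p) log 2 pi term and no
|X'X| adjustment) is fixed so likelihood differences, LRT statistics and
information criteria are convention-free.

Optimization is a bounded quasi-Newton (L-BFGS-B) on log-variances with an
analytic gradient, with a safeguarded fixed-point fallback.  Random-effect
solutions, prediction error variances (PEV) and fixed effects are recovered
at the optimum from the equivalent of Henderson's mixed-model equations:

    u_hat_k = sigma2_k K_k Z' P y
    PEV_k   = diag( sigma2_k K_k - sigma2_k^2 K_k Z' P Z K_k )

which avoids inverting possibly singular kernels.  For the additive +
dominance model the genetic prediction of an individual is g_hat + d_hat and
its PEV includes the error cross-covariance of the two terms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .kernels import RelationshipMatrix, identity_kernel

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_JITTER = 1e-6


class MixedModelDesign:
    """Design bundle: response, incidence matrices and kernel projections."""

    def __init__(
        self,
        y: np.ndarray,
        year: np.ndarray,
        individual_idx: np.ndarray,
        kernels: Sequence[RelationshipMatrix],
        records: pd.DataFrame,
        trait: str | None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.n_records = self.y.size
        self.trait = trait
        self.records = records
        self.kernels = list(kernels)
        if not self.kernels:
            raise ValueError("at least one random term is required")
        self.term_names = [k.kind for k in self.kernels]
        if len(set(self.term_names)) != len(self.term_names):
            raise ValueError("kernel kinds (term names) must be unique")
        self.individual_ids = self.kernels[0].individual_ids
        for k in self.kernels[1:]:
            if not np.array_equal(k.individual_ids, self.individual_ids):
                raise ValueError("all kernels must share the same individual labels")
        self.individual_idx = np.asarray(individual_idx, dtype=int)
        self.year_levels = np.array(sorted(set(year.tolist())))
        self.X = (year[:, None] == self.year_levels[None, :]).astype(float)
        self.rank_X = self.X.shape[1]
        # bookkeeping for the individual-level (Woodbury) likelihood: only
        # individuals with records enter V; the rest are predicted afterwards
        self.obs, self.rec_pos = np.unique(self.individual_idx, return_inverse=True)
        self.n_obs = self.obs.size
        self.counts = np.bincount(self.rec_pos, minlength=self.n_obs).astype(float)
        ix = np.ix_(self.obs, self.obs)
        self.K_obs = [k.values[ix] for k in self.kernels]
        self.n_terms = len(self.kernels)

    @property
    def n_individuals(self) -> int:
        return self.individual_ids.size

    def Z(self) -> np.ndarray:
        Z = np.zeros((self.n_records, self.n_individuals))
        Z[np.arange(self.n_records), self.individual_idx] = 1.0
        return Z


def build_design(
    phenotypes: pd.DataFrame,
    kernels: Sequence[RelationshipMatrix],
    trait: str | None = None,
) -> MixedModelDesign:
    """Assemble the design bundle from a long-format phenotype table.

    ``phenotypes`` needs columns ``genotype_id``, ``year`` and ``value``
    (plus ``trait`` when ``trait`` is given to select a subset).
    """
    df = phenotypes
    if trait is not None:
        if "trait" not in df.columns:
            raise ValueError("phenotype table has no 'trait' column")
        df = df[df["trait"] == trait]
    df = df.dropna(subset=["value"])
    if len(df) == 0:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    ids = kernels[0].individual_ids
    pos = {g: i for i, g in enumerate(ids)}
    missing = set(df["genotype_id"]) - set(pos)
    if missing:
        raise KeyError(
            f"{len(missing)} phenotyped individuals absent from kernel labels, "
            f"e.g. {sorted(missing)[:3]}"
        )
    idx = df["genotype_id"].map(pos).to_numpy(int)
    return MixedModelDesign(
        df["value"].to_numpy(float),
        df["year"].to_numpy(),
        idx,
        kernels,
        df.reset_index(drop=True),
        trait,
    )


def _chol(B: np.ndarray):
    try:
        return linalg.cho_factor(B, lower=True, check_finite=False)
    except linalg.LinAlgError:
        # one jitter retry inside the solver only; reported matrices untouched
        logger.warning("factorization failed; retrying with %.0e jitter", _JITTER)
        scale = max(np.mean(np.diag(B)), 1e-300)
        return linalg.cho_factor(
            B + _JITTER * scale * np.eye(B.shape[0]), lower=True, check_finite=False
        )


def _loglik_core(design: MixedModelDesign, comps: np.ndarray, need_aux: bool):
    """Restricted log-likelihood via an individual-level factorization.

    All genetic terms share the one-hot record-to-individual incidence Z and
    the residual is i.i.d., so V = sigma2_e I_N + Z M Z' with the n_obs x
    n_obs genetic covariance M = sum_k sigma2_k K_k.  Writing M = Aq Aq'
    (eigenfactorization) turns every solve with V into a solve with the
    n_obs x n_obs matrix B = sigma2_e I + Aq' Z'Z Aq, which keeps the cost
    at the number of phenotyped individuals instead of the record count.
    When ``need_aux`` is set, the pieces required for gradients, BLUPs and
    PEVs (Z'Py and Z'PZ on the observed block) are returned as well.
    """
    y, X = design.y, design.X
    N, p = design.n_records, design.rank_X
    pos, counts, n_o = design.rec_pos, design.counts, design.n_obs
    s_e = comps[-1]

    M = np.zeros((n_o, n_o))
    for s2, K in zip(comps[:-1], design.K_obs):
        M += s2 * K
    w, Q = np.linalg.eigh(M)
    Aq = Q * np.sqrt(np.clip(w, 0.0, None))
    UtU = (Aq * counts[:, None]).T @ Aq  # Aq' Z'Z Aq
    B = s_e * np.eye(n_o) + UtU
    cB = _chol(B)
    logdetV = (N - n_o) * np.log(s_e) + 2.0 * np.sum(np.log(np.diag(cB[0])))

    def vsolve(x):
        """V^{-1} x for x of shape (N,) or (N, q)."""
        Utx = Aq.T @ _gather(x, pos, n_o)
        corr = Aq @ linalg.cho_solve(cB, Utx, check_finite=False)
        return (x - corr[pos]) / s_e

    ViX = vsolve(X)
    Viy = vsolve(y)
    XtViX = X.T @ ViX
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise linalg.LinAlgError("X'V^-1 X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ beta
    ytPy = float(y @ Py)
    ll = -0.5 * (logdetV + logdetXtViX + ytPy + (N - p) * _LOG2PI)
    if not need_aux:
        return ll, beta, Py, None

    # Z'V^-1 Z = (R - R Aq B^-1 Aq' R) / sigma2_e, with R = diag(counts)
    RAq = Aq * counts[:, None]
    ZtViZ = (np.diag(counts) - RAq @ linalg.cho_solve(cB, RAq.T, check_finite=False)) / s_e
    F = _gather(ViX, pos, n_o)  # Z'V^-1 X
    H = F @ np.linalg.solve(XtViX, F.T)
    aux = {
        "ZtPZ": ZtViZ - H,  # Z'PZ on the observed block
        "ZtPy": _gather(Py, pos, n_o),
        "trVi": (N - np.trace(linalg.cho_solve(cB, UtU, check_finite=False))) / s_e,
        "ViX": ViX,
        "XtViX": XtViX,
    }
    return ll, beta, Py, aux


def _gather(x: np.ndarray, pos: np.ndarray, n_o: int) -> np.ndarray:
    """Z' x: sum records by observed-individual position."""
    if x.ndim == 1:
        return np.bincount(pos, weights=x, minlength=n_o)
    out = np.zeros((n_o, x.shape[1]))
    np.add.at(out, pos, x)
    return out


def restricted_loglik(design: MixedModelDesign, components) -> float:
    """Evaluate the restricted log-likelihood at the given variance components.

    ``components`` is ordered (genetic terms in design order, residual last).
    The additive constant is -(N - p)/2 log 2 pi with no |X'X| adjustment,
    so likelihood differences are convention-free.
    """
    comps = np.asarray(components, dtype=float)
    if comps.size != design.n_terms + 1:
        raise ValueError("component vector length must be n_terms + 1")
    if (comps[:-1] < 0).any() or comps[-1] <= 0:
        raise ValueError("genetic components must be >= 0 and residual > 0")
    return _loglik_core(design, comps, need_aux=False)[0]


def _nll_grad(design: MixedModelDesign, theta: np.ndarray):
    comps = np.exp(theta)
    ll, _, Py, aux = _loglik_core(design, comps, need_aux=True)
    ZtPZ, ZtPy = aux["ZtPZ"], aux["ZtPy"]
    grad = np.empty_like(comps)
    for k, K in enumerate(design.K_obs):
        grad[k] = -0.5 * (np.sum(ZtPZ * K) - ZtPy @ (K @ ZtPy))
    ViX = aux["ViX"]
    trP = aux["trVi"] - np.trace(np.linalg.solve(aux["XtViX"], ViX.T @ ViX))
    grad[-1] = -0.5 * (trP - Py @ Py)
    # chain rule for theta = log sigma2
    return -ll, -(grad * comps)


@dataclass
class REMLResults:
    """Variance components, solutions and fit diagnostics of a REML fit."""

    model: "GBLUPModel"
    components: pd.Series  # sigma2 per term plus 'residual'
    loglik: float
    converged: bool
    n_iter: int
    boundary: pd.Series
    fe_params: pd.Series
    random_effects: pd.DataFrame  # individuals x terms
    pev: pd.DataFrame  # individuals x terms
    genetic_values: pd.Series  # sum of genetic terms per individual
    pev_genetic: pd.Series  # PEV of the summed genetic prediction
    message: str = ""

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_records(self) -> int:
        return self.model.design.n_records

    @property
    def rank_X(self) -> int:
        return self.model.design.rank_X

    @property
    def df_resid(self) -> int:
        return self.n_records - self.rank_X

    @property
    def k_fixed(self) -> int:
        """Number of estimated fixed-effect parameters (year levels)."""
        return self.rank_X

    # -- criteria ----------------------------------------------------------
    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k_fixed)

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.k_fixed, self.df_resid)

    @property
    def sigma2_g(self) -> float:
        """Total genetic variance of the model (sum of non-residual terms)."""
        return float(self.components.drop("residual").sum())

    @property
    def pev_mean(self) -> float:
        """Scalar PEV: mean over individuals of the genetic-term PEV."""
        return float(self.pev_genetic.mean())

    @property
    def accuracy(self) -> float:
        """Theoretical accuracy r = sqrt(1 - PEV / sigma2_g), clipped at 0."""
        from .parameters import accuracy

        return accuracy(self.pev_mean, self.sigma2_g)

    def summary(self) -> str:
        lines = [
            f"{self.model.label} REML fit" + (f" [{self.model.design.trait}]" if self.model.design.trait else ""),
            f"  records: {self.n_records}  individuals: {self.model.design.n_individuals}"
            f"  years: [{', '.join(str(y) for y in self.model.design.year_levels)}]",
            f"  converged: {self.converged}  iterations: {self.n_iter}",
            "  variance components:",
        ]
        for name, v in self.components.items():
            flag = "  (boundary)" if self.boundary.get(name, False) else ""
            lines.append(f"    sigma2[{name}] = {v:.6g}{flag}")
        lines += [
            f"  logLik = {self.loglik:.4f}   AIC = {self.aic:.4f}   BIC = {self.bic:.4f}",
            f"  mean PEV = {self.pev_mean:.6g}   accuracy r = {self.accuracy:.4f}",
            "  fixed effects (year means): "
            + ", ".join(f"{y}: {b:.4g}" for y, b in self.fe_params.items()),
        ]
        return "\n".join(lines)


class GBLUPModel:
    """Linear mixed model for genomic prediction, statsmodels-style.

    Build from a long-format phenotype table and one or more relationship
    kernels, then call :meth:`fit` to estimate variance components by REML.

    Examples
    --------
    >>> model = GBLUPModel.additive_dominance(phenotypes, G, D, trait="FWB")
    >>> res = model.fit()
    >>> res.components["additive"], res.loglik, res.aic
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        kernels: Sequence[RelationshipMatrix],
        trait: str | None = None,
    ) -> None:
        self.design = build_design(phenotypes, kernels, trait)
        self.kernels = self.design.kernels
        kinds = tuple(self.design.term_names)
        self.label = {
            ("identity",): "BLUP",
            ("additive",): "GBLUP-A",
            ("additive", "dominance"): "GBLUP-AD",
        }.get(kinds, "+".join(kinds))

    # -- constructors ------------------------------------------------------
    @classmethod
    def blup(cls, phenotypes, individual_ids, trait=None) -> "GBLUPModel":
        """No-pedigree BLUP: identity kinship among individuals."""
        return cls(phenotypes, [identity_kernel(individual_ids)], trait)

    @classmethod
    def additive(cls, phenotypes, G: RelationshipMatrix, trait=None) -> "GBLUPModel":
        return cls(phenotypes, [G], trait)

    @classmethod
    def additive_dominance(
        cls, phenotypes, G: RelationshipMatrix, D: RelationshipMatrix, trait=None
    ) -> "GBLUPModel":
        return cls(phenotypes, [G, D], trait)

    # -- likelihood --------------------------------------------------------
    def loglike(self, components) -> float:
        return restricted_loglik(self.design, components)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start: Sequence[float] | None = None,
        fixed_components: Sequence[float] | None = None,
        max_iter: int = 200,
    ) -> REMLResults:
        """Maximize the restricted likelihood over the non-negative orthant.

        ``start`` optionally seeds the optimizer; ``fixed_components`` skips
        optimization and computes solutions at the supplied values (used for
        oracle checks and no-refit cross-validation).
        """
        design = self.design
        n_terms = design.n_terms
        vy = float(np.var(design.y))
        if vy <= 0:
            raise ValueError("phenotype variance is zero; REML is degenerate")

        if fixed_components is not None:
            comps = np.asarray(fixed_components, dtype=float)
            ll = restricted_loglik(design, comps)
            return self._results(comps, ll, True, 0, np.zeros(n_terms + 1, bool), "fixed components")

        lo = 1e-8 * vy
        hi = 1e3 * vy
        bounds = [(np.log(lo), np.log(hi))] * (n_terms + 1)
        if start is None:
            start = np.full(n_terms + 1, vy / (n_terms + 1))
        theta0 = np.log(np.clip(np.asarray(start, float), lo, hi))

        res = optimize.minimize(
            lambda t: _nll_grad(design, t),
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-8},
        )
        comps = np.exp(res.x)
        converged, n_iter, message = bool(res.success), int(res.nit), str(res.message)
        if not converged:
            comps, extra = self._fixed_point_polish(comps, max_iter)
            n_iter += extra
            nll_new = _nll_grad(design, np.log(comps))[0]
            converged = nll_new <= res.fun + 1e-6
            message += " + fixed-point fallback"
            if not converged:
                logger.warning("REML did not converge: %s", message)
        ll = restricted_loglik(design, comps)
        boundary = comps <= 2.0 * lo
        if boundary.any():
            logger.info(
                "REML: components at the zero boundary: %s",
                [design.term_names[i] if i < n_terms else "residual" for i in np.where(boundary)[0]],
            )
        return self._results(comps, ll, converged, n_iter, boundary, message)

    def _fixed_point_polish(self, comps: np.ndarray, max_iter: int):
        """Safeguarded EM-style fixed-point iteration on sigma2_k.

        At a stationary point tr(P V_k) = y'P V_k P y for every term; the
        update multiplies each component by the square root of that ratio.
        """
        design = self.design
        it = 0
        for it in range(1, max_iter + 1):
            _, _, Py, aux = _loglik_core(design, comps, need_aux=True)
            ZtPZ, ZtPy = aux["ZtPZ"], aux["ZtPy"]
            new = comps.copy()
            for k, K in enumerate(design.K_obs):
                tr = np.sum(ZtPZ * K)
                quad = ZtPy @ (K @ ZtPy)
                if tr > 0 and quad > 0:
                    new[k] = comps[k] * np.sqrt(quad / tr)
            ViX = aux["ViX"]
            tr = aux["trVi"] - np.trace(np.linalg.solve(aux["XtViX"], ViX.T @ ViX))
            quad = Py @ Py
            new[-1] = comps[-1] * np.sqrt(quad / tr)
            if np.max(np.abs(new - comps) / (comps + 1e-12)) < 1e-8:
                comps = new
                break
            comps = new
        return comps, it

    # -- solutions ---------------------------------------------------------
    def _results(self, comps, ll, converged, n_iter, boundary, message) -> REMLResults:
        design = self.design
        _, beta, _Py, aux = _loglik_core(design, comps, need_aux=True)
        ids = design.individual_ids
        obs = design.obs
        terms = design.term_names
        ZtPy, ZtPZ = aux["ZtPy"], aux["ZtPZ"]

        u_hat = {}
        pev = {}
        n_ind = design.n_individuals
        M_cols = np.zeros((n_ind, design.n_obs))  # sum_k sigma2_k K_k[:, obs]
        M_diag = np.zeros(n_ind)
        for s2, K, name in zip(comps[:-1], design.kernels, terms):
            Kcols = s2 * K.values[:, obs]
            u_hat[name] = Kcols @ ZtPy
            C = Kcols @ ZtPZ
            pev[name] = s2 * np.diag(K.values) - np.einsum("ij,ij->i", C, Kcols)
            M_cols += Kcols
            M_diag += s2 * np.diag(K.values)
        Cs = M_cols @ ZtPZ
        pev_genetic = M_diag - np.einsum("ij,ij->i", Cs, M_cols)
        pev_genetic = np.maximum(pev_genetic, 0.0)

        random_effects = pd.DataFrame(u_hat, index=ids)
        genetic_values = random_effects.sum(axis=1)
        genetic_values.name = "genetic_value"
        comp_index = terms + ["residual"]
        return REMLResults(
            model=self,
            components=pd.Series(comps, index=comp_index, name="sigma2"),
            loglik=float(ll),
            converged=converged,
            n_iter=n_iter,
            boundary=pd.Series(boundary, index=comp_index),
            fe_params=pd.Series(beta, index=design.year_levels, name="year_mean"),
            random_effects=random_effects,
            pev=pd.DataFrame({k: np.maximum(v, 0.0) for k, v in pev.items()}, index=ids),
            genetic_values=genetic_values,
            pev_genetic=pd.Series(pev_genetic, index=ids, name="pev_genetic"),
            message=message,
        )


# -- information criteria and model comparison ------------------------------

def aic(loglik: float, k: int) -> float:
    """Akaike criterion 2k - 2 logLik, with k the fixed-effect parameter count."""
    return 2.0 * k - 2.0 * loglik


def bic(loglik: float, k: int, df_resid: int) -> float:
    """Bayesian criterion -2 logLik + k log(v), v the residual degrees of freedom."""
    return -2.0 * loglik + k * np.log(df_resid)


def information_criteria(fit: REMLResults) -> tuple[float, float]:
    return fit.aic, fit.bic


def lrt_dominance(fit_a: REMLResults, fit_ad: REMLResults) -> tuple[float, float]:
    """Likelihood-ratio test for the dominance variance component.

    The statistic 2(LL_AD - LL_A) is clipped at zero; because sigma2_d sits
    on the boundary of its parameter space under the null, the p-value uses
    the 1/2 chi2_0 + 1/2 chi2_1 mixture (p = 0.5 at statistic 0).
    """
    da, dad = fit_a.model.design, fit_ad.model.design
    if not set(da.term_names) < set(dad.term_names):
        raise ValueError("fits are not nested: AD terms must strictly contain A terms")
    if da.n_records != dad.n_records or not np.allclose(da.y, dad.y):
        raise ValueError("fits are not on the same data")
    stat = max(0.0, 2.0 * (fit_ad.loglik - fit_a.loglik))
    p = 0.5 * stats.chi2.sf(stat, df=1) if stat > 0 else 0.5
    return stat, float(p)


def fit_dominance_pair(
    phenotypes: pd.DataFrame,
    G: RelationshipMatrix,
    D: RelationshipMatrix,
    trait: str | None = None,
    max_iter: int = 200,
) -> tuple[REMLResults, REMLResults]:
    """Fit GBLUP-A and GBLUP-AD on the same records.

    The AD model is started both from the default point and warm-started
    from the A-model optimum (with a small dominance component); the start
    with the higher restricted likelihood wins.  This keeps the nested pair
    well-ordered (LL_AD >= LL_A) for likelihood-ratio testing.
    """
    res_a = GBLUPModel.additive(phenotypes, G, trait).fit(max_iter=max_iter)
    model_ad = GBLUPModel.additive_dominance(phenotypes, G, D, trait)
    vy = float(np.var(model_ad.design.y))
    warm = [
        float(res_a.components["additive"]),
        0.05 * vy,
        float(res_a.components["residual"]),
    ]
    cand = [model_ad.fit(max_iter=max_iter), model_ad.fit(start=warm, max_iter=max_iter)]
    res_ad = max(cand, key=lambda r: r.loglik)
    return res_a, res_ad
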