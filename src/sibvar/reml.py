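"""Profiled REML for the sibling variance-components model.

Model: ``y = X beta + a + c + e`` with ``Cov(a) = sigma2_A K``,
``Cov(c) = sigma2_C H``, ``Cov(e) = sigma2_E I``; y is the ln-transformed
(age-corrected) BMI.  The restricted log-likelihood

    l_R(sigma2) = -1/2 [ (n-p) log 2pi + log|Sigma| + log|X' Sigma^-1 X|
                         + y' P y ]

with ``P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1`` is
maximized in the variance ratios ``gamma_k = sigma2_k / sigma2_E`` with
sigma2_E profiled out in closed form:  writing
``Sigma = sigma2_E (I + sum_k gamma_k M_k)``, the inner maximizer is
``sigma2_E(gamma) = y' P0 y / (n - p)`` on the unit scale.

The union of the component matrices' sparsity patterns splits the cohort
into small family blocks; all block operations are batched by block size,
which keeps a single fit at a few milliseconds and makes the 999-replicate
permutation test cheap.  Gradients of the profiled criterion are analytic;
the covariance of the variance-component estimates comes from the observed
information of the unprofiled criterion at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .covariance import LabeledMatrix

__all__ = [
    "VarianceComponentsREML",
    "VarCompFit",
    "FitComparison",
    "reml_fit",
    "likelihood_ratio_test",
    "aic_model_selection",
    "back_transform_effects",
    "build_design",
    "FIXED_TERMS",
]

_LOG2PI = math.log(2.0 * math.pi)

#: Candidate fixed-effect terms in canonical order (intercept implicit).
FIXED_TERMS = (
    "sex",
    "race3",
    "ethnicity",
    "home_type",
    "reared_by_bioparent",
    "home_type:reared_by_bioparent",
)


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    records: pd.DataFrame, terms: Sequence[str] = FIXED_TERMS
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix (no intercept column) for the terms.

    Reference levels: female sex, Caucasian race, non-Hispanic ethnicity,
    adoptive home, not reared by a biological parent.  Columns constant in
    the data (an absent factor level) are dropped.
    """
    n = len(records)
    cols: list[np.ndarray] = []
    names: list[str] = []

    def add(name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if np.ptp(values) > 0:
            cols.append(values)
            names.append(name)

    cache: dict[str, np.ndarray] = {}

    def main_effect(term: str) -> None:
        if term == "sex":
            add("sex[male]", (records["sex"].astype(str) == "male").to_numpy())
        elif term == "race3":
            r = records["race3"].astype(str)
            add("race3[AfricanAmerican]", (r == "AfricanAmerican").to_numpy())
            add("race3[Other]", (r == "Other").to_numpy())
        elif term == "ethnicity":
            add(
                "ethnicity[Hispanic]",
                (records["ethnicity"].astype(str) == "Hispanic").to_numpy(),
            )
        elif term == "home_type":
            v = (records["home_type"].astype(str) == "birth").to_numpy()
            cache["home_type"] = v.astype(float)
            add("home_type[birth]", v)
        elif term == "reared_by_bioparent":
            v = records["reared_by_bioparent"].astype(bool).to_numpy()
            cache["reared_by_bioparent"] = v.astype(float)
            add("reared_by_bioparent[True]", v)
        else:
            raise ValueError(f"unknown fixed-effect term {term!r}")

    for term in terms:
        if ":" in term:
            continue
        main_effect(term)
    for term in terms:
        if ":" not in term:
            continue
        a, b = term.split(":")
        for t in (a, b):
            if t not in cache:
                # marginality: interaction only meaningful with both mains
                raise ValueError(f"interaction {term!r} requires main {t!r}")
        add(
            "home_type[birth]:reared_by_bioparent[True]",
            cache[a] * cache[b],
        )
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


# ---------------------------------------------------------------------------
# block-wise GLS kernel


class _BlockKernel:
    """Batched family-block computations for Sigma0 = I + sum_k gamma_k M_k.

    The union of the component matrices' nonzero patterns decomposes the
    cohort into independent family blocks; blocks are grouped by size so
    every linear-algebra step is one batched numpy call per group.  The
    block structure depends only on X and the matrices, so a kernel can be
    reused across outcome vectors (permutation refits) via :meth:`set_y`.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, mats: list[np.ndarray]):
        n = len(y)
        pattern = np.eye(n, dtype=bool)
        for M in mats:
            pattern |= M != 0
        _, labels = connected_components(csr_matrix(pattern), directed=False)
        order = np.argsort(labels, kind="stable")
        bounds = np.flatnonzero(np.diff(labels[order])) + 1
        blocks = np.split(order, bounds)
        sizes = np.array([len(b) for b in blocks])
        self.groups = []
        for s in np.unique(sizes):
            idx = np.array([b for b, sz in zip(blocks, sizes) if sz == s])
            self.groups.append(
                {
                    "idx": idx,
                    # (k, nb, s, s): all component blocks stacked
                    "M": np.stack(
                        [M[idx[:, :, None], idx[:, None, :]] for M in mats]
                    )
                    if mats
                    else np.empty((0, len(idx), s, s)),
                    "X": X[idx],  # (nb, s, p)
                    "y": y[idx],  # (nb, s)
                    "eye": np.eye(s),
                }
            )
        self.n, self.p = n, X.shape[1]
        self.k = len(mats)

    def set_y(self, y: np.ndarray) -> None:
        for g in self.groups:
            g["y"] = y[g["idx"]]

    def core(self, gamma: np.ndarray, want_cache: bool = False):
        """logdet Sigma0, X'Si0X, X'Si0y, y'Si0y (+ per-group caches)."""
        p = self.p
        logdet0 = 0.0
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        caches = []
        for g in self.groups:
            V = g["eye"] + np.einsum("k,kbst->bst", gamma, g["M"])
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                raise np.linalg.LinAlgError("unit-scale covariance not PD")
            logdet0 += float(ld.sum())
            Vinv = np.linalg.inv(V)
            Xy = np.concatenate([g["X"], g["y"][:, :, None]], axis=2)
            ViXy = np.einsum("bst,btq->bsq", Vinv, Xy)
            G = np.einsum("bsp,bsq->pq", Xy, ViXy)  # [[X'ViX, X'Viy], ...]
            XtViX += G[:p, :p]
            XtViy += G[:p, p]
            ytViy += float(G[p, p])
            if want_cache:
                caches.append((Vinv, ViXy))
        return logdet0, XtViX, XtViy, ytViy, caches


class _ProfiledObjective:
    """Negative profiled (restricted or full ML) log-likelihood + gradient.

    REML profiles sigma2_E on n - p degrees of freedom and carries the
    log|X' Sigma0^-1 X| term; ML profiles both beta (by GLS) and sigma2_E
    on n degrees of freedom.
    """

    def __init__(self, kernel: _BlockKernel, ml: bool = False):
        self.kernel = kernel
        self.ml = ml

    def __call__(self, gamma: np.ndarray):
        ker = self.kernel
        n, p, k = ker.n, ker.p, ker.k
        df = n if self.ml else n - p
        logdet0, XtViX, XtViy, ytViy, caches = ker.core(gamma, want_cache=True)
        sign, ld_xtx = np.linalg.slogdet(XtViX)
        if p and sign <= 0:
            return np.inf, np.full(k, np.nan)
        if p == 0 or self.ml:
            ld_xtx = 0.0
        coef = np.linalg.solve(XtViX, XtViy) if p else np.empty(0)
        yPy = ytViy - float(XtViy @ coef)
        if yPy <= 0:
            return np.inf, np.full(k, np.nan)
        sigma2e = yPy / df
        value = -0.5 * (
            df * (_LOG2PI + 1.0) + df * math.log(sigma2e) + logdet0 + ld_xtx
        )
        W = np.linalg.inv(XtViX) if p else np.empty((0, 0))
        grad = np.zeros(k)
        coef1 = np.append(-coef, 1.0)  # u = Vi(y - X coef) = ViXy @ [-coef, 1]
        for g, (Vinv, ViXy) in zip(ker.groups, caches):
            u = ViXy @ coef1  # (nb, s): the P0 y block
            ViX = ViXy[:, :, :p]
            # d(yPy)/dgamma_j = -y'P0 Mj P0 y, and df / yPy = 1/sigma2e
            tr1 = np.einsum("bst,kbts->k", Vinv, g["M"])
            if self.ml:
                tr2 = 0.0
            else:
                tr2 = np.einsum(
                    "bsp,kbst,btq,qp->k", ViX, g["M"], ViX, W, optimize=True
                )
            quad = np.einsum("bs,kbst,bt->k", u, g["M"], u)
            grad += -0.5 * (tr1 - tr2 - quad / sigma2e)
        return -value, -grad


# ---------------------------------------------------------------------------
# estimator


class VarianceComponentsREML(BaseEstimator):
    """Gaussian variance-components regression fitted by profiled REML.

    Decomposes the outcome covariance as
    ``sigma2_A K + sigma2_C H + sigma2_E I`` (any ordered subset of
    structured components; the identity term is always present) and
    estimates fixed effects by GLS at the REML variances.

    Parameters
    ----------
    component_names : names of the structured components, matched
        positionally with the matrices passed to :meth:`fit`.
    fit_intercept : prepend an all-ones column to the design.
    n_starts : L-BFGS-B restarts on a coarse ratio ladder.
    gamma_max : upper box bound on each variance ratio.
    boundary_tol : ratios below this are snapped to an exact zero and
        flagged as boundary estimates.
    max_iter : iteration cap per optimizer start.
    compute_information : compute the observed-information covariance of
        the variance components after fitting (skippable for speed in
        permutation loops).
    method : ``"reml"`` (default) or ``"ml"``.  REML is used for all
        variance reporting; ML log-likelihoods are comparable across
        fixed-effect sets and back the AIC fixed-effect selection.

    Attributes
    ----------
    sigma2_ : estimated variances, ordered ``(*component_names, "E")``.
    beta_, beta_se_, beta_t_, beta_p_ : fixed-effect estimates (ln scale),
        standard errors from ``(X' Sigma^-1 X)^-1``, t ratios and normal
        two-sided p-values.
    restricted_loglik_ : maximized restricted log-likelihood.
    vc_covariance_ : covariance of ``sigma2_`` (zeros at boundary rows).
    boundary_ : per-component boundary flags (E included, always False
        unless the profile degenerates).
    converged_, n_iter_, n_, rank_
    """

    def __init__(
        self,
        component_names: Sequence[str] = ("A", "C"),
        fit_intercept: bool = True,
        n_starts: int = 3,
        gamma_max: float = 1e8,
        boundary_tol: float = 1e-7,
        max_iter: int = 500,
        compute_information: bool = True,
        method: str = "reml",
    ):
        self.component_names = component_names
        self.fit_intercept = fit_intercept
        self.n_starts = n_starts
        self.gamma_max = gamma_max
        self.boundary_tol = boundary_tol
        self.max_iter = max_iter
        self.compute_information = compute_information
        self.method = method

    # -- helpers ----------------------------------------------------------

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    @staticmethod
    def _matrices(component_matrices, n: int) -> list[np.ndarray]:
        mats = []
        for M in component_matrices or []:
            V = M.values if isinstance(M, LabeledMatrix) else np.asarray(M, float)
            if V.shape != (n, n):
                raise ValueError(
                    f"component matrix shape {V.shape} does not match n={n}"
                )
            mats.append(V)
        return mats

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, component_matrices=None):
        self._kernel = None
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite outcome values")
        Xd = self._design(X)
        n, p = Xd.shape
        if np.linalg.matrix_rank(Xd) < p:
            raise ValueError("rank-deficient fixed-effect design")
        mats = self._matrices(component_matrices, n)
        k = len(mats)
        names = tuple(self.component_names)[:k]
        if len(names) != k:
            raise ValueError("component_names shorter than matrix list")
        if n <= p + k:
            raise ValueError("too few observations for the model")
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        ml = self.method == "ml"
        df = n if ml else n - p

        if k == 0:
            beta, rss = _ols(Xd, y)
            sigma2e = rss / df
            self.gamma_ = np.empty(0)
            self.sigma2_ = np.array([sigma2e])
            ll = -0.5 * (
                df * (_LOG2PI + 1.0)
                + df * math.log(sigma2e)
                + (0.0 if ml else np.linalg.slogdet(Xd.T @ Xd)[1])
            )
            self._finalize(Xd, y, mats, names, beta, ll, True, 0)
            return self

        kernel = _BlockKernel(y, Xd, mats)
        self._kernel = kernel
        gamma, n_iter = self._optimize(_ProfiledObjective(kernel, ml=ml), k)

        logdet0, XtViX, XtViy, ytViy, _ = kernel.core(gamma)
        coef = np.linalg.solve(XtViX, XtViy) if p else np.empty(0)
        yPy = ytViy - float(XtViy @ coef)
        sigma2e = yPy / df
        self.gamma_ = gamma
        self.sigma2_ = np.append(gamma * sigma2e, sigma2e)
        ll = -0.5 * (
            df * (_LOG2PI + 1.0)
            + df * math.log(sigma2e)
            + logdet0
            + (0.0 if ml else np.linalg.slogdet(XtViX)[1])
        )
        self._finalize(Xd, y, mats, names, coef, ll, bool(np.isfinite(ll)), n_iter)
        return self

    def _optimize(self, objective, k: int) -> tuple[np.ndarray, int]:
        """Multi-start bounded quasi-Newton with a Nelder-Mead fallback."""
        ladder = [0.2, 2.0, 20.0][: max(1, self.n_starts)]
        best = None
        n_iter = 0
        for start in ladder:
            res = optimize.minimize(
                objective,
                np.full(k, start),
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, self.gamma_max)] * k,
                options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-9},
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise RuntimeError(
                f"REML optimization failed to converge: {best.message}"
            )
        gamma = np.asarray(best.x, dtype=float)
        # boundary-aware polish: restart Nelder-Mead when L-BFGS-B ended
        # unhappy (tiny blocks can make the profiled surface kinky at 0)
        if not best.success:
            nm = optimize.minimize(
                lambda g: objective(g)[0],
                gamma,
                method="Nelder-Mead",
                bounds=[(0.0, self.gamma_max)] * k,
                options={"maxiter": 200 * k, "xatol": 1e-10, "fatol": 1e-12},
            )
            if nm.fun < best.fun:
                gamma = np.asarray(nm.x, dtype=float)
        gamma[gamma < self.boundary_tol] = 0.0
        return gamma, n_iter

    def refit_sigma2(self, y) -> np.ndarray:
        """Re-estimate the variances for a new outcome vector.

        Reuses the cached block structure (same design and component
        matrices), skipping information and fixed-effect bookkeeping —
        the workhorse of the permutation test.  Leaves the fitted
        attributes untouched except for the kernel's outcome buffer.
        """
        kernel = self._kernel
        y = np.asarray(y, dtype=float).ravel()
        kernel.set_y(y)
        k = kernel.k
        gamma, _ = self._optimize(
            _ProfiledObjective(kernel, ml=self.method == "ml"), k
        )
        _, XtViX, XtViy, ytViy, _ = kernel.core(gamma)
        coef = np.linalg.solve(XtViX, XtViy) if kernel.p else np.empty(0)
        yPy = ytViy - float(XtViy @ coef)
        df = kernel.n if self.method == "ml" else kernel.n - kernel.p
        sigma2e = yPy / df
        return np.append(gamma * sigma2e, sigma2e)

    def _finalize(self, Xd, y, mats, names, beta, loglik, converged, n_iter):
        n, p = Xd.shape
        k = len(mats)
        self.component_names_ = tuple(names) + ("E",)
        self.n_, self.rank_ = n, p
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.restricted_loglik_ = float(loglik)
        self._X, self._y, self._mats = Xd, y, mats
        sigma2e = self.sigma2_[-1]
        gamma = self.gamma_
        self.boundary_ = np.append(gamma == 0.0, sigma2e == 0.0)

        if k:
            kernel = getattr(self, "_kernel", None) or _BlockKernel(y, Xd, mats)
            _, XtViX, _, _, _ = kernel.core(gamma)
            cov_beta = np.linalg.inv(XtViX) * sigma2e
        else:
            cov_beta = np.linalg.inv(Xd.T @ Xd) * sigma2e
        self.beta_ = np.asarray(beta, dtype=float)
        self.beta_cov_ = cov_beta
        self.beta_se_ = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.beta_t_ = self.beta_ / self.beta_se_
        self.beta_p_ = 2.0 * stats.norm.sf(np.abs(self.beta_t_))

        if self.compute_information and self.method == "reml":
            self.vc_covariance_ = self._information_covariance()
        else:
            self.vc_covariance_ = None
        return self

    def _information_covariance(self) -> np.ndarray:
        """Inverse observed information at the optimum (dense, one-shot).

        Boundary components are excluded from the information matrix and
        reported with zero rows/columns, mirroring an SE of 0 at a variance
        pinned to 0.
        """
        X, y = self._X, self._y
        n = len(y)
        all_mats = list(self._mats) + [np.eye(n)]
        sigma2 = self.sigma2_
        free = np.flatnonzero(~self.boundary_)
        Sigma = sum(s * M for s, M in zip(sigma2, all_mats))
        Si = np.linalg.inv(Sigma)
        SiX = Si @ X
        W = np.linalg.inv(X.T @ SiX)
        P = Si - SiX @ W @ SiX.T
        Py = P @ y
        PM = [P @ all_mats[i] for i in free]
        v = [all_mats[i] @ Py for i in free]
        m = len(free)
        info = np.empty((m, m))
        for a in range(m):
            for b in range(a, m):
                quad = float(v[a] @ (P @ v[b]))
                tr = float(np.einsum("ij,ji->", PM[a], PM[b]))
                info[a, b] = info[b, a] = quad - 0.5 * tr
        # near a boundary the observed information can go indefinite; clip
        # its spectrum so the returned covariance is PSD
        w, Q = np.linalg.eigh((info + info.T) / 2.0)
        w_floor = max(np.abs(w).max() * 1e-10, 1e-300)
        cov_free = (Q / np.maximum(w, w_floor)) @ Q.T
        cov = np.zeros((len(sigma2), len(sigma2)))
        cov[np.ix_(free, free)] = cov_free
        return cov

    # -- post-fit API ------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        return self._design(X) @ self.beta_

    def residuals_(self) -> np.ndarray:
        return self._y - self._X @ self.beta_

    def profiled_restricted_loglik(self, gamma) -> float:
        """Profiled criterion at arbitrary non-negative variance ratios."""
        gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
        kernel = self._fresh_kernel()
        val, _ = _ProfiledObjective(kernel)(gamma)
        return -val

    def _fresh_kernel(self) -> _BlockKernel:
        kernel = getattr(self, "_kernel", None)
        if kernel is None:
            kernel = _BlockKernel(self._y, self._X, self._mats)
            self._kernel = kernel
        else:
            kernel.set_y(self._y)  # undo any permutation refits
        return kernel

    def restricted_loglik(self, sigma2) -> float:
        """Unprofiled restricted log-likelihood at a full sigma2 vector."""
        sigma2 = np.asarray(sigma2, dtype=float)
        sigma2e = sigma2[-1]
        if sigma2e <= 0:
            return -np.inf
        gamma = sigma2[:-1] / sigma2e
        kernel = self._fresh_kernel()
        n, p = kernel.n, kernel.p
        logdet0, XtViX, XtViy, ytViy, _ = kernel.core(gamma)
        sign, ld_xtx = np.linalg.slogdet(XtViX) if p else (1.0, 0.0)
        coef = np.linalg.solve(XtViX, XtViy) if p else np.empty(0)
        yPy = ytViy - float(XtViy @ coef)
        df = n - p
        return -0.5 * (
            df * _LOG2PI
            + df * math.log(sigma2e)
            + logdet0
            + ld_xtx
            + yPy / sigma2e
        )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


# ---------------------------------------------------------------------------
# result containers and module-level operations


@dataclass
class VarCompFit:
    """REML solution bundle for one model subset."""

    sigma2: dict[str, float]
    beta: pd.DataFrame  # columns: term, estimate, se, t, p
    restricted_loglik: float
    vc_covariance: np.ndarray | None
    n: int
    rank: int
    converged: bool
    boundary: dict[str, bool]
    component_names: tuple[str, ...]
    outcome_transform: str = "ln"
    estimator: VarianceComponentsREML | None = field(default=None, repr=False)

    @property
    def total_variance(self) -> float:
        return float(sum(self.sigma2.values()))

    @property
    def n_parameters(self) -> int:
        """Fixed effects + fitted variance components (AIC bookkeeping)."""
        return self.rank + len(self.component_names)

    @property
    def aic(self) -> float:
        return -2.0 * self.restricted_loglik + 2.0 * self.n_parameters


@dataclass(frozen=True)
class FitComparison:
    """Likelihood-ratio comparison of two nested REML fits."""

    delta_loglik: float
    chi_square: float
    df: int
    p_value: float
    aic_full: float
    aic_reduced: float


def reml_fit(
    y,
    X,
    component_matrices=None,
    component_names: Sequence[str] = ("A", "C"),
    fixed_effect_names: Sequence[str] | None = None,
    outcome_transform: str = "ln",
    fit_intercept: bool = True,
    compute_information: bool = True,
    method: str = "reml",
) -> VarCompFit:
    """Fit the variance-components model and return a result bundle."""
    est = VarianceComponentsREML(
        component_names=component_names,
        fit_intercept=fit_intercept,
        compute_information=compute_information,
        method=method,
    ).fit(X, y, component_matrices=component_matrices)
    p = est.rank_
    if fixed_effect_names is None:
        base = [f"x{i}" for i in range(p - (1 if fit_intercept else 0))]
    else:
        base = list(fixed_effect_names)
    names = (["intercept"] if fit_intercept else []) + base
    beta = pd.DataFrame(
        {
            "term": names,
            "estimate": est.beta_,
            "se": est.beta_se_,
            "t": est.beta_t_,
            "p": est.beta_p_,
        }
    )
    return VarCompFit(
        sigma2=dict(zip(est.component_names_, est.sigma2_)),
        beta=beta,
        restricted_loglik=est.restricted_loglik_,
        vc_covariance=est.vc_covariance_,
        n=est.n_,
        rank=est.rank_,
        converged=est.converged_,
        boundary=dict(zip(est.component_names_, est.boundary_)),
        component_names=est.component_names_,
        outcome_transform=outcome_transform,
        estimator=est,
    )


def likelihood_ratio_test(
    fit_full: VarCompFit,
    fit_reduced: VarCompFit,
    boundary_mixture: bool = False,
) -> FitComparison:
    """Chi-square test of nested random-effect structures.

    ``chi2 = 2 (lR_full - lR_reduced)`` on ``df`` = difference in the number
    of structured variance components, with the upper chi-square tail.  With
    ``boundary_mixture=True`` the p-value uses the equal-weight
    chi2(df-1)/chi2(df) mixture appropriate when the reduced model pins
    variances to the boundary of the parameter space.
    """
    full_set = set(fit_full.component_names)
    red_set = set(fit_reduced.component_names)
    if not red_set <= full_set:
        raise ValueError("fits are not nested in their component sets")
    if fit_full.n != fit_reduced.n or fit_full.rank != fit_reduced.rank:
        raise ValueError(
            "REML log-likelihoods only comparable with identical fixed effects"
        )
    if fit_full.estimator is not None and fit_reduced.estimator is not None:
        if not np.array_equal(fit_full.estimator._X, fit_reduced.estimator._X):
            raise ValueError("fixed-effect designs differ between fits")
    df = len(full_set) - len(red_set)
    delta = fit_full.restricted_loglik - fit_reduced.restricted_loglik
    chi2 = max(0.0, 2.0 * delta)
    if df == 0:
        p = 1.0
    elif boundary_mixture:
        lower = 1.0 if df == 1 else stats.chi2.sf(chi2, df - 1)
        if df == 1 and chi2 > 0:
            lower = 0.0  # chi2_0 is a point mass at zero
        p = 0.5 * lower + 0.5 * stats.chi2.sf(chi2, df)
    else:
        p = float(stats.chi2.sf(chi2, df))
    return FitComparison(
        delta_loglik=float(delta),
        chi_square=float(chi2),
        df=df,
        p_value=float(p),
        aic_full=fit_full.aic,
        aic_reduced=fit_reduced.aic,
    )


def _term_subsets(terms: Sequence[str]) -> list[tuple[str, ...]]:
    """All fixed-term subsets respecting marginality of interactions."""
    mains = [t for t in terms if ":" not in t]
    inters = [t for t in terms if ":" in t]
    out = []
    for r in range(len(mains) + 1):
        for m in combinations(mains, r):
            ok_inters = [
                i for i in inters if all(part in m for part in i.split(":"))
            ]
            for r2 in range(len(ok_inters) + 1):
                for iv in combinations(ok_inters, r2):
                    out.append(tuple(m) + iv)
    return out


def aic_model_selection(
    records: pd.DataFrame,
    outcome_column: str,
    component_matrices,
    component_names: Sequence[str] = ("A", "C"),
    candidate_terms: Sequence[str] = FIXED_TERMS,
    criterion: str = "ml",
) -> pd.DataFrame:
    """Dredge-style AIC ranking over all fixed-effect subsets.

    Every admissible subset (intercept always included; an interaction only
    with both main effects) is fitted with the fixed random-effect
    structure; models are ranked by ``AIC = -2 l + 2k`` with ``k`` the
    count of fixed-effect columns plus variance parameters.  By default the
    candidates are refitted by full maximum likelihood for the ranking
    (restricted likelihoods are not comparable across fixed-effect sets);
    ``criterion="reml"`` ranks on the restricted likelihood instead.
    Failed candidates are kept in the table with ``failed=True``.
    """
    y = records[outcome_column].to_numpy(float)
    rows = []
    for terms in _term_subsets(candidate_terms):
        try:
            X, names = build_design(records, terms)
            fit = reml_fit(
                y,
                X,
                component_matrices,
                component_names=component_names,
                fixed_effect_names=names,
                compute_information=False,
                method="ml" if criterion == "ml" else "reml",
            )
            rows.append(
                {
                    "terms": terms,
                    "aic": fit.aic,
                    "loglik": fit.restricted_loglik,
                    "n_params": fit.n_parameters,
                    "failed": False,
                    "fit": fit,
                }
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            rows.append(
                {
                    "terms": terms,
                    "aic": np.inf,
                    "loglik": np.nan,
                    "n_params": np.nan,
                    "failed": True,
                    "fit": None,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable")
    return table.reset_index(drop=True)


def back_transform_effects(fit: VarCompFit) -> pd.DataFrame:
    """exp(beta) multiplicative effects on the median outcome scale.

    Only meaningful for an ln-transformed outcome; the multiplier for the
    intercept is the model's median BMI for the reference child.
    """
    if fit.outcome_transform != "ln":
        raise ValueError(
            "back-transform requires an ln-transformed outcome, got "
            f"{fit.outcome_transform!r}"
        )
    out = fit.beta.copy()
    out["multiplier"] = np.exp(out["estimate"].to_numpy(float))
    return out
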