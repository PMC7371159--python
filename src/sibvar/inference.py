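"""Derived inference: h2/c2 ratios, permutation tests, FDR, ICCs, power.

Heritability h2 = V_A / V_p and the common-environment share c2 = V_C / V_p
(V_p = V_A + V_C + V_E) are reported with delta-method standard errors from
the REML information matrix and Wald 95% intervals (estimate +/- 1.96 se,
deliberately not truncated to [0, 1]).  Significance of each variance
component comes from a permutation test that shuffles the outcome across
individuals while holding K and H fixed; q-values are Benjamini-Hochberg
across the pooled family of fixed-effect and variance-component p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reml import (
    VarCompFit,
    build_design,
    likelihood_ratio_test,
    reml_fit,
)

__all__ = [
    "RatioEstimate",
    "variance_ratios",
    "permutation_test",
    "fdr_adjust",
    "icc_by_class",
    "within_family_variance",
    "levene_residual_compare",
    "welch_t_test",
    "pairwise_fixed_contrasts",
    "simulation_power",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96  # fixed Wald multiplier, matching the reported intervals

_RATIO_FOR_COMPONENT = {"A": "h2", "C": "c2", "E": "e2"}


@dataclass(frozen=True)
class RatioEstimate:
    """One variance proportion (h2, c2 or e2) with its uncertainty."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    perm_p: float | None = None
    q_value: float | None = None


def variance_ratios(fit: VarCompFit) -> dict[str, RatioEstimate]:
    """h2, c2, e2 with delta-method SEs and Wald 95% CIs.

    For ratio r_i = sigma2_i / V_p the gradient has entries
    ``(V_p - sigma2_i) / V_p**2`` at i and ``-sigma2_i / V_p**2`` elsewhere;
    se(r_i)^2 = g' Cov(sigma2) g.  A component pinned to the zero boundary
    is reported as exactly 0 with zero-width interval.
    """
    if not fit.converged:
        raise ValueError("variance ratios require a converged fit")
    comps = list(fit.component_names)
    sig = np.array([fit.sigma2[c] for c in comps])
    vp = float(sig.sum())
    if vp <= 0:
        raise ValueError("total variance must be positive")
    cov = fit.vc_covariance
    if cov is None:
        cov = np.zeros((len(comps), len(comps)))
    out: dict[str, RatioEstimate] = {}
    for i, comp in enumerate(comps):
        name = _RATIO_FOR_COMPONENT.get(comp, comp.lower() + "2")
        r = sig[i] / vp
        if fit.boundary.get(comp, False):
            out[name] = RatioEstimate(name, 0.0, 0.0, 0.0, 0.0)
            continue
        g = np.full(len(comps), -sig[i] / vp**2)
        g[i] = (vp - sig[i]) / vp**2
        se = float(np.sqrt(max(0.0, g @ cov @ g)))
        out[name] = RatioEstimate(
            name, float(r), se, float(r - Z_95 * se), float(r + Z_95 * se)
        )
    return out


def permutation_test(
    y,
    X,
    component_matrices,
    component_names=("A", "C"),
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    plus_one_correction: bool = False,
    max_failure_rate: float = 0.05,
    fit_intercept: bool = True,
) -> dict[str, object]:
    """Permutation null distribution for each variance component.

    The outcome is shuffled uniformly across individuals ``n_perm`` times
    with the component matrices fixed, the model refitted, and the p-value
    of component k taken as the proportion of permuted estimates at least
    as large as the observed one (optionally the (k+1)/(n+1) variant).  A
    permutation whose fit fails is retried once on a fresh shuffle; more
    than ``max_failure_rate`` failures aborts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = np.asarray(y, dtype=float)
    # the observed statistic and every permuted one must be the identical
    # function of the data, or the permutation null is biased: one shared
    # single-start estimator computes both, reusing the cached block
    # structure across refits
    from .reml import VarianceComponentsREML

    fast = VarianceComponentsREML(
        component_names=component_names,
        fit_intercept=fit_intercept,
        n_starts=1,
        compute_information=False,
    ).fit(X, y, component_matrices=component_matrices)
    comps = [c for c in fast.component_names_ if c != "E"]
    obs = fast.sigma2_[: len(comps)].copy()
    perm_sigma2 = np.empty((n_perm, len(comps)))
    failures = 0
    for b in range(n_perm):
        for attempt in range(2):
            yp = rng.permutation(y)
            try:
                perm_sigma2[b] = fast.refit_sigma2(yp)[: len(comps)]
                break
            except (RuntimeError, np.linalg.LinAlgError, ValueError):
                failures += 1
        else:
            perm_sigma2[b] = np.nan
    n_bad = int(np.isnan(perm_sigma2[:, 0]).sum())
    if failures > max_failure_rate * n_perm:
        raise RuntimeError(
            f"{failures} permutation fits failed out of {n_perm}"
        )
    if n_bad:
        logger.warning("dropped %d failed permutations", n_bad)
    valid = perm_sigma2[~np.isnan(perm_sigma2[:, 0])]
    counts = (valid >= obs[None, :]).sum(axis=0)
    denom = len(valid)
    if plus_one_correction:
        p = (counts + 1) / (denom + 1)
    else:
        p = counts / denom
    return {
        "perm_p": dict(zip(comps, p.astype(float))),
        "observed": dict(zip(comps, obs.astype(float))),
        "n_perm_used": denom,
        "n_failed": n_bad,
        "null_distribution": pd.DataFrame(valid, columns=comps),
    }


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, rank-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def icc_by_class(
    pairs: pd.DataFrame,
    outcome: pd.Series,
    by=("pair_class", "same_home", "age_composition"),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Double-entry intraclass correlations per pair-class cell.

    Each pair is entered in both member orders and the Pearson correlation
    of the doubled lists taken — the twin-literature estimator for
    interchangeable siblings, symmetric in member labels by construction.
    Significance is the one-way ANOVA F between/within pairs.  Cells with
    fewer than ``min_pairs`` pairs or degenerate variance are flagged
    undefined (NaN icc).
    """
    outcome = outcome.copy()
    outcome.index = outcome.index.astype(str)
    rows = []
    for key, cell in pairs.groupby(list(by), observed=True):
        a = outcome.loc[cell["id_a"].astype(str)].to_numpy(float)
        b = outcome.loc[cell["id_b"].astype(str)].to_numpy(float)
        n_pairs = len(cell)
        d = a - b
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec.update(
            n_pairs=n_pairs,
            mean_abs_diff=float(np.mean(np.abs(d))),
            diff_variance=float(np.var(d, ddof=1)) if n_pairs > 1 else np.nan,
        )
        x1 = np.concatenate([a, b])
        x2 = np.concatenate([b, a])
        if n_pairs < min_pairs or np.std(x1) == 0:
            rec.update(icc=np.nan, icc_p=np.nan)
        else:
            rec["icc"] = float(np.corrcoef(x1, x2)[0, 1])
            rec["icc_p"] = _pair_anova_p(a, b)
        rows.append(rec)
    return pd.DataFrame(rows)


def _pair_anova_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-way ANOVA F across pairs (2 members each), upper-tail p."""
    k = len(a)
    grand = np.mean(np.concatenate([a, b]))
    means = (a + b) / 2.0
    ss_between = 2.0 * np.sum((means - grand) ** 2)
    ss_within = np.sum((a - means) ** 2 + (b - means) ** 2)
    df_b, df_w = k - 1, k
    if ss_within == 0 or df_b == 0:
        return 0.0 if ss_between > 0 else np.nan
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(stats.f.sf(F, df_b, df_w))


def within_family_variance(pairs: pd.DataFrame, outcome: pd.Series) -> float:
    """Sample variance of per-pair outcome differences.

    Each pair enters once, signed by the fixed (id_a, id_b) order of the
    pair table; divisor n_pairs - 1.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    outcome = outcome.copy()
    outcome.index = outcome.index.astype(str)
    d = (
        outcome.loc[pairs["id_a"].astype(str)].to_numpy(float)
        - outcome.loc[pairs["id_b"].astype(str)].to_numpy(float)
    )
    return float(np.var(d, ddof=1))


def levene_residual_compare(
    residuals_a,
    residuals_b,
    center: str = "median",
    overlap: int = 0,
) -> tuple[float, float]:
    """Brown-Forsythe comparison of two residual groups.

    Used to judge whether a single-component model explains similar
    variance shares in two age-group subsets: equal residual spread means
    no detectable difference.  ``center="mean"`` gives classic Levene.
    """
    if overlap > 0:
        logger.warning(
            "residual groups share %d individuals; test treated as "
            "approximate",
            overlap,
        )
    stat, p = stats.levene(
        np.asarray(residuals_a, float),
        np.asarray(residuals_b, float),
        center=center,
    )
    return float(stat), float(p)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite df: (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_fixed_contrasts(
    fit: VarCompFit, alpha: float = 0.017
) -> pd.DataFrame:
    """The three race contrasts with Bonferroni-threshold significance.

    Contrasts on the ln scale (Caucasian is the model's reference level),
    back-transformed to multiplicative BMI effects; flagged significant
    below the Bonferroni-corrected alpha of 0.05 / 3.
    """
    terms = list(fit.beta["term"])
    needed = ["race3[AfricanAmerican]", "race3[Other]"]
    idx = {t: i for i, t in enumerate(terms)}
    present = [t for t in needed if t in idx]
    if len(present) < 1 or (len(present) == 1 and len(needed) == 2):
        # fewer than 2 distinct non-reference levels in the fit
        raise ValueError("race3 contrasts need at least 2 race levels in X")
    beta = fit.beta["estimate"].to_numpy(float)
    cov = fit.estimator.beta_cov_
    p_dim = len(beta)
    contrasts = {
        "Caucasian_vs_AfricanAmerican": {"race3[AfricanAmerican]": 1.0},
        "Caucasian_vs_Other": {"race3[Other]": 1.0},
        "Other_vs_AfricanAmerican": {
            "race3[AfricanAmerican]": 1.0,
            "race3[Other]": -1.0,
        },
    }
    rows = []
    for name, weights in contrasts.items():
        if not all(t in idx for t in weights):
            continue
        c = np.zeros(p_dim)
        for t, w in weights.items():
            c[idx[t]] = w
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t_val = est / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(t_val)) if se > 0 else np.nan
        rows.append(
            {
                "contrast": name,
                "estimate_ln": est,
                "multiplier": float(np.exp(est)),
                "se": se,
                "t": t_val,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def simulation_power(
    config,
    alpha: float = 0.05,
    target_power: float = 0.8,
    n_grid=(0.5, 1.0, 1.5, 2.0),
    reps: int = 100,
    seed: int = 0,
    component: str = "A",
) -> dict[str, object]:
    """Monte-Carlo power for detecting a variance component.

    For each scale factor on the grid the study composition is scaled,
    ``reps`` cohorts simulated at the configured true variances, and the
    component tested by the likelihood-ratio test at level ``alpha``.
    Returns the empirical power curve, cohort sizes, and the smallest
    grid size reaching ``target_power`` (None if none does).  Power that
    decreases with n beyond Monte-Carlo noise triggers a warning.
    """
    from .simulate import generate_cohort, scale_composition

    if reps < 1:
        raise ValueError("reps must be positive")
    rng = np.random.default_rng(seed)
    comp_idx = {"A": 0, "C": 1}[component]
    curve = []
    for factor in n_grid:
        cfg = scale_composition(config, factor)
        hits = 0
        n_children = None
        for _ in range(reps):
            cfg_r = cfg.with_seed(int(rng.integers(2**31 - 1)))
            cohort = generate_cohort(cfg_r)
            y = np.log(cohort.table["bmi"].to_numpy(float))
            X, names = build_design(cohort.table, ("home_type",))
            mats = [cohort.K.values, cohort.H.values]
            full = reml_fit(
                y, X, mats, ("A", "C"), compute_information=False
            )
            reduced = reml_fit(
                y,
                X,
                [mats[1 - comp_idx]],
                (("C",) if component == "A" else ("A",)),
                compute_information=False,
            )
            lrt = likelihood_ratio_test(full, reduced)
            hits += lrt.p_value < alpha
            n_children = full.n
        curve.append(
            {"scale": factor, "n_children": n_children, "power": hits / reps}
        )
    power = np.array([c["power"] for c in curve])
    mc_se = np.sqrt(np.maximum(power * (1 - power), 1e-12) / reps)
    drops = np.diff(power) < -2 * (mc_se[:-1] + mc_se[1:])
    if np.any(drops):
        logger.warning("power curve decreases with n beyond MC noise")
    required = next(
        (c["n_children"] for c in curve if c["power"] >= target_power), None
    )
    return {
        "curve": pd.DataFrame(curve),
        "required_n": required,
        "alpha": alpha,
        "target_power": target_power,
    }
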