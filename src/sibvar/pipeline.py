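"""End-to-end analysis: prepare -> matrices -> three subset models -> report.

Mirrors the study workflow: cohort preparation and exclusions, sibling-pair
enumeration, separate variance-partitioning models for middle-childhood,
adolescent and cross-age sibling pairs (each with AIC fixed-effect
selection, likelihood-ratio structure checks and permutation tests), pooled
FDR correction, descriptive statistics, intraclass correlations and
within-family variances.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    build_model_subsets,
    enumerate_pairs,
    prepare_cohort,
)
from .covariance import (
    LabeledMatrix,
    read_matrix_csv,
    subset_matrix,
)
from .inference import (
    fdr_adjust,
    icc_by_class,
    levene_residual_compare,
    pairwise_fixed_contrasts,
    permutation_test,
    variance_ratios,
    welch_t_test,
    within_family_variance,
)
from .reml import (
    FIXED_TERMS,
    aic_model_selection,
    build_design,
    likelihood_ratio_test,
    reml_fit,
)

__all__ = ["RunConfig", "run_full_analysis", "analyze_cohort", "describe_cohort"]

logger = logging.getLogger(__name__)

SUBSET_NAMES = ("middle", "adolescent", "cross")


@dataclass(frozen=True)
class RunConfig:
    """File-level configuration for a full pipeline run."""

    cohort_path: str
    kinship_path: str
    home_path: str | None = None
    lms_path: str | None = None
    outcome: str = "ln_bmi"
    permutations: int = 999
    seed: int = 0
    fdr_policy: str = "pooled"  # or "per_model"
    candidate_terms: tuple[str, ...] = FIXED_TERMS
    subset: str = "all"
    out_dir: str | None = None

    def __post_init__(self):
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")
        if self.fdr_policy not in ("pooled", "per_model"):
            raise ValueError("fdr_policy must be 'pooled' or 'per_model'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "candidate_terms" in data:
            data["candidate_terms"] = tuple(data["candidate_terms"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        data["candidate_terms"] = list(data["candidate_terms"])
        Path(path).write_text(yaml.safe_dump(data))


def run_full_analysis(config: RunConfig) -> dict:
    """Load the input CSVs, run the analysis, optionally write reports."""
    raw = pd.read_csv(config.cohort_path)
    K = read_matrix_csv(config.kinship_path, "relatedness")
    H = (
        read_matrix_csv(config.home_path, "home_sharing")
        if config.home_path
        else None
    )
    lms = pd.read_csv(config.lms_path) if config.lms_path else None
    report = analyze_cohort(
        raw,
        K,
        H,
        lms_reference=lms,
        outcome=config.outcome,
        permutations=config.permutations,
        seed=config.seed,
        fdr_policy=config.fdr_policy,
        candidate_terms=config.candidate_terms,
        subset=config.subset,
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def analyze_cohort(
    raw: pd.DataFrame,
    K: LabeledMatrix,
    H: LabeledMatrix | None = None,
    lms_reference: pd.DataFrame | None = None,
    outcome: str = "ln_bmi",
    permutations: int = 999,
    seed: int = 0,
    fdr_policy: str = "pooled",
    candidate_terms=FIXED_TERMS,
    subset: str = "all",
) -> dict:
    """Full in-memory analysis; returns the study-report dictionary."""
    t0 = time.time()
    table_ids = set(raw["id"].astype(str))
    missing = sorted(table_ids - set(K.ids))
    if missing:
        raise ValueError(f"ids missing from the relatedness matrix: {missing}")
    if H is not None:
        missing = sorted(table_ids - set(H.ids))
        if missing:
            raise ValueError(f"ids missing from the home matrix: {missing}")

    prepared, exclusions = prepare_cohort(raw, lms_reference, outcome=outcome)
    ids = prepared["id"].tolist()
    K = subset_matrix(K, ids)
    if H is None:
        logger.warning(
            "no home-sharing matrix supplied: fitting an A+E model "
            "(common-environment component omitted)"
        )
        components, names = [K], ("A",)
        H_for_pairs = LabeledMatrix(
            ids=tuple(ids), values=np.eye(len(ids)), kind="home_sharing"
        )
    else:
        H = subset_matrix(H, ids)
        components, names = [K, H], ("A", "C")
        H_for_pairs = H

    pairs = enumerate_pairs(prepared, K, H_for_pairs)
    subsets = build_model_subsets(pairs, prepared)
    outcome_col = outcome
    outcome_series = prepared.set_index("id")[outcome_col]

    report: dict = {
        "meta": {
            "package_version": __version__,
            "seed": seed,
            "outcome": outcome,
            "permutations": permutations,
            "fdr_policy": fdr_policy,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "n_children": len(prepared),
            "n_households": int(prepared["household_id"].nunique()),
            "n_pairs": len(pairs),
            "n_excluded": len(exclusions),
            "zscore_source": prepared.attrs.get("zscore_source", "none"),
        },
        "pair_class_counts": pairs["pair_class"].value_counts().to_dict(),
        "descriptives": describe_cohort(prepared),
        "subsets": {},
    }

    comp_map = {
        "middle": "both_middle",
        "adolescent": "both_adolescent",
        "cross": "cross_age",
    }
    run_names = SUBSET_NAMES if subset == "all" else (subset,)
    rng = np.random.default_rng(seed)
    pooled_p: list[tuple[str, str, float]] = []  # (subset, label, p)
    single_A_residuals: dict[str, np.ndarray] = {}
    subset_members: dict[str, set] = {}

    for name in run_names:
        rec = subsets[name]
        sub_pairs = pairs.loc[pairs["age_composition"] == comp_map[name]]
        sub_ids = rec["id"].tolist()
        subset_members[name] = set(sub_ids)
        Ks = subset_matrix(K, sub_ids)
        mats = [Ks.values]
        if H is not None:
            mats.append(subset_matrix(H, sub_ids).values)
        y = rec[outcome_col].to_numpy(float)

        block: dict = {
            "n_children": len(rec),
            "n_pairs": len(sub_pairs),
        }
        try:
            dredge = aic_model_selection(
                rec, outcome_col, mats, names, candidate_terms
            )
            top = dredge.iloc[0]
            final_terms = tuple(top["terms"])
            block["dredge"] = [
                {
                    "terms": list(r["terms"]),
                    "aic": float(r["aic"]),
                    "failed": bool(r["failed"]),
                }
                for _, r in dredge.head(10).iterrows()
            ]
            block["final_terms"] = list(final_terms)

            X, xnames = build_design(rec, final_terms)
            fit = reml_fit(y, X, mats, names, fixed_effect_names=xnames)
            block["fit"] = fit
            beta = fit.beta.copy()
            beta["multiplier"] = np.exp(beta["estimate"])
            block["fixed_effects"] = beta
            block["variance_components"] = {
                c: {
                    "estimate": fit.sigma2[c],
                    "se": float(np.sqrt(max(fit.vc_covariance[i, i], 0.0)))
                    if fit.vc_covariance is not None
                    else np.nan,
                    "boundary": bool(fit.boundary[c]),
                }
                for i, c in enumerate(fit.component_names)
            }

            # likelihood-ratio structure checks against reduced structures
            lrts = {}
            none_fit = reml_fit(y, X, [], (), fixed_effect_names=xnames,
                                compute_information=False)
            lrts["AC_vs_none" if H is not None else "A_vs_none"] = (
                likelihood_ratio_test(fit, none_fit)
            )
            if H is not None:
                a_fit = reml_fit(y, X, [mats[0]], ("A",),
                                 fixed_effect_names=xnames,
                                 compute_information=False)
                c_fit = reml_fit(y, X, [mats[1]], ("C",),
                                 fixed_effect_names=xnames,
                                 compute_information=False)
                lrts["A_vs_none"] = likelihood_ratio_test(a_fit, none_fit)
                lrts["C_vs_none"] = likelihood_ratio_test(c_fit, none_fit)
                single_A_residuals[name] = a_fit.estimator.residuals_()
            else:
                single_A_residuals[name] = fit.estimator.residuals_()
            block["lrt"] = {
                k: dataclasses.asdict(v) for k, v in lrts.items()
            }

            ratios = variance_ratios(fit)
            if permutations > 0:
                perm = permutation_test(
                    y,
                    X,
                    mats,
                    names,
                    n_perm=permutations,
                    seed=np.random.default_rng(rng.integers(2**31 - 1)),
                )
                block["perm"] = {
                    "perm_p": perm["perm_p"],
                    "n_perm_used": perm["n_perm_used"],
                    "n_failed": perm["n_failed"],
                }
                for comp, pval in perm["perm_p"].items():
                    rname = {"A": "h2", "C": "c2"}.get(comp)
                    if rname in ratios:
                        ratios[rname] = dataclasses.replace(
                            ratios[rname], perm_p=float(pval)
                        )
                    pooled_p.append((name, f"vc:{comp}", float(pval)))
            block["ratios"] = {
                k: dataclasses.asdict(v) for k, v in ratios.items()
            }
            for _, r in beta.iterrows():
                pooled_p.append((name, f"fe:{r['term']}", float(r["p"])))

            if "race3[AfricanAmerican]" in xnames and "race3[Other]" in xnames:
                block["race_contrasts"] = pairwise_fixed_contrasts(fit)

            if len(sub_pairs) >= 2:
                block["within_family_variance"] = within_family_variance(
                    sub_pairs, outcome_series
                )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            logger.error("subset %s failed: %s", name, exc)
            block["failed"] = str(exc)
        report["subsets"][name] = block

    # pooled (or per-model) BH correction across fixed effects and
    # variance-component permutation p-values
    if pooled_p:
        if fdr_policy == "pooled":
            groups = {"all": pooled_p}
        else:
            groups = {}
            for s, label, p in pooled_p:
                groups.setdefault(s, []).append((s, label, p))
        qmap: dict[tuple[str, str], float] = {}
        for members in groups.values():
            qs = fdr_adjust([p for _, _, p in members])
            for (s, label, _), q in zip(members, qs):
                qmap[(s, label)] = float(q)
        for s in report["subsets"]:
            block = report["subsets"][s]
            if "fixed_effects" in block:
                block["fixed_effects"]["q"] = [
                    qmap.get((s, f"fe:{t}"), np.nan)
                    for t in block["fixed_effects"]["term"]
                ]
            if "ratios" in block:
                for comp, rname in (("A", "h2"), ("C", "c2")):
                    key = (s, f"vc:{comp}")
                    if key in qmap and rname in block["ratios"]:
                        block["ratios"][rname]["q_value"] = qmap[key]

    # residual-variance comparison between the two single-age models
    if {"middle", "adolescent"} <= set(single_A_residuals):
        overlap = len(
            subset_members.get("middle", set())
            & subset_members.get("adolescent", set())
        )
        stat, p = levene_residual_compare(
            single_A_residuals["middle"],
            single_A_residuals["adolescent"],
            overlap=overlap,
        )
        report["levene_middle_vs_adolescent"] = {"statistic": stat, "p": p}

    report["icc"] = icc_by_class(pairs, outcome_series)
    report["meta"]["runtime_s"] = round(time.time() - t0, 2)
    return report


def describe_cohort(prepared: pd.DataFrame) -> dict:
    """Descriptive block: BMI/age means, covariate frequencies, weight
    status, and the Welch home-type comparison of age-corrected BMI."""
    if prepared.empty:
        raise ValueError("prepared table is empty")

    def _summary(df: pd.DataFrame) -> dict:
        n = len(df)
        out = {
            "n": n,
            "mean_bmi": float(df["bmi"].mean()),
            "sd_bmi": float(df["bmi"].std(ddof=1)) if n > 1 else np.nan,
            "mean_age": float(df["age"].mean()),
            "sd_age": float(df["age"].std(ddof=1)) if n > 1 else np.nan,
            "pct_male": 100.0 * float((df["sex"] == "male").mean()),
            "pct_reared_by_bioparent": 100.0
            * float(df["reared_by_bioparent"].astype(bool).mean())
            if "reared_by_bioparent" in df
            else np.nan,
            "race3_pct": {
                k: 100.0 * v
                for k, v in df["race3"].value_counts(normalize=True).items()
            },
        }
        if "ethnicity" in df:
            out["pct_hispanic"] = 100.0 * float(
                (df["ethnicity"].astype(str) == "Hispanic").mean()
            )
        return out

    desc = {"overall": _summary(prepared)}
    for ht, grp in prepared.groupby("home_type"):
        desc[str(ht)] = _summary(grp)
    if "weight_status" in prepared:
        counts = prepared["weight_status"].value_counts().to_dict()
        desc["weight_status_counts"] = {
            k: int(counts.get(k, 0))
            for k in ("underweight", "normal", "overweight", "obese")
        }
        desc["obesity_prevalence_pct"] = 100.0 * float(
            (prepared["weight_status"] == "obese").mean()
        )
    groups = {
        str(ht): grp["bmi"].to_numpy(float)
        for ht, grp in prepared.groupby("home_type")
    }
    if {"adoptive", "birth"} <= set(groups):
        t, df_w, p = welch_t_test(groups["adoptive"], groups["birth"])
        desc["welch_home_type"] = {"t": t, "df": df_w, "p": p}
    return desc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"type": type(obj).__name__}
    return obj


def write_report(report: dict, out_dir) -> dict[str, Path]:
    """Machine-readable JSON (full precision) + human-readable text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"json": out / "report.json", "text": out / "report.txt"}
    slim = {k: v for k, v in report.items()}
    slim["subsets"] = {
        s: {k: v for k, v in b.items() if k != "fit"}
        for s, b in report["subsets"].items()
    }
    paths["json"].write_text(json.dumps(_jsonable(slim), indent=1))
    paths["text"].write_text(format_report(report))
    for s, b in report["subsets"].items():
        if "fixed_effects" in b:
            b["fixed_effects"].to_csv(
                out / f"fixed_effects_{s}.csv", index=False
            )
    if isinstance(report.get("icc"), pd.DataFrame):
        report["icc"].to_csv(out / "icc.csv", index=False)
    return paths


def format_report(report: dict) -> str:
    """Plain-text study report, rounded for reading."""
    lines = []
    meta = report["meta"]
    lines.append(
        f"sibvar {meta['package_version']} — seed {meta['seed']}, "
        f"{meta['n_children']} children, {meta['n_households']} households, "
        f"{meta['n_pairs']} sibling pairs"
    )
    counts = report.get("pair_class_counts", {})
    lines.append(
        "pairs by class: "
        + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
    )
    desc = report.get("descriptives", {})
    if "overall" in desc:
        o = desc["overall"]
        lines.append(
            f"overall BMI {o['mean_bmi']:.1f} ({o['sd_bmi']:.1f}), age "
            f"{o['mean_age']:.1f} ({o['sd_age']:.1f}), {o['pct_male']:.1f}% male"
        )
    if "obesity_prevalence_pct" in desc:
        lines.append(
            f"obesity prevalence {desc['obesity_prevalence_pct']:.1f}%"
        )
    if "welch_home_type" in desc:
        w = desc["welch_home_type"]
        lines.append(
            f"Welch home-type test: t={w['t']:.2f}, df={w['df']:.1f}, "
            f"p={w['p']:.3f}"
        )
    for s, b in report.get("subsets", {}).items():
        lines.append("")
        lines.append(
            f"[{s}] n={b.get('n_children')} children, "
            f"{b.get('n_pairs')} pairs"
        )
        if "failed" in b:
            lines.append(f"  FAILED: {b['failed']}")
            continue
        lines.append(f"  final fixed terms: {b.get('final_terms')}")
        vcs = b.get("variance_components", {})
        for c, v in vcs.items():
            lines.append(
                f"  V_{c} = {v['estimate']:.4f} (se {v['se']:.4f})"
                + (" [boundary]" if v["boundary"] else "")
            )
        for rname, r in b.get("ratios", {}).items():
            extra = ""
            if r.get("perm_p") is not None:
                extra += f", perm p={r['perm_p']:.3f}"
            if r.get("q_value") is not None:
                extra += f", q={r['q_value']:.3f}"
            lines.append(
                f"  {rname} = {r['estimate']:.2f} (se {r['se']:.2f}) "
                f"CI ({r['ci_low']:.2f}, {r['ci_high']:.2f}){extra}"
            )
        for lname, l in b.get("lrt", {}).items():
            lines.append(
                f"  LRT {lname}: chi2={l['chi_square']:.2f} df={l['df']} "
                f"p={l['p_value']:.3g}"
            )
        if "within_family_variance" in b:
            lines.append(
                f"  within-family variance = "
                f"{b['within_family_variance']:.3f}"
            )
    if "levene_middle_vs_adolescent" in report:
        l = report["levene_middle_vs_adolescent"]
        lines.append("")
        lines.append(
            f"Levene (middle vs adolescent single-A residuals): "
            f"stat={l['statistic']:.2f}, p={l['p']:.3f}"
        )
    return "\n".join(lines) + "\n"
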