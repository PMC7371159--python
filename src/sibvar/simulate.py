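"""Synthetic sibling-adoption cohorts with known ground truth.

The generator emulates the study design the package analyzes: households of
biological siblings reared together or apart and nonbiological siblings
reared together, with the outcome drawn from the generative model itself —
``y = X beta + L z`` where ``L`` is the Cholesky factor of
``sigma2_A K + sigma2_C H + sigma2_E I`` and z is iid standard normal.

The default ("study mimic") composition reproduces the printed design
margins exactly: 711 children in 414 households forming 579 sibling pairs
(12 MZ, 115 full/DZ, 192 half, 260 nonbiological), 500 children in adoptive
homes and 211 in birth homes.  Sibling age gaps are drawn at mean 3.56 y
(SD 2.35 y); covariate frequencies follow the study's descriptive table
(53.6% male, 58.8% Caucasian, 12.9% Hispanic, ...).  Default true variance
components are the middle-childhood estimates (0.025, 0.012, 0.003
ln-BMI units squared).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import (
    LabeledMatrix,
    build_home_matrix,
    build_relatedness_matrix,
    write_matrix_csv,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "study_mimic_config",
    "perturb_truth",
    "scale_composition",
    "write_cohort",
]

#: Family-unit templates: per-child household slot and home type, plus the
#: pedigree links among the unit's children.  ``homes`` indexes distinct
#: households within the unit; ``home_types`` is per household slot.
_TEMPLATES: dict[str, dict] = {
    "mz_together": dict(
        n=2, rels=[(0, 1, "MZ")], homes=[0, 0], home_types=["adoptive"]
    ),
    "full_together": dict(
        n=2, rels=[(0, 1, "full_or_DZ")], homes=[0, 0], home_types=["birth"]
    ),
    "full_apart": dict(
        n=2,
        rels=[(0, 1, "full_or_DZ")],
        homes=[0, 1],
        home_types=["adoptive", "birth"],
    ),
    # adopted-together full sibs plus their half sibling with the birth mother
    "trio_full_together_half_apart": dict(
        n=3,
        rels=[(0, 1, "full_or_DZ"), (0, 2, "half"), (1, 2, "half")],
        homes=[0, 0, 1],
        home_types=["adoptive", "birth"],
    ),
    "half_together_birth": dict(
        n=2, rels=[(0, 1, "half")], homes=[0, 0], home_types=["birth"]
    ),
    "half_together_adoptive": dict(
        n=2, rels=[(0, 1, "half")], homes=[0, 0], home_types=["adoptive"]
    ),
    "half_apart": dict(
        n=2,
        rels=[(0, 1, "half")],
        homes=[0, 1],
        home_types=["adoptive", "birth"],
    ),
    "unrelated_trio": dict(
        n=3, rels=[], homes=[0, 0, 0], home_types=["adoptive"]
    ),
    "unrelated_duo": dict(n=2, rels=[], homes=[0, 0], home_types=["adoptive"]),
}

#: Template counts solving the study margins exactly (see module docstring).
STUDY_COMPOSITION: dict[str, int] = {
    "mz_together": 12,
    "trio_full_together_half_apart": 64,
    "full_apart": 30,
    "full_together": 21,
    "half_together_birth": 18,
    "half_together_adoptive": 7,
    "half_apart": 39,
    "unrelated_trio": 85,
    "unrelated_duo": 5,
}

_DEFAULT_RACE_FREQS = {
    "Caucasian": 0.588,
    "Multiracial": 0.219,
    "African American": 0.179,
    "Native American": 0.005,
    "Asian": 0.004,
    "Native Hawaiian/Pacific Islander": 0.002,
    "Unknown": 0.003,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic sibling-adoption cohort."""

    composition: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_COMPOSITION)
    )
    true_sigma2: tuple[float, float, float] = (0.025, 0.012, 0.003)
    #: coefficients on the ln-BMI scale keyed by design column name;
    #: ``intercept`` is the reference child's median ln BMI.
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": float(np.log(18.4)),
            "home_type[birth]": float(np.log(1.05)),
            "race3[AfricanAmerican]": float(np.log(1.08)),
            "race3[Other]": float(np.log(1.07)),
        }
    )
    male_frequency: float = 0.536
    race_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RACE_FREQS)
    )
    hispanic_frequency: float = 0.129
    #: adoptive-home children reared by >= 1 biological parent (birth-home
    #: children always are)
    adoptive_reared_bio_frequency: float = 0.138
    age_min: float = 5.0
    age_max: float = 19.0
    age_gap_mean: float = 3.56
    age_gap_sd: float = 2.35
    #: cohort mean z against the growth reference, sets obesity prevalence
    zref_shift: float = 0.63
    seed: int = 0

    def __post_init__(self):
        sig = self.true_sigma2
        if any(s < 0 for s in sig) or sum(sig) <= 0:
            raise ValueError("true_sigma2 must be >= 0 with positive sum")
        unknown = set(self.composition) - set(_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return dataclasses.replace(self, seed=int(seed))


@dataclass
class SyntheticCohort:
    """Generated cohort table, component matrices and ground truth."""

    table: pd.DataFrame
    K: LabeledMatrix
    H: LabeledMatrix
    truth: dict


def study_mimic_config(seed: int = 0) -> SyntheticConfig:
    """Default configuration matching the study's printed design margins."""
    return SyntheticConfig(seed=seed)


def perturb_truth(
    config: SyntheticConfig, component: str, value: float
) -> SyntheticConfig:
    """Copy of the config with one true variance component replaced."""
    idx = {"A": 0, "C": 1, "E": 2}
    if component not in idx:
        raise ValueError("component must be one of A, C, E")
    if value < 0:
        raise ValueError("variance must be non-negative")
    sig = list(config.true_sigma2)
    sig[idx[component]] = float(value)
    if sum(sig) <= 0:
        raise ValueError("all-zero variance vector")
    return dataclasses.replace(config, true_sigma2=tuple(sig))


def scale_composition(
    config: SyntheticConfig, factor: float
) -> SyntheticConfig:
    """Scale every template count by ``factor`` (minimum 1 per template)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    comp = {
        name: max(1, int(round(count * factor)))
        for name, count in config.composition.items()
        if count > 0
    }
    return dataclasses.replace(config, composition=comp)


def _draw_ages(rng, n, cfg: SyntheticConfig) -> np.ndarray:
    """First child uniform on [age_min, age_max); siblings offset by the
    configured gap distribution, rejection-sampled into range."""
    ages = np.empty(n)
    ages[0] = rng.uniform(cfg.age_min, cfg.age_max)
    for i in range(1, n):
        for _ in range(50):
            gap = abs(rng.normal(cfg.age_gap_mean, cfg.age_gap_sd))
            a = ages[0] + rng.choice([-1.0, 1.0]) * gap
            if cfg.age_min <= a < cfg.age_max:
                ages[i] = a
                break
        else:
            ages[i] = float(np.clip(ages[0], cfg.age_min, cfg.age_max - 0.01))
    return ages


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Sample one cohort (table + K + H + ground truth) under the seed."""
    from .reml import build_design  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    rels: list[tuple[str, str, str]] = []
    households: dict[str, str] = {}
    child_i = 0
    hh_i = 0
    races = list(config.race_frequencies)
    race_p = np.array([config.race_frequencies[r] for r in races], float)
    race_p = race_p / race_p.sum()

    for name in sorted(config.composition):
        tpl = _TEMPLATES[name]
        for _ in range(config.composition[name]):
            hh_ids = []
            for ht in tpl["home_types"]:
                hh_i += 1
                hh_ids.append((f"H{hh_i:04d}", ht))
            ages = _draw_ages(rng, tpl["n"], config)
            unit_ids = []
            for c in range(tpl["n"]):
                child_i += 1
                cid = f"C{child_i:04d}"
                unit_ids.append(cid)
                hh_id, home_type = hh_ids[tpl["homes"][c]]
                households[cid] = hh_id
                if home_type == "birth":
                    reared = True
                else:
                    reared = bool(
                        rng.random() < config.adoptive_reared_bio_frequency
                    )
                rows.append(
                    {
                        "id": cid,
                        "household_id": hh_id,
                        # keep strictly inside [5, 19) after 2-dp rounding
                        "age": min(round(float(ages[c]), 2), 18.99),
                        "sex": "male"
                        if rng.random() < config.male_frequency
                        else "female",
                        "race": races[rng.choice(len(races), p=race_p)],
                        "ethnicity": "Hispanic"
                        if rng.random() < config.hispanic_frequency
                        else "non-Hispanic",
                        "home_type": home_type,
                        "reared_by_bioparent": reared,
                    }
                )
            for a, b, cls in tpl["rels"]:
                rels.append((unit_ids[a], unit_ids[b], cls))

    table = pd.DataFrame(rows)
    ids = table["id"].tolist()
    K = build_relatedness_matrix(rels, ids)
    H = build_home_matrix(households, ids)

    sA, sC, sE = config.true_sigma2
    Sigma = sA * K.values + sC * H.values + sE * np.eye(len(ids))
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance not positive definite; use sigma2_E > 0 (MZ pairs "
            "duplicate rows of K)"
        ) from exc

    from .cohort import recode_race

    table["race3"] = table["race"].map(recode_race)
    terms = []
    if any(k.startswith("race3") for k in config.beta):
        terms.append("race3")
    if "sex[male]" in config.beta:
        terms.append("sex")
    if "ethnicity[Hispanic]" in config.beta:
        terms.append("ethnicity")
    if "home_type[birth]" in config.beta:
        terms.append("home_type")
    if "reared_by_bioparent[True]" in config.beta:
        terms.append("reared_by_bioparent")
    X, names = build_design(table, tuple(terms))
    coef = np.array([config.beta.get(nm, 0.0) for nm in names])
    mu = config.beta.get("intercept", 0.0) + (X @ coef if len(names) else 0.0)
    z = rng.standard_normal(len(ids))
    y = mu + L @ z

    table["bmi"] = np.exp(y)
    # z-score against a synthetic growth reference: the cohort mean sits
    # zref_shift SD above the reference median, so weight-status prevalences
    # resemble the study's (about 15% obese at the default 0.63); the
    # reference SD covers both the random components and the fixed-effect
    # spread so cohort z-scores have unit scale
    mu_arr = np.asarray(mu) if np.ndim(mu) else np.full(len(ids), float(mu))
    s_ref = float(np.sqrt(sA + sC + sE + mu_arr.var()))
    ln_m_ref = float(mu_arr.mean()) - config.zref_shift * s_ref
    table["bmi_z"] = (y - ln_m_ref) / s_ref
    table = table.drop(columns=["race3"])

    truth = {
        "sigma2": {"A": sA, "C": sC, "E": sE},
        "beta": dict(config.beta),
        "seed": config.seed,
        "linear_predictor": mu if np.ndim(mu) else np.full(len(ids), mu),
        "composition": dict(config.composition),
    }
    return SyntheticCohort(table=table, K=K, H=H, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the cohort in the supplementary-compatible CSV layouts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "relatedness": outdir / "relatedness_matrix.csv",
        "home": outdir / "home_matrix.csv",
        "truth": outdir / "ground_truth.json",
    }
    cohort.table.to_csv(paths["cohort"], index=False)
    write_matrix_csv(cohort.K, paths["relatedness"])
    write_matrix_csv(cohort.H, paths["home"])
    truth = dict(cohort.truth)
    truth["linear_predictor"] = np.asarray(
        truth["linear_predictor"]
    ).tolist()
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
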