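"""Cohort preparation: LMS z-scoring, exclusions, age groups, pairs, subsets.

Raw child records (one row per child: id, household, BMI, age, sex, race,
ethnicity, home type, reared-by-biological-parent flag) are transformed into
the analysis table.  BMI is age-corrected to a z-score against an LMS growth
reference (Box-Cox power L, median M, coefficient of variation S per sex and
age in months), screened for implausible values, ln-transformed, and each
child is assigned to the middle-childhood ([5, 12) years) or adolescent
([12, 19) years) group.  Sibling pairs are enumerated from the K and H
matrices and drive the three age-composition model subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import RELATEDNESS_PAIR_CLASS, LabeledMatrix

__all__ = [
    "RACE3_LEVELS",
    "lms_zscore",
    "exclude_outliers",
    "classify_weight",
    "assign_age_group",
    "recode_race",
    "enumerate_pairs",
    "build_model_subsets",
    "prepare_cohort",
]

RACE3_LEVELS = ("Caucasian", "AfricanAmerican", "Other")

#: kept z-score interval: values strictly below -4 or above 8 are removed.
Z_KEPT_LOW, Z_KEPT_HIGH = -4.0, 8.0

AGE_MIN, AGE_SPLIT, AGE_MAX = 5.0, 12.0, 19.0

WEIGHT_CUTS = (5.0, 85.0, 95.0)  # percentile cuts under/normal/over/obese


def lms_zscore(bmi, sex, age_years, reference: pd.DataFrame):
    """Age-corrected BMI z-score by the LMS method.

    ``reference`` holds columns ``sex``, ``age_months``, ``L``, ``M``, ``S``;
    L, M, S are linearly interpolated to the child's age in months.  The
    score is ``((bmi/M)**L - 1) / (L*S)`` for L != 0 and ``ln(bmi/M)/S`` at
    L == 0.
    """
    bmi = np.asarray(bmi, dtype=float)
    scalar = bmi.ndim == 0
    bmi = np.atleast_1d(bmi)
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    age = np.atleast_1d(np.asarray(age_years, dtype=float))
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    months = age * 12.0
    z = np.empty_like(bmi)
    for s in np.unique(sex_arr):
        ref_s = reference.loc[reference["sex"] == s].sort_values("age_months")
        if ref_s.empty:
            raise ValueError(f"sex {s!r} not covered by the LMS reference")
        sel = sex_arr == s
        m = months[sel]
        lo, hi = ref_s["age_months"].iloc[0], ref_s["age_months"].iloc[-1]
        if np.any((m < lo) | (m > hi)):
            raise ValueError(
                f"age outside LMS reference range [{lo / 12:.2f}, "
                f"{hi / 12:.2f}] years for sex {s!r}"
            )
        L = np.interp(m, ref_s["age_months"], ref_s["L"])
        M = np.interp(m, ref_s["age_months"], ref_s["M"])
        S = np.interp(m, ref_s["age_months"], ref_s["S"])
        b = bmi[sel]
        with np.errstate(invalid="ignore"):
            z_s = np.where(
                L != 0.0,
                ((b / M) ** L - 1.0) / (L * S),
                np.log(b / M) / np.where(S == 0, np.nan, S),
            )
        z[sel] = z_s
    return float(z[0]) if scalar else z


def exclude_outliers(
    records: pd.DataFrame, z_column: str = "bmi_z"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into kept ([-4, 8] z) and excluded (outside).

    Pure partition: kept and excluded are disjoint and their union is the
    input; order is preserved within each part.
    """
    z = records[z_column].to_numpy(dtype=float)
    keep = (z >= Z_KEPT_LOW) & (z <= Z_KEPT_HIGH)
    return records.loc[keep].copy(), records.loc[~keep].copy()


def classify_weight(bmi_z):
    """Weight-status category and percentile from the z-score.

    Percentile = 100 * Phi(z); categories: underweight (< 5th), normal
    ([5th, 85th)), overweight ([85th, 95th)), obese (>= 95th).
    """
    z = np.asarray(bmi_z, dtype=float)
    scalar = z.ndim == 0
    pct = 100.0 * stats.norm.cdf(np.atleast_1d(z))
    cats = np.select(
        [pct < WEIGHT_CUTS[0], pct < WEIGHT_CUTS[1], pct < WEIGHT_CUTS[2]],
        ["underweight", "normal", "overweight"],
        default="obese",
    )
    if scalar:
        return str(cats[0]), float(pct[0])
    return cats, pct


def assign_age_group(age_years):
    """``middle`` for ages [5, 12), ``adolescent`` for [12, 19)."""
    age = np.asarray(age_years, dtype=float)
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    if np.any((age < AGE_MIN) | (age >= AGE_MAX)):
        raise ValueError(f"age outside [{AGE_MIN}, {AGE_MAX})")
    grp = np.where(age < AGE_SPLIT, "middle", "adolescent")
    return str(grp[0]) if scalar else grp


def recode_race(race_label) -> str:
    """Collapse the reported race label to three analysis levels."""
    label = str(race_label).strip()
    norm = label.replace(" ", "").replace("/", "").replace("-", "").lower()
    if norm == "caucasian":
        return "Caucasian"
    if norm == "africanamerican":
        return "AfricanAmerican"
    return "Other"


@dataclass(frozen=True)
class PairRecord:
    """One unordered sibling pair (by relatedness or co-rearing)."""

    id_a: str
    id_b: str
    relatedness: float
    same_home: bool
    pair_class: str
    age_composition: str


def enumerate_pairs(
    records: pd.DataFrame, K: LabeledMatrix, H: LabeledMatrix
) -> pd.DataFrame:
    """All unordered pairs with relatedness > 0 or a shared home.

    Inclusion mirrors the study design: a child enters a pair if it shares a
    home with a biological sibling, has a biological sibling in a different
    home, or shares a home with a nonbiological sibling.  Each pair gets a
    pedigree class from its coefficient and an age composition from the two
    members' age groups.
    """
    ids = records["id"].astype(str).tolist()
    ki = np.array([K.index_of(i) for i in ids])
    hi = np.array([H.index_of(i) for i in ids])
    Ksub = K.values[np.ix_(ki, ki)]
    Hsub = H.values[np.ix_(hi, hi)]
    group = records.set_index(records["id"].astype(str))["age_group"]
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = (Ksub[iu, ju] > 0) | (Hsub[iu, ju] == 1)
    rows = []
    for i, j in zip(iu[mask], ju[mask]):
        r = float(Ksub[i, j])
        if r not in RELATEDNESS_PAIR_CLASS:
            raise ValueError(f"relatedness {r} has no pedigree class")
        ga, gb = group[ids[i]], group[ids[j]]
        if ga != gb:
            comp = "cross_age"
        elif ga == "middle":
            comp = "both_middle"
        else:
            comp = "both_adolescent"
        rows.append(
            {
                "id_a": ids[i],
                "id_b": ids[j],
                "relatedness": r,
                "same_home": bool(Hsub[i, j] == 1),
                "pair_class": RELATEDNESS_PAIR_CLASS[r],
                "age_composition": comp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a",
            "id_b",
            "relatedness",
            "same_home",
            "pair_class",
            "age_composition",
        ],
    )


def build_model_subsets(
    pairs: pd.DataFrame, records: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Children entering each age-composition model.

    middle: union of children in both-middle pairs; adolescent: union in
    both-adolescent pairs; cross: union in cross-age pairs.  A child with
    siblings in both age groups appears in more than one subset.
    """
    comp_map = {
        "middle": "both_middle",
        "adolescent": "both_adolescent",
        "cross": "cross_age",
    }
    rec = records.copy()
    rec["id"] = rec["id"].astype(str)
    out: dict[str, pd.DataFrame] = {}
    for name, comp in comp_map.items():
        sel = pairs.loc[pairs["age_composition"] == comp]
        members = set(sel["id_a"]).union(sel["id_b"])
        if not members:
            raise ValueError(f"model subset {name!r} is empty")
        out[name] = rec.loc[rec["id"].isin(members)].reset_index(drop=True)
    return out


def prepare_cohort(
    raw: pd.DataFrame,
    lms_reference: pd.DataFrame | None = None,
    outcome: str = "ln_bmi",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw child table -> (analysis table, exclusion log).

    Steps: drop rows with missing required fields (logged), z-score BMI via
    the LMS reference when given (otherwise an existing ``bmi_z`` column is
    used as-is), remove z outliers outside [-4, 8], recode race, assign age
    groups, and ln-transform BMI.  The analyzed outcome defaults to the
    natural log of the (age-corrected) BMI column.
    """
    required = ["id", "household_id", "bmi", "age", "sex", "home_type"]
    df = raw.copy()
    df["id"] = df["id"].astype(str)
    missing_mask = df[required].isna().any(axis=1)
    log_rows = [
        {"id": r["id"], "reason": "missing required field"}
        for _, r in df.loc[missing_mask].iterrows()
    ]
    df = df.loc[~missing_mask].copy()

    if lms_reference is not None:
        df["bmi_z"] = lms_zscore(
            df["bmi"].to_numpy(float),
            df["sex"].to_numpy(object),
            df["age"].to_numpy(float),
            lms_reference,
        )
        df.attrs["zscore_source"] = "lms_reference"
    elif "bmi_z" in df.columns:
        df.attrs["zscore_source"] = "provided"
    else:
        df.attrs["zscore_source"] = "none"

    if "bmi_z" in df.columns:
        kept, excluded = exclude_outliers(df)
        log_rows += [
            {"id": r["id"], "reason": f"bmi_z outlier ({r['bmi_z']:.2f})"}
            for _, r in excluded.iterrows()
        ]
        df = kept
        cat, pct = classify_weight(df["bmi_z"].to_numpy(float))
        df["weight_status"] = cat
        df["bmi_percentile"] = pct

    df["race3"] = df.get("race", pd.Series("Unknown", index=df.index)).map(
        recode_race
    )
    df["age_group"] = assign_age_group(df["age"].to_numpy(float))
    if outcome == "ln_bmi":
        df["ln_bmi"] = np.log(df["bmi"].to_numpy(float))
    elif outcome == "bmi_z":
        if "bmi_z" not in df.columns:
            raise ValueError("bmi_z outcome requested but no z-scores present")
    else:
        raise ValueError(f"unknown outcome transform {outcome!r}")
    df.attrs["outcome"] = outcome
    exclusion_log = pd.DataFrame(log_rows, columns=["id", "reason"])
    return df.reset_index(drop=True), exclusion_log
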