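"""Ratios, permutation p-values, FDR, ICCs, Levene, Welch, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sibvar as sv
from sibvar.inference import (
    _pair_anova_p,
    fdr_adjust,
    icc_by_class,
    levene_residual_compare,
    pairwise_fixed_contrasts,
    permutation_test,
    simulation_power,
    variance_ratios,
    welch_t_test,
    within_family_variance,
)
from sibvar.reml import build_design, reml_fit

from conftest import ln_outcome


def _fit(cohort, terms=(), **kw):
    rec = cohort.table.copy()
    rec["race3"] = rec["race"].map(sv.recode_race)
    X, names = build_design(rec, terms)
    return reml_fit(
        ln_outcome(cohort), X, [cohort.K.values, cohort.H.values],
        ("A", "C"), fixed_effect_names=names, **kw,
    )


class TestVarianceRatios:
    def test_table_values(self, small_cohort):
        fit = _fit(small_cohort)
        fit.sigma2.update(A=0.025, C=0.012, E=0.003)
        fit.boundary = {"A": False, "C": False, "E": False}
        r = variance_ratios(fit)
        assert r["h2"].estimate == pytest.approx(0.625)
        assert r["c2"].estimate == pytest.approx(0.300)
        assert r["e2"].estimate == pytest.approx(0.075)

    def test_ratios_sum_to_one(self, small_cohort):
        r = variance_ratios(_fit(small_cohort))
        total = sum(v.estimate for v in r.values())
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_pure_genetic_variance(self, small_cohort):
        fit = _fit(small_cohort)
        fit.sigma2.update(A=0.04, C=0.0, E=0.0)
        fit.boundary = {"A": False, "C": True, "E": True}
        r = variance_ratios(fit)
        assert r["h2"].estimate == 1.0
        assert r["c2"].estimate == 0.0
        assert r["e2"].estimate == 0.0

    def test_delta_method_matches_numeric_jacobian(self, small_cohort):
        fit = _fit(small_cohort)
        comps = list(fit.component_names)
        sig = np.array([fit.sigma2[c] for c in comps])
        cov = fit.vc_covariance
        r = variance_ratios(fit)
        eps = 1e-7
        for i, name in enumerate(["h2", "c2", "e2"]):
            g = np.zeros(3)
            for j in range(3):
                s_hi, s_lo = sig.copy(), sig.copy()
                s_hi[j] += eps
                s_lo[j] -= eps
                g[j] = (s_hi[i] / s_hi.sum() - s_lo[i] / s_lo.sum()) / (2 * eps)
            se_num = np.sqrt(g @ cov @ g)
            assert r[name].se == pytest.approx(se_num, rel=1e-4)


class TestPermutation:
    def test_boundary_component_gets_p_one(self):
        """Observed estimate 0 cannot be exceeded-strictly: p = 1."""
        cfg = sv.perturb_truth(
            sv.scale_composition(sv.study_mimic_config(seed=21), 0.08), "A", 0.0
        )
        cohort = sv.generate_cohort(cfg)
        y = ln_outcome(cohort)
        res = permutation_test(
            y, np.empty((len(y), 0)), [cohort.K.values, cohort.H.values],
            ("A", "C"), n_perm=19, seed=5,
        )
        if res["observed"]["A"] == 0.0:
            assert res["perm_p"]["A"] == 1.0
        assert 0 <= res["perm_p"]["A"] <= 1

    def test_reproducible_under_seed(self, small_cohort):
        y = ln_outcome(small_cohort)
        mats = [small_cohort.K.values, small_cohort.H.values]
        r1 = permutation_test(y, np.empty((len(y), 0)), mats, ("A", "C"),
                              n_perm=15, seed=42)
        r2 = permutation_test(y, np.empty((len(y), 0)), mats, ("A", "C"),
                              n_perm=15, seed=42)
        assert r1["perm_p"] == r2["perm_p"]
        pd.testing.assert_frame_equal(
            r1["null_distribution"], r2["null_distribution"]
        )

    def test_plus_one_correction_variant(self, small_cohort):
        y = ln_outcome(small_cohort)
        mats = [small_cohort.K.values, small_cohort.H.values]
        r = permutation_test(y, np.empty((len(y), 0)), mats, ("A", "C"),
                             n_perm=19, seed=3, plus_one_correction=True)
        for p in r["perm_p"].values():
            assert p >= 1 / 20

    def test_strong_signal_detected_in_most_replicates(self):
        """At the study effect sizes (h2 = 0.625) the genetic component's
        permutation p falls below 0.05 in the large majority of cohorts,
        already at a third of the study size."""
        rng = np.random.default_rng(99)
        hits, reps = 0, 10
        for _ in range(reps):
            cfg = sv.scale_composition(
                sv.study_mimic_config(seed=int(rng.integers(2**31 - 1))), 0.3
            )
            c = sv.generate_cohort(cfg)
            y = ln_outcome(c)
            res = permutation_test(
                y, np.empty((len(y), 0)), [c.K.values, c.H.values],
                ("A", "C"), n_perm=79, seed=int(rng.integers(2**31 - 1)),
            )
            hits += res["perm_p"]["A"] < 0.05
        assert hits >= 7


class TestFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_oracles(self, p, expected):
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)
    )
    def test_never_decreases_and_preserves_ranking(self, p):
        q = fdr_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order_p = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order_p]) >= -1e-12)


class TestIcc:
    def _pairs(self, n, prefix="P"):
        return pd.DataFrame(
            {
                "id_a": [f"{prefix}{i}a" for i in range(n)],
                "id_b": [f"{prefix}{i}b" for i in range(n)],
                "pair_class": "full_or_DZ",
                "same_home": True,
                "age_composition": "both_middle",
            }
        )

    def test_identical_within_pair_gives_one(self):
        pairs = self._pairs(6)
        vals = {}
        for i, row in pairs.iterrows():
            vals[row.id_a] = vals[row.id_b] = float(i)
        out = icc_by_class(pairs, pd.Series(vals))
        assert out.iloc[0]["icc"] == pytest.approx(1.0)
        assert out.iloc[0]["icc_p"] < 0.05

    def test_independent_members_near_zero(self, rng):
        pairs = self._pairs(500)
        vals = pd.Series(
            rng.normal(size=1000),
            index=list(pairs.id_a) + list(pairs.id_b),
        )
        out = icc_by_class(pairs, vals)
        assert abs(out.iloc[0]["icc"]) < 3 / np.sqrt(500)

    def test_double_entry_symmetric_in_member_order(self, rng):
        pairs = self._pairs(20)
        vals = pd.Series(
            rng.normal(size=40), index=list(pairs.id_a) + list(pairs.id_b)
        )
        swapped = pairs.rename(columns={"id_a": "id_b", "id_b": "id_a"})
        i1 = icc_by_class(pairs, vals).iloc[0]["icc"]
        i2 = icc_by_class(swapped, vals).iloc[0]["icc"]
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_small_cells_flagged_undefined(self, rng):
        pairs = self._pairs(2)
        vals = pd.Series(
            rng.normal(size=4), index=list(pairs.id_a) + list(pairs.id_b)
        )
        out = icc_by_class(pairs, vals)
        assert np.isnan(out.iloc[0]["icc"])

    def test_mz_pairs_reared_together_high_icc(self, mimic_cohort):
        rec = mimic_cohort.table.copy()
        rec["age_group"] = [sv.assign_age_group(a) for a in rec["age"]]
        pairs = sv.enumerate_pairs(rec, mimic_cohort.K, mimic_cohort.H)
        out = icc_by_class(
            pairs, rec.set_index("id")["bmi"].map(np.log),
            by=("pair_class", "same_home"),
        )
        mz = out.query("pair_class == 'MZ' and same_home").iloc[0]
        unrel = out.query("pair_class == 'unrelated' and same_home").iloc[0]
        assert mz["icc"] > 0.8  # A+C share ~0.93 of total variance for MZ
        assert mz["icc"] > unrel["icc"]


class TestWithinFamilyVariance:
    def test_identical_members_give_zero(self):
        pairs = pd.DataFrame({"id_a": ["a1", "a2"], "id_b": ["b1", "b2"]})
        vals = pd.Series({"a1": 3.0, "b1": 3.0, "a2": 5.0, "b2": 5.0})
        assert within_family_variance(pairs, vals) == 0.0

    def test_two_point_variance(self):
        # differences d and -d: sample variance = 2 d^2
        d = 0.7
        pairs = pd.DataFrame({"id_a": ["a1", "a2"], "id_b": ["b1", "b2"]})
        vals = pd.Series({"a1": d, "b1": 0.0, "a2": 0.0, "b2": d})
        assert within_family_variance(pairs, vals) == pytest.approx(2 * d**2)

    def test_single_pair_raises(self):
        pairs = pd.DataFrame({"id_a": ["a1"], "id_b": ["b1"]})
        with pytest.raises(ValueError):
            within_family_variance(pairs, pd.Series({"a1": 1.0, "b1": 2.0}))


class TestLeveneAndWelch:
    def test_identical_residuals_give_zero_statistic(self):
        r = np.array([0.1, -0.2, 0.3, -0.1, 0.05])
        stat, p = levene_residual_compare(r, r)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ninefold_variance_difference_detected(self, rng):
        rejections = 0
        for _ in range(10):
            a = rng.normal(0, 1, 100)
            b = rng.normal(0, 3, 100)
            _, p = levene_residual_compare(a, b)
            rejections += p < 0.05
        assert rejections >= 9

    def test_welch_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_welch_hand_oracle(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)

    def test_welch_needs_variance(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestContrasts:
    def test_equal_group_effects_give_unit_multipliers(self, mimic_cohort):
        cfg = sv.SyntheticConfig(beta={"intercept": 3.0})  # no race effect
        cohort = sv.generate_cohort(cfg.with_seed(8))
        fit = _fit(cohort, ("race3",))
        out = pairwise_fixed_contrasts(fit)
        assert len(out) == 3
        for m in out["multiplier"]:
            assert m == pytest.approx(1.0, abs=0.06)

    def test_bonferroni_threshold(self, mimic_cohort):
        fit = _fit(mimic_cohort, ("race3", "home_type"))
        out = pairwise_fixed_contrasts(fit)
        for _, row in out.iterrows():
            assert row["significant"] == (row["p"] < 0.017)

    def test_requires_race_in_design(self, small_cohort):
        fit = _fit(small_cohort, ("home_type",))
        with pytest.raises(ValueError, match="race"):
            pairwise_fixed_contrasts(fit)


class TestSimulationPower:
    def test_null_component_power_near_alpha(self):
        cfg = sv.perturb_truth(sv.study_mimic_config(), "A", 0.0)
        res = simulation_power(
            cfg, alpha=0.05, n_grid=(0.1,), reps=30, seed=44
        )
        assert res["curve"]["power"].iloc[0] <= 0.2

    def test_power_grows_with_n_for_strong_effect(self):
        res = simulation_power(
            sv.study_mimic_config(), alpha=0.05, n_grid=(0.05, 0.4),
            reps=25, seed=45,
        )
        p = res["curve"]["power"].to_numpy()
        assert p[1] >= p[0] - 0.15  # monotone up to MC noise
        assert p[1] > 0.5


def test_pair_anova_p_detects_between_pair_spread(rng):
    a = np.repeat(np.arange(10.0), 1) + rng.normal(0, 0.01, 10)
    b = np.repeat(np.arange(10.0), 1) + rng.normal(0, 0.01, 10)
    assert _pair_anova_p(a, b) < 1e-6
    c = rng.normal(size=10)
    d = rng.normal(size=10)
    assert _pair_anova_p(c, d) > 0.01
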