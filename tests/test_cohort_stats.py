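"""Mixed models, releveling, ROC/Youden and the biomarker screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carotidwave.cohort_stats import (day50_biomarker_screen, fit_lmm,
                                      genotype_effect, relevel_posthoc,
                                      roc_analysis, correlation)
from carotidwave.synthwave import CohortSpec, simulate_cohort


def brute_force_auc(values, labels, positive="dcr"):
    """Mann–Whitney pair-count oracle: P(pos > neg) + ½·P(tie)."""
    v = np.asarray(values, dtype=float)
    pos = v[np.asarray(labels) == positive]
    neg = v[np.asarray(labels) != positive]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def cohort():
    table, _ = simulate_cohort(CohortSpec(n_per_group=6, seed=17))
    return table


class TestFitLmm:
    def test_deterministic_limit_recovers_plant_exactly(self):
        # vanishing noise: the genotype coefficient equals the planted shift
        zeros = {m: 0.0 for m in CohortSpec().baselines}
        tiny = {m: 1e-8 for m in CohortSpec().baselines}
        effects = {"diameter_mm": {"F": {50: 0.10, 125: 0.10},
                                   "M": {50: 0.10, 125: 0.10}}}
        spec = CohortSpec(n_per_group=4, between_sd=dict(zeros),
                          resid_sd=tiny, effects=effects,
                          age_slopes=dict(zeros),
                          side_ratio={m: 1.0 for m in zeros},
                          arrhythmia_fraction=0.0, seed=1)
        table, _ = simulate_cohort(spec)
        fit = fit_lmm(table, "diameter_mm",
                      fixed_spec="genotype + sex + age + side")
        planted = 0.10 * CohortSpec().baselines["diameter_mm"]
        assert genotype_effect(fit)["estimate"] == pytest.approx(planted, abs=1e-6)

    def test_balanced_two_group_effect_equals_mean_difference(self):
        rng = np.random.default_rng(3)
        rows = []
        for genotype in ("control", "dcr"):
            for i in range(10):
                rows.append({"mouse_id": f"{genotype}{i}", "genotype": genotype,
                             "sex": "F", "age_days": 50, "side": "LCCA",
                             "y": rng.normal(1.0 + (genotype == "dcr") * 0.5, 0.2)})
        table = pd.DataFrame(rows)
        fit = fit_lmm(table, "y", fixed_spec="genotype")
        diff = (table[table.genotype == "dcr"]["y"].mean()
                - table[table.genotype == "control"]["y"].mean())
        assert genotype_effect(fit)["estimate"] == pytest.approx(diff, abs=1e-6)

    def test_single_level_factor_rejected(self, cohort):
        with pytest.raises(ValueError):
            fit_lmm(cohort[cohort.sex == "F"], "diameter_mm")

    def test_missing_outcomes_dropped(self, cohort):
        table = cohort.copy()
        table.loc[table.index[:6], "flow_ml_min"] = np.nan
        fit = fit_lmm(table, "flow_ml_min")
        assert fit.n_obs == len(table) - 6


class TestReleveling:
    def test_involution_restores_coefficients(self, cohort):
        fit = fit_lmm(cohort, "pwv_m_s")
        there = relevel_posthoc(fit, "sex", "M")
        back = relevel_posthoc(there, "sex", "F")
        pd.testing.assert_frame_equal(fit.coefficients, back.coefficients)

    def test_log_likelihood_invariant(self, cohort):
        fit = fit_lmm(cohort, "flow_ml_min")
        for factor, level in (("sex", "M"), ("genotype", "dcr"), ("age", 125)):
            releveled = relevel_posthoc(fit, factor, level)
            assert releveled.llf == pytest.approx(fit.llf, abs=1e-4)

    def test_releveled_sex_changes_genotype_simple_effect(self, cohort):
        fit = fit_lmm(cohort, "pwv_m_s")  # reference: females at day 50
        male = relevel_posthoc(fit, "sex", "M")
        # planted: no female PWV effect at day 50, −22% in males
        assert genotype_effect(male)["estimate"] < genotype_effect(fit)["estimate"]


class TestRocAnalysis:
    def test_auc_equals_brute_force_mann_whitney(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(3, 12, size=2)
            values = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n2)])
            if rng.random() < 0.3:  # inject ties
                values = np.round(values)
            labels = np.array(["dcr"] * n1 + ["control"] * n2)
            roc = roc_analysis(values, labels)
            oracle = brute_force_auc(values, labels)
            assert roc.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        values = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.5, "dcr", "control")
        values[labels == "dcr"] += 0.8
        roc = roc_analysis(values, labels)
        assert roc.auc == pytest.approx(
            roc_auc_score(labels == "dcr", values), abs=1e-12)

    def test_perfect_separation(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array(["control"] * 3 + ["dcr"] * 3)
        roc = roc_analysis(values, labels)
        assert roc.auc == 1.0 and roc.youden_j == 1.0
        assert roc.youden_cutoff == pytest.approx(6.5)  # midpoint of the gap

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=4000)
        labels = np.array(["dcr", "control"] * 2000)
        rng.shuffle(labels)
        roc = roc_analysis(values, labels)
        assert 0.5 <= roc.auc < 0.53  # orientation forces ≥ 0.5

    def test_one_class_empty_raises(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], ["dcr", "dcr"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12).filter(
        lambda v: len(v) >= 2))
    def test_auc_oracle_property_with_heavy_ties(self, vals):
        labels = np.array(["dcr", "control"] * ((len(vals) + 1) // 2))[:len(vals)]
        roc = roc_analysis(np.array(vals, dtype=float), labels)
        oracle = brute_force_auc(vals, labels)
        assert roc.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)


class TestBiomarkerScreen:
    def test_planted_female_flow_deficit_flagged(self):
        effects = {"flow_ml_min": {"F": {50: -0.30, 125: -0.30},
                                   "M": {50: 0.0, 125: 0.0}}}
        spec = CohortSpec(n_per_group=6, effects=effects, seed=21)
        table, _ = simulate_cohort(spec)
        screen = day50_biomarker_screen(table, metrics=["flow_ml_min"])
        by_sex = screen.set_index("sex")
        assert bool(by_sex.loc["F", "significant"])
        assert by_sex.loc["F", "direction"] == "decrease"
        assert not bool(by_sex.loc["M", "significant"])
        assert by_sex.loc["F", "auc"] > 0.7

    def test_null_cohort_rarely_flags(self):
        n_flags, n_tests = 0, 0
        for seed in range(20):
            table, _ = simulate_cohort(CohortSpec(n_per_group=6, effects={},
                                                  seed=seed))
            screen = day50_biomarker_screen(table, metrics=["diameter_mm",
                                                            "flow_ml_min"])
            n_flags += int(screen["significant"].sum())
            n_tests += len(screen)
        # false-flag rate should be near alpha (no multiplicity correction)
        assert n_flags / n_tests < 0.15

    def test_separated_toy_cutoff_at_group_midpoint(self):
        rows = []
        for genotype, base in (("control", 1.0), ("dcr", 2.0)):
            for i in range(4):
                for age in (50, 75):
                    for side in ("LCCA", "RCCA"):
                        rows.append({"mouse_id": f"{genotype}{i}",
                                     "genotype": genotype, "sex": "F",
                                     "age_days": age, "side": side,
                                     "metric_mm": base + 0.01 * i})
        rows_m = [dict(r, sex="M", mouse_id=r["mouse_id"] + "m") for r in rows]
        table = pd.DataFrame(rows + rows_m)
        screen = day50_biomarker_screen(table, metrics=["metric_mm"])
        f_row = screen[(screen.sex == "F")].iloc[0]
        assert f_row["significant"]
        assert f_row["youden_cutoff"] == pytest.approx((1.03 + 2.0) / 2)


    def test_fdr_option_only_raises_p_values(self):
        table, _ = simulate_cohort(CohortSpec(n_per_group=6, seed=21))
        raw = day50_biomarker_screen(table, metrics=["flow_ml_min",
                                                     "diameter_mm"])
        adj = day50_biomarker_screen(table, metrics=["flow_ml_min",
                                                     "diameter_mm"], fdr=True)
        assert (adj["p_adjusted"] >= raw["p_value"] - 1e-15).all()
        assert adj["significant"].sum() <= raw["significant"].sum()


def test_correlation_utility(cohort):
    r, p = correlation(cohort, "pulsatility_index", "heart_rate_bpm")
    assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0
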