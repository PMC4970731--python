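"""Statistical-stage tests: mixed models, GLMs, curve/stepwise fits,
association helpers, and their calibration properties."""

import numpy as np
import pandas as pd
import pytest

from saccadetools import group_stats
from saccadetools.group_stats import (
    AnalysisError, age_and_epilepsy_models, assoc_stats, bonferroni,
    mixed_model, proportion_glm,
)


def _trial_table(rng, n_child=30, n_trials=12, group_offsets=None):
    group_offsets = group_offsets or {}
    rows = []
    for i in range(n_child):
        g = ["HC", "chronic", "controlled"][i % 3]
        u = rng.normal(0, 1)
        for j in range(n_trials):
            st = ["PS", "AS", "PE"][j % 3]
            base = {"PS": 6.0, "AS": 3.5, "PE": 7.5}[st]
            rows.append({
                "child_id": f"c{i}", "group": g, "saccade_type": st,
                "recip_srt": base + group_offsets.get(g, 0.0) + u + rng.normal(0, 1),
            })
    return pd.DataFrame(rows)


def _child_table(rng, means, n=(48, 15, 11), sd=0.15):
    rows = []
    for g, m, k in zip(("HC", "chronic", "controlled"), means, n):
        for i in range(k):
            rows.append({"child_id": f"{g}{i}", "group": g,
                         "value": rng.normal(m, sd)})
    return pd.DataFrame(rows)


class TestBonferroni:
    def test_formula(self):
        assert bonferroni(0.01) == pytest.approx(0.03)
        assert bonferroni(0.5) == 1.0

    def test_adjusted_at_least_raw(self):
        for p in np.linspace(0, 1, 21):
            assert bonferroni(p) >= p


class TestMixedModel:
    def test_effect_recovery_within_ci(self):
        rng = np.random.default_rng(0)
        df = _trial_table(rng, n_child=120, n_trials=12,
                          group_offsets={"chronic": 1.0})
        et = mixed_model(df, "recip_srt")
        assert et.contrasts is not None
        # HC - chronic estimate should be ~ -1.0, CI covering the truth
        row = et.contrasts[(et.contrasts["family"] == "PS")
                           & (et.contrasts["contrast"] == "HC-chronic")].iloc[0]
        assert abs(row["estimate"] - (-1.0)) < 1.96 * row["se"]

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(1)
        df = _trial_table(rng)
        df["recip_srt"] = 5.0
        with pytest.raises(AnalysisError):
            mixed_model(df, "recip_srt")

    def test_needs_two_children_per_group(self):
        rng = np.random.default_rng(2)
        df = _trial_table(rng, n_child=4)
        with pytest.raises(AnalysisError):
            mixed_model(df, "recip_srt")

    def test_bonferroni_on_contrasts(self):
        rng = np.random.default_rng(3)
        et = mixed_model(_trial_table(rng), "recip_srt")
        c = et.contrasts.dropna(subset=["p"])
        assert np.allclose(c["p_adj"], np.minimum(1.0, 3 * c["p"]))

    def test_agrees_in_sign_with_child_means(self):
        rng = np.random.default_rng(4)
        df = _trial_table(rng, n_child=60, group_offsets={"chronic": 1.5})
        et = mixed_model(df, "recip_srt")
        means = df.groupby(["child_id", "group"], observed=True)["recip_srt"] \
            .mean().reset_index()
        delta = (means[means.group == "HC"]["recip_srt"].mean()
                 - means[means.group == "chronic"]["recip_srt"].mean())
        row = et.contrasts[(et.contrasts["family"] == "AS")
                           & (et.contrasts["contrast"] == "HC-chronic")].iloc[0]
        assert np.sign(row["estimate"]) == np.sign(delta)


class TestProportionGlm:
    def test_power_at_large_separation(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            df = _child_table(rng, (0.9, 0.9, 0.65), sd=0.18)
            et = proportion_glm(df, "value", predictors=["group"])
            hits += et.term("C(group)")["p"] < 0.05
        assert hits >= 20  # >= 80% of seeds

    def test_null_eta_sq_near_zero(self):
        etas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = _child_table(rng, (0.5, 0.5, 0.5), n=(48, 48, 48))
            et = proportion_glm(df, "value", predictors=["group"])
            etas.append(et.term("C(group)")["eta_sq"])
        assert np.median(etas) < 0.02

    def test_constant_predictor_named_in_error(self):
        rng = np.random.default_rng(5)
        df = _child_table(rng, (0.5, 0.6, 0.7))
        df["iq"] = 100.0
        with pytest.raises(AnalysisError, match="iq"):
            proportion_glm(df, "value", predictors=["group", "iq"])

    def test_all_missing_outcome_rejected(self):
        rng = np.random.default_rng(6)
        df = _child_table(rng, (0.5, 0.6, 0.7))
        df["value"] = np.nan
        with pytest.raises(AnalysisError):
            proportion_glm(df, "value", predictors=["group"])

    def test_eta_sq_partition(self):
        rng = np.random.default_rng(7)
        df = _child_table(rng, (0.4, 0.6, 0.8))
        et = proportion_glm(df, "value", predictors=["group"])
        row = et.term("C(group)")
        assert 0.0 <= row["eta_sq"] <= row["partial_eta_sq"] <= 1.0


def _patient_table(rng, n=26, onset_coef=0.0, noise=40.0):
    age = rng.uniform(8, 18, n)
    onset = np.clip(rng.normal(7, 2, n), 1, age - 1)
    duration = np.clip(rng.normal(4, 2.5, n), 0.1, age - onset)
    last = np.clip(rng.normal(1.5, 1.5, n), 0, duration)
    iq = rng.normal(90, 16, n)
    v = 340.0 + onset_coef * onset + rng.normal(0, noise, n)
    return pd.DataFrame({
        "group": ["chronic"] * (n // 2) + ["controlled"] * (n - n // 2),
        "age": age, "onset": onset, "duration": duration,
        "last_seizure": last, "iq": iq, "peak_vel_AS": v})


class TestAgeAndEpilepsyModels:
    def test_quadratic_vertex_recovery(self):
        rng = np.random.default_rng(0)
        n = 80
        age = rng.uniform(8, 18, n)
        v = 340.0 - 2.0 * (age - 13.0) ** 2 + rng.normal(0, 10, n)
        df = pd.DataFrame({"group": ["HC"] * n, "age": age, "peak_vel_PS": v})
        et = age_and_epilepsy_models(df, "peak_vel_PS", ["age"], form="quadratic")
        row = et.terms[et.terms["term"] == "I(age ** 2)"].iloc[0]
        assert 12.0 <= row["vertex"] <= 14.0
        assert row["p"] < 0.01

    def test_onset_sign_recovery(self):
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = _patient_table(rng, onset_coef=8.0, noise=30.0)
            et = age_and_epilepsy_models(df, "peak_vel_AS", ["onset"],
                                         covariates=["group", "iq"])
            signs.append(et.coefs["onset"] > 0)
        assert np.mean(signs) >= 0.95

    def test_stepwise_null_retains_few(self):
        # three candidates at alpha-to-enter 0.05: expect ~0.95^3 = 86%
        # of null seeds to retain nothing; assert a safe lower bound
        none_kept = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = _patient_table(rng)
            et = age_and_epilepsy_models(
                df, "peak_vel_AS", ["onset", "duration", "last_seizure"],
                stepwise=True, covariates=["group", "iq"])
            none_kept += et.terms.empty
        assert none_kept >= 32  # >= 80%

    def test_stepwise_finds_injected_factor(self):
        rng = np.random.default_rng(1)
        df = _patient_table(rng, onset_coef=15.0, noise=20.0)
        et = age_and_epilepsy_models(
            df, "peak_vel_AS", ["onset", "duration", "last_seizure"],
            stepwise=True, covariates=["group", "iq"])
        assert "onset" in list(et.terms["term"])

    def test_patient_predictor_with_controls_rejected(self):
        rng = np.random.default_rng(2)
        df = _patient_table(rng)
        df.loc[0, "group"] = "HC"
        with pytest.raises(AnalysisError, match="patient-only"):
            age_and_epilepsy_models(df, "peak_vel_AS", ["onset"],
                                    covariates=["group", "iq"])


class TestAssocStats:
    def test_monotone_rho_one(self):
        x = np.arange(10.0)
        assert assoc_stats(x, x ** 3, "spearman")[0] == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        x = np.arange(10.0)
        assert assoc_stats(x, -x, "spearman")[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(AnalysisError):
            assoc_stats(np.ones(10), np.arange(10.0), "spearman")

    def test_r2_change_nonnegative_and_small_for_noise(self):
        changes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(40, 1))
            y = 2.0 * base[:, 0] + rng.normal(size=40)
            noise_term = rng.normal(size=40)
            r2c, p = assoc_stats(noise_term, y, "ols_r2_change", base=base)
            assert r2c >= -1e-12
            changes.append(r2c)
        assert np.median(changes) < 0.02

    def test_r2_change_detects_real_term(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(60, 1))
        x = rng.normal(size=60)
        y = base[:, 0] + 2.0 * x + rng.normal(size=60)
        r2c, p = assoc_stats(x, y, "ols_r2_change", base=base)
        assert r2c > 0.3 and p < 1e-6

    def test_too_few_pairs(self):
        with pytest.raises(AnalysisError):
            assoc_stats([1, 2, 3], [3, 2, 1], "spearman")
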