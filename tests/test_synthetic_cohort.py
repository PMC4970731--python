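"""Tests for the cohort generator: profiles, promptness race, trials, traces."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import kstest, truncnorm

from saccadetools.cli_reporting import classify_cohort, simulate_cohort
from saccadetools.event_processing import detect_saccades, gate_trial
from saccadetools.synthetic_cohort import (
    ChildProfile, ConfigError, SimConfig, SimulationError, make_cohort,
    sample_promptness, simulate_trials, synth_gaze_trace,
)
from saccadetools.trial_classification import classify


class TestMakeCohort:
    def test_default_group_counts(self):
        profiles = make_cohort(SimConfig())
        groups = [p.group for p in profiles]
        assert groups.count("HC") == 48
        assert groups.count("chronic") == 15
        assert groups.count("controlled") == 11

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError):
            make_cohort(SimConfig(n_per_group=(0, 0, 0)))

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            make_cohort(SimConfig(n_per_group=(10, -1, 5)))

    def test_determinism(self):
        a = make_cohort(SimConfig(seed=42))
        b = make_cohort(SimConfig(seed=42))
        assert a == b

    def test_hc_children_have_no_epilepsy_fields(self):
        for p in make_cohort(SimConfig(seed=3)):
            if p.group == "HC":
                assert p.iq is None and p.onset is None and p.duration is None
                assert not p.on_medication
            else:
                assert p.onset is not None and p.duration is not None

    def test_onset_plus_duration_within_age(self):
        for p in make_cohort(SimConfig(seed=4)):
            if p.group != "HC":
                assert p.onset + p.duration <= p.age + 1e-9

    def test_group_effect_shifts_parameter(self):
        cfg = SimConfig(seed=1, group_effects={"chronic": {"ps_mu": 2.0}})
        base = SimConfig(seed=1)
        shifted = {p.child_id: p for p in make_cohort(cfg)}
        for p in make_cohort(base):
            dmu = shifted[p.child_id].params["later"]["PS"][0] - p.params["later"]["PS"][0]
            assert dmu == pytest.approx(2.0 if p.group == "chronic" else 0.0)

    def test_covariate_effect_enters_linearly(self):
        cfg = SimConfig(seed=1, covariate_effects={"ps_mu": {"age": 0.1}})
        for p in make_cohort(cfg):
            expected = SimConfig().later_params[p.group]["PS"][0] + 0.1 * p.age
            assert p.params["later"]["PS"][0] == pytest.approx(expected)


class TestSamplePromptness:
    def test_moments_without_early_unit(self):
        p = sample_promptness(6.04, 1.38, 0.0, 100_000, np.random.default_rng(0))
        assert p.mean() == pytest.approx(6.04, abs=0.02)
        assert p.std() == pytest.approx(1.38, abs=0.02)
        assert (p > 0).all()

    def test_degenerate_race_is_truncated_normal(self):
        p = sample_promptness(4.0, 1.5, 0.0, 10_000, np.random.default_rng(1))
        law = truncnorm(a=-4.0 / 1.5, b=np.inf, loc=4.0, scale=1.5)
        assert kstest(p, law.cdf).pvalue > 0.01

    def test_express_fraction_increases_with_sigma_e(self):
        fracs = []
        for se in (0.0, 2.5, 5.0):
            p = sample_promptness(6.04, 1.38, se, 100_000, np.random.default_rng(2))
            lat = 1000.0 / p
            fracs.append(((lat >= 80) & (lat <= 120)).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_vanishing_acceptance_rejected(self):
        with pytest.raises(SimulationError):
            sample_promptness(-10.0, 1.0, 0.0, 10, np.random.default_rng(0))

    @pytest.mark.parametrize("bad", [dict(sigma=0.0), dict(sigma_e=-1.0), dict(n=0)])
    def test_invalid_args(self, bad):
        kw = dict(mu=5.0, sigma=1.0, sigma_e=0.0, n=10)
        kw.update(bad)
        with pytest.raises(ValueError):
            sample_promptness(kw["mu"], kw["sigma"], kw["sigma_e"], kw["n"])


def _one_child(config):
    return make_cohort(config)[0]


class TestSimulateTrials:
    def test_trial_counts_and_sides(self, small_config):
        child = _one_child(small_config)
        trials = simulate_trials(child, small_config, rng=1)
        assert len(trials) == 2 * small_config.trials_per_task
        for task in ("PS", "AS"):
            sub = [t for t in trials if t.task == task]
            assert len(sub) == small_config.trials_per_task
            sides = [t.target_side for t in sub]
            assert abs(sides.count("L") - sides.count("R")) <= 1

    def test_no_errors_when_logit_floor(self, small_config):
        cfg = dataclasses.replace(small_config, error_logit_intercept=-60.0)
        child = _one_child(cfg)
        trials = simulate_trials(child, cfg, rng=2)
        for t in trials:
            if t.task == "AS":
                label = classify(t)
                assert label.saccade_class in ("AS_correct", "none")

    def test_all_errors_when_logit_ceiling(self, small_config):
        cfg = dataclasses.replace(small_config, error_logit_intercept=60.0)
        child = _one_child(cfg)
        trials = simulate_trials(child, cfg, rng=3)
        classes = [classify(t).saccade_class for t in trials if t.task == "AS"]
        assert set(classes) <= {"PE", "none"}
        assert "PE" in classes

    def test_corrections_recovered_at_configured_rate(self):
        # ~10^4 simulated AS error trials; corrective saccades inside the window
        cfg = SimConfig(n_per_group=(1, 0, 0), trials_per_task=5000,
                        error_logit_intercept=60.0, correction_prob=0.9,
                        correction_delay=(150.0, 150.0),
                        blink_rate=0.0, fixation_break_rate=0.0, seed=5)
        child = _one_child(cfg)
        trials = simulate_trials(child, cfg, rng=5)
        labels = [classify(t) for t in trials if t.task == "AS"]
        pe = [l for l in labels if l.saccade_class == "PE"]
        corrected = sum(bool(l.corrected) for l in pe)
        assert corrected / len(pe) == pytest.approx(0.9, abs=0.02)

    def test_blink_rate_one_excludes_everything(self, small_config):
        cfg = dataclasses.replace(small_config, blink_rate=1.0)
        child = _one_child(cfg)
        for t in simulate_trials(child, cfg, rng=6):
            passed, reason = gate_trial(t)
            assert not passed and reason == "blink"

    def test_unknown_mode_rejected(self, small_config):
        child = _one_child(small_config)
        with pytest.raises(ConfigError):
            simulate_trials(child, small_config, rng=0, mode="movie")


class TestSynthGazeTrace:
    def test_round_trip_amp_and_velocity(self, rng):
        s = synth_gaze_trace([{"onset": 1150.0, "amp": 8.0, "peak_vel": 340.0}], rng=rng)
        events, blinks, unusable = detect_saccades(s)
        assert not unusable and len(events) == 1
        assert events[0].amp == pytest.approx(8.0, abs=0.25)
        assert events[0].peak_vel == pytest.approx(340.0, rel=0.05)

    def test_no_planned_saccade_no_event(self, rng):
        s = synth_gaze_trace([], rng=rng)
        events, _, _ = detect_saccades(s)
        assert events == []

    def test_two_saccades_detected_in_order(self, rng):
        s = synth_gaze_trace([
            {"onset": 1100.0, "amp": 6.0, "peak_vel": 280.0},
            {"onset": 1300.0, "amp": -5.0, "peak_vel": 240.0}], rng=rng)
        events, _, _ = detect_saccades(s)
        assert len(events) == 2
        assert events[0].onset < events[1].onset
        assert events[0].amp == pytest.approx(6.0, abs=0.25)
        assert events[1].amp == pytest.approx(-5.0, abs=0.25)

    def test_zero_amplitude_rejected(self, rng):
        with pytest.raises(SimulationError):
            synth_gaze_trace([{"onset": 1100.0, "amp": 0.0, "peak_vel": 300.0}], rng=rng)

    def test_blink_becomes_invalid_samples(self, rng):
        s = synth_gaze_trace([], blinks=[(500.0, 540.0)], rng=rng)
        gap = (s["t"] >= 500) & (s["t"] <= 540)
        assert not s["valid"][gap].any()
        assert np.isnan(s["x"][gap]).all()

    def test_fixation_jitter_is_small(self, rng):
        s = synth_gaze_trace([], rng=rng)
        assert s["x"].std() < 0.3


class TestPipelineProperties:
    def test_cohort_determinism_bit_for_bit(self, small_config):
        def run():
            profiles, trials = simulate_cohort(small_config)
            return [(t.child_id, t.trial_id, t.task, t.target_side,
                     [(e.onset, e.amp, e.peak_vel) for e in t.events])
                    for ts in trials.values() for t in ts]
        assert run() == run()

    def test_round_trip_classification_through_detector(self, small_config):
        # planned class must survive trace synthesis + detection + labelling
        cfg = dataclasses.replace(small_config, n_per_group=(3, 1, 1),
                                  trials_per_task=8, seed=21)
        profiles, ev_trials = simulate_cohort(cfg, mode="events")
        _, sm_trials = simulate_cohort(cfg, mode="samples")
        mismatches = total = 0
        _, ev_lab = classify_cohort(ev_trials)
        _, sm_lab = classify_cohort(sm_trials)
        for cid in ev_lab:
            ev_classes = {t.trial_id: l.saccade_class for t, l in ev_lab[cid]}
            sm_classes = {t.trial_id: l.saccade_class for t, l in sm_lab[cid]}
            for tid, cls in ev_classes.items():
                total += 1
                if sm_classes.get(tid) != cls:
                    mismatches += 1
        assert total > 0
        assert mismatches / total < 0.05
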