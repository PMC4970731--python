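"""Self-contained parameter-recovery benchmarks.

Each function generates synthetic data with the package's own generator at
healthy-control reference parameters, runs the relevant analysis stage
from scratch, and returns the recovered quantity.  Used by the acceptance
script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .cli_reporting import classify_cohort, measures_table, simulate_cohort
from .later_model import fit_later
from .synthetic_cohort import (
    DEFAULT_LATER, SimConfig, calibrate_sigma_e, sample_promptness,
)

#: Healthy-control reference values used to parameterise the generators.
REFERENCE = {
    "ps_mu_hz": 6.04,
    "ps_sigma_hz": 1.38,
    "ps_sigma_e_hz": 4.9,
    "v8_dps": 334.6,
    "gain": 1.00,
    "express_rate": 0.14,
    "corrected_rate": 0.90,
}

_CLEAN = dict(blink_rate=0.0, fixation_break_rate=0.0, sigma_e_child_sd=0.0)


def later_two_param_recovery(seed: int, n: int = 10_000):
    """Fit (mu, sigma) by KS minimisation on a recinormal sample."""
    p = sample_promptness(REFERENCE["ps_mu_hz"], REFERENCE["ps_sigma_hz"], 0.0,
                          n, np.random.default_rng(seed))
    fit = fit_later(p, with_early=False)
    return fit.mu, fit.sigma, n


def later_three_param_recovery(seed: int, n: int = 10_000):
    """Fit (mu, sigma, sigma_e) on a sample with the early unit active."""
    p = sample_promptness(REFERENCE["ps_mu_hz"], REFERENCE["ps_sigma_hz"],
                          REFERENCE["ps_sigma_e_hz"], n, np.random.default_rng(seed))
    fit = fit_later(p, with_early=True)
    return fit.mu, fit.sigma, fit.sigma_e, n


def _hc_cohort(seed: int, n_children: int = 48, trials: int = 30, **overrides):
    later = {g: dict(d) for g, d in DEFAULT_LATER.items()}
    cfg = SimConfig(n_per_group=(n_children, 0, 0), trials_per_task=trials,
                    later_params=later, seed=seed, **_CLEAN, **overrides)
    profiles, trials_by_child = simulate_cohort(cfg)
    _, labelled = classify_cohort(trials_by_child)
    return measures_table(labelled, profiles), cfg


def main_sequence_recovery(seed: int, n_children: int = 48, trials: int = 30):
    """Cohort mean of per-child velocity-at-8-deg estimates.

    Amplitude jitter SD 1 deg (gain SD 1/8) and velocity noise SD 30 deg/s
    around a line whose value at 8 deg is the reference velocity.
    """
    df, _ = _hc_cohort(seed, n_children, trials, gain_noise_sd=1.0 / 8.0)
    vals = df["v8_PS_correct"].dropna()
    return float(vals.mean()), int(len(vals))


def gain_recovery(seed: int, n_children: int = 48, trials: int = 30):
    """Cohort mean prosaccade gain with unbiased endpoints (SD 1.6 deg at 8)."""
    df, _ = _hc_cohort(seed, n_children, trials, gain_noise_sd=0.2)
    vals = df["gain_PS_correct"].dropna()
    return float(vals.mean()), int(len(vals))


def express_rate_recovery(seed: int, n_trials: int = 10_000):
    """Express-flag rate on trials whose race is calibrated to the
    reference express proportion (sigma_e solved from the model mass)."""
    se = calibrate_sigma_e(REFERENCE["express_rate"], REFERENCE["ps_mu_hz"],
                           REFERENCE["ps_sigma_hz"])
    later = {g: dict(d) for g, d in DEFAULT_LATER.items()}
    later["HC"]["PS"] = (REFERENCE["ps_mu_hz"], REFERENCE["ps_sigma_hz"], se)
    cfg = SimConfig(n_per_group=(1, 0, 0), trials_per_task=n_trials,
                    later_params=later, seed=seed, **_CLEAN)
    profiles, trials_by_child = simulate_cohort(cfg)
    records, labelled = classify_cohort(trials_by_child)
    ps = [lab for _, lab in next(iter(labelled.values()))
          if lab.saccade_class == "PS_correct"]
    n = len(ps)
    return sum(l.express for l in ps) / n, n


def corrected_rate_recovery(seed: int, n_trials: int = 10_000):
    """Corrected fraction among simulated antisaccade direction errors.

    Every AS trial is forced to a direction error; the reference fraction
    receives a corrective saccade with delay ~ U(100, 250) ms after error
    offset, inside the 300 ms rule window.
    """
    cfg = SimConfig(n_per_group=(1, 0, 0), trials_per_task=n_trials,
                    error_logit_intercept=60.0,
                    correction_prob=REFERENCE["corrected_rate"],
                    correction_delay=(100.0, 250.0), seed=seed, **_CLEAN)
    profiles, trials_by_child = simulate_cohort(cfg)
    _, labelled = classify_cohort(trials_by_child)
    pe = [lab for _, lab in next(iter(labelled.values()))
          if lab.saccade_class == "PE"]
    n = len(pe)
    return sum(bool(l.corrected) for l in pe) / n, n
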