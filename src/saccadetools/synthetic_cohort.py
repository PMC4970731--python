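"""Synthetic cohort generator for the overlap pro/antisaccade paradigm.

Generates children (three groups: healthy controls, medicated chronic
epilepsy, unmedicated controlled epilepsy) with covariates and per-trial
data — either saccade-event tables directly ("events" mode) or raw
1000-Hz gaze traces ("samples" mode) for round-tripping through the
detector.  Latencies come from a rate race: a main unit N(mu, sigma^2)
against a zero-mean early unit N(0, sigma_e^2); observed promptness is
the larger rate conditioned positive.  Kinematics follow a linear
amplitude / peak-velocity main sequence with noise.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit, ndtr

from .event_processing import SaccadeEvent, Trial


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """Simulation cannot proceed (e.g. vanishing acceptance region)."""


GROUPS = ("HC", "chronic", "controlled")
TASKS = ("PS", "AS")
SACCADE_TYPES = ("PS", "AS", "PE")

#: Per-group, per-type promptness race parameters (mu, sigma, sigma_e), Hz.
#: Defaults reproduce a healthy school-age reference cohort; the early unit
#: is attached to the reflexive drive (PS and PE) only.
DEFAULT_LATER = {
    "HC": {"PS": (6.04, 1.38, 4.9), "AS": (3.56, 1.07, 0.0), "PE": (7.54, 1.78, 4.9)},
    "chronic": {"PS": (6.03, 1.96, 4.9), "AS": (3.43, 1.26, 0.0), "PE": (7.73, 1.66, 4.9)},
    "controlled": {"PS": (5.50, 1.78, 4.8), "AS": (3.49, 0.67, 0.0), "PE": (7.01, 2.04, 4.8)},
}

#: Mean saccadic gain per saccade type (amplitude / target eccentricity).
DEFAULT_GAIN = {"PS": 1.00, "AS": 1.21, "PE": 0.82}


@dataclass(frozen=True)
class MainSequence:
    """Linear amplitude -> peak velocity relation with Gaussian noise."""

    slope: float = 30.0  # (deg/s) per deg
    intercept: float = 94.6  # deg/s; slope*8 + intercept = 334.6 at 8 deg
    noise_sd: float = 30.0  # deg/s

    def velocity(self, amp: float) -> float:
        return self.slope * abs(amp) + self.intercept


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator.

    Probabilities live in [0, 1]; a fixed ``seed`` reproduces the cohort
    bit-for-bit.  ``group_effects`` adds per-group offsets to any child
    parameter; ``covariate_effects`` maps a parameter name to
    ``{covariate: coefficient}`` with covariates drawn from
    {age, age2, iq, onset, duration, last_seizure, cbcl} entering
    linearly (age2 = age squared).
    """

    n_per_group: tuple[int, int, int] = (48, 15, 11)
    trials_per_task: int = 30
    target_eccentricity_deg: float = 8.0
    sampling_hz: float = 1000.0
    later_params: dict = field(default_factory=lambda: {
        g: dict(d) for g, d in DEFAULT_LATER.items()})
    mainseq: MainSequence = MainSequence()
    gain_mean: dict = field(default_factory=lambda: dict(DEFAULT_GAIN))
    gain_noise_sd: float = 0.20  # ratio
    # P(direction error on AS trial) = expit(intercept + slope * reflexive promptness)
    # intercept calibrated so defaults yield ~36% direction errors on AS trials
    error_logit_intercept: float = -7.77
    error_logit_slope: float = 0.9
    correction_prob: float = 0.90
    correction_delay: tuple[float, float] = (100.0, 250.0)  # uniform, ms
    blink_rate: float = 0.05
    fixation_break_rate: float = 0.03
    # between-child SD of the reflexive early-unit sigma (shared by PS and
    # PE); >0 couples a child's express-saccade rate to their error rate
    sigma_e_child_sd: float = 0.0
    group_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        probs = {"correction_prob": self.correction_prob,
                 "blink_rate": self.blink_rate,
                 "fixation_break_rate": self.fixation_break_rate}
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.trials_per_task <= 0:
            raise ConfigError("trials_per_task must be positive")
        if self.target_eccentricity_deg <= 0:
            raise ConfigError("target eccentricity must be positive")
        if any(n < 0 for n in self.n_per_group):
            raise ConfigError("group counts must be non-negative")
        if sum(self.n_per_group) <= 0:
            raise ConfigError("cohort must contain at least one child")
        for g, tasks in self.later_params.items():
            for task, (mu, sg, se) in tasks.items():
                if sg <= 0:
                    raise ConfigError(f"sigma must be > 0 for {g}/{task}")
                if se < 0:
                    raise ConfigError(f"sigma_e must be >= 0 for {g}/{task}")
        if self.gain_noise_sd < 0:
            raise ConfigError("gain_noise_sd must be >= 0")


@dataclass
class ChildProfile:
    """One simulated child: covariates plus realised generator parameters.

    Healthy controls carry no epilepsy fields (None); invariant
    ``onset + duration <= age`` holds for patients.  ``params`` holds the
    child's realised per-type race parameters, main-sequence and gain
    settings, error-logit terms and correction settings.
    """

    child_id: str
    group: str
    age: float
    iq: float | None
    cbcl_attention: float
    onset: float | None
    duration: float | None
    last_seizure: float | None
    on_medication: bool
    params: dict = field(default_factory=dict)


# covariate distributions per group: (mean, sd) on reference scales
_COVARIATES = {
    "HC": {"cbcl": (53.9, 5.3)},
    "chronic": {"cbcl": (63.1, 12.4), "iq": (86.7, 15.9),
                "onset": (6.5, 2.0), "duration": (5.5, 2.8), "last_seizure": (0.5, 1.0)},
    "controlled": {"cbcl": (54.9, 6.2), "iq": (93.8, 16.4),
                   "onset": (7.9, 2.6), "duration": (2.0, 1.6), "last_seizure": (3.2, 1.9)},
}


def sample_promptness(mu: float, sigma: float, sigma_e: float, n: int,
                      rng=None) -> np.ndarray:
    """Draw ``n`` promptness values (Hz) from the two-unit rate race.

    Each value is ``max(r_main, r_early)`` with ``r_main ~ N(mu, sigma^2)``
    and ``r_early ~ N(0, sigma_e^2)``; draws where both rates are <= 0 are
    rejected and redrawn, so every output is positive.

    Raises
    ------
    SimulationError
        When the acceptance region vanishes (sigma_e = 0 and
        mu/sigma < -6).
    ValueError
        On invalid parameters.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if sigma_e < 0:
        raise ValueError("sigma_e must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    if sigma_e == 0 and (mu / sigma) < -6.0:
        raise SimulationError(
            "acceptance probability vanishes: mu/sigma < -6 with no early unit")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    accept = 1.0 - ndtr(-mu / sigma) * (0.5 if sigma_e > 0 else 1.0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) / max(accept, 1e-6) * 1.1) + 16, 16)
        r_main = rng.normal(mu, sigma, m)
        r_early = rng.normal(0.0, sigma_e, m) if sigma_e > 0 else np.full(m, -np.inf)
        p = np.maximum(r_main, r_early)
        p = p[p > 0]
        take = min(p.size, n - filled)
        out[filled:filled + take] = p[:take]
        filled += take
    return out


def _linear_effect(cfg: SimConfig, param: str, group: str, cov: dict) -> float:
    delta = cfg.group_effects.get(group, {}).get(param, 0.0)
    for name, coef in cfg.covariate_effects.get(param, {}).items():
        base = name[:-1] if name.endswith("2") else name
        v = cov.get(base)
        if v is None:
            continue
        delta += coef * (v ** 2 if name.endswith("2") else v)
    return delta


def make_cohort(config: SimConfig) -> list[ChildProfile]:
    """Generate the configured number of children per group.

    Covariates are drawn from group-specific distributions; epilepsy
    fields are clipped so that ``onset + duration <= age``.  Deterministic
    under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles: list[ChildProfile] = []
    idx = 0
    for group, n in zip(GROUPS, config.n_per_group):
        dist = _COVARIATES[group]
        for _ in range(n):
            age = float(rng.uniform(8.0, 18.0))
            cbcl = float(rng.normal(*dist["cbcl"]))
            if group == "HC":
                iq = onset = duration = last = None
                med = False
            else:
                iq = float(np.clip(rng.normal(*dist["iq"]), 60.0, 121.0))
                onset = float(np.clip(rng.normal(*dist["onset"]), 0.5, age - 0.5))
                duration = float(np.clip(rng.normal(*dist["duration"]), 0.1, age - onset))
                last = float(np.clip(rng.normal(*dist["last_seizure"]), 0.0, duration))
                med = group == "chronic"
            cov = {"age": age, "iq": iq, "cbcl": cbcl, "onset": onset,
                   "duration": duration, "last_seizure": last}

            params = {"later": {}, "gain_mean": {}, "gain_sd": config.gain_noise_sd}
            dse = rng.normal(0.0, config.sigma_e_child_sd) if config.sigma_e_child_sd > 0 else 0.0
            for st in SACCADE_TYPES:
                mu, sg, se = config.later_params[group][st]
                mu += _linear_effect(config, f"{st.lower()}_mu", group, cov)
                sg = max(sg + _linear_effect(config, f"{st.lower()}_sigma", group, cov), 1e-3)
                se = max(se + _linear_effect(config, f"{st.lower()}_sigma_e", group, cov), 0.0)
                if st in ("PS", "PE") and se > 0:
                    se = max(se + dse, 0.0)
                params["later"][st] = (mu, sg, se)
                params["gain_mean"][st] = (config.gain_mean[st]
                                           + _linear_effect(config, f"{st.lower()}_gain", group, cov))
            ms = config.mainseq
            params["mainseq"] = MainSequence(
                slope=ms.slope + _linear_effect(config, "mainseq_slope", group, cov),
                intercept=ms.intercept + _linear_effect(config, "mainseq_intercept", group, cov),
                noise_sd=ms.noise_sd)
            params["error_logit"] = (
                config.error_logit_intercept + _linear_effect(config, "error_logit", group, cov),
                config.error_logit_slope)
            params["correction_prob"] = float(np.clip(
                config.correction_prob + _linear_effect(config, "correction_prob", group, cov),
                0.0, 1.0))

            profiles.append(ChildProfile(
                child_id=f"{group}{idx:03d}", group=group, age=age, iq=iq,
                cbcl_attention=cbcl, onset=onset, duration=duration,
                last_seizure=last, on_medication=med, params=params))
            idx += 1
    return profiles


def _minjerk_duration_ms(amp: float, peak_vel: float) -> float:
    # minimum-jerk profile: peak velocity = 1.875 * amplitude / duration
    return 1875.0 * abs(amp) / peak_vel


def simulate_trials(child: ChildProfile, config: SimConfig, rng=None,
                    mode: str = "events") -> list[Trial]:
    """Simulate one child's full session (both tasks).

    In ``events`` mode each trial carries a ready-made event list; in
    ``samples`` mode trials carry a raw gaze trace built by
    :func:`synth_gaze_trace` and no events (the detector fills them in).
    Targets alternate side in a shuffled balanced order.
    """
    config.validate()
    if mode not in ("events", "samples"):
        raise ConfigError(f"unknown simulation mode: {mode!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ecc = config.target_eccentricity_deg

    plan_list: list[tuple[str, str]] = []
    for task in TASKS:
        n = config.trials_per_task
        sides = np.array(["L", "R"])[np.tile([0, 1], (n + 1) // 2)[:n]]
        rng.shuffle(sides)
        plan_list.extend((task, str(s)) for s in sides)

    trials: list[Trial] = []
    # separate plan/trace streams keep trial plans identical across modes
    for tid, ((task, side), stream) in enumerate(zip(plan_list,
                                                     rng.spawn(len(plan_list)))):
        plan_rng, trace_rng = stream.spawn(2)
        trial = Trial(child_id=child.child_id, trial_id=tid, task=task,
                      target_side=side, target_onset=1000.0, target_ecc=ecc)
        sign = trial.target_sign

        blink = plan_rng.random() < config.blink_rate
        fixation_break = (not blink) and plan_rng.random() < config.fixation_break_rate
        planned = _plan_saccades(child, config, task, sign, ecc, plan_rng)
        if blink:
            trial.blinks = [(950.0, 1080.0)]
        if fixation_break:
            trial.pre_target_gaze = (3.0 * (1 if plan_rng.random() < 0.5 else -1), 0.0)

        if mode == "events":
            trial.events = [_event_from_plan(p) for p in planned]
        else:
            trial.samples = synth_gaze_trace(
                planned, duration_ms=2000.0, sampling_hz=config.sampling_hz,
                blinks=trial.blinks,
                start_x=trial.pre_target_gaze[0] if fixation_break else 0.0,
                rng=trace_rng)
        trials.append(trial)
    return trials


def _plan_saccades(child: ChildProfile, config: SimConfig, task: str,
                   sign: float, ecc: float, rng) -> list[dict]:
    """Decide latency, direction, amplitude and velocity of the trial's saccades."""
    later = child.params["later"]
    gains = child.params["gain_mean"]
    gsd = child.params["gain_sd"]
    ms: MainSequence = child.params["mainseq"]

    def _amp(stype: str, direction: float) -> float:
        g = max(gains[stype] + rng.normal(0.0, gsd), 0.15)
        return direction * ecc * g

    def _vel(amp: float) -> float:
        return max(ms.velocity(amp) + rng.normal(0.0, ms.noise_sd), 40.0)

    planned = []
    if task == "PS":
        p = sample_promptness(*later["PS"], 1, rng)[0]
        amp = _amp("PS", sign)
        planned.append({"onset": 1000.0 + 1000.0 / p, "amp": amp, "peak_vel": _vel(amp)})
    else:
        k0, k1 = child.params["error_logit"]
        p_reflex = sample_promptness(*later["PE"], 1, rng)[0]
        if rng.random() < expit(k0 + k1 * p_reflex):
            amp = _amp("PE", sign)  # direction error toward the target
            err = {"onset": 1000.0 + 1000.0 / p_reflex, "amp": amp, "peak_vel": _vel(amp)}
            planned.append(err)
            if rng.random() < child.params["correction_prob"]:
                delay = rng.uniform(*config.correction_delay)
                err_offset = err["onset"] + _minjerk_duration_ms(amp, err["peak_vel"])
                camp = _amp("AS", -sign) - amp  # re-cross to the mirror location
                planned.append({"onset": err_offset + delay, "amp": camp,
                                "peak_vel": _vel(camp)})
        else:
            p = sample_promptness(*later["AS"], 1, rng)[0]
            amp = _amp("AS", -sign)
            planned.append({"onset": 1000.0 + 1000.0 / p, "amp": amp, "peak_vel": _vel(amp)})
    return planned


def _event_from_plan(plan: dict, x_start: float = 0.0) -> SaccadeEvent:
    dur = _minjerk_duration_ms(plan["amp"], plan["peak_vel"])
    return SaccadeEvent(onset=plan["onset"], offset=plan["onset"] + dur,
                        amp=plan["amp"], peak_vel=plan["peak_vel"],
                        x_start=x_start, x_end=x_start + plan["amp"])


def synth_gaze_trace(planned: list[dict], duration_ms: float = 2000.0,
                     sampling_hz: float = 1000.0, blinks=(), start_x: float = 0.0,
                     jitter_sd: float = 0.05, rng=None) -> dict:
    """Render planned saccades as a gaze-sample series.

    Each saccade follows a minimum-jerk displacement whose peak
    instantaneous velocity equals the planned value; smooth fixation
    jitter (< 0.3 deg SD) is superimposed and blink intervals become
    invalid samples.

    Raises
    ------
    SimulationError
        If any planned amplitude is <= 0 in magnitude.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dt = 1000.0 / sampling_hz
    t = np.arange(0.0, duration_ms, dt)
    x = np.full(t.size, float(start_x))
    for plan in planned:
        amp, pv = plan["amp"], plan["peak_vel"]
        if abs(amp) <= 0:
            raise SimulationError("planned saccade amplitude must be non-zero")
        dur = _minjerk_duration_ms(amp, pv)
        tau = np.clip((t - plan["onset"]) / dur, 0.0, 1.0)
        x = x + amp * (10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5)

    jitter = gaussian_filter1d(rng.normal(0.0, 1.0, t.size), sigma=12.0, mode="nearest")
    sd = jitter.std()
    if sd > 0:
        x = x + jitter * (jitter_sd / sd)
    y = gaussian_filter1d(rng.normal(0.0, 1.0, t.size), sigma=12.0, mode="nearest")
    y *= jitter_sd / max(y.std(), 1e-12)

    valid = np.ones(t.size, dtype=bool)
    for b0, b1 in blinks:
        valid &= ~((t >= b0) & (t <= b1))
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return {"t": t, "x": x, "y": y, "valid": valid}


# ---------------------------------------------------------------------------
# calibration helpers

def calibrate_error_intercept(target_rate: float, mu: float, sigma: float,
                              sigma_e: float, slope: float, n: int = 200_000,
                              seed: int = 0) -> float:
    """Find the error-logit intercept giving ``target_rate`` mean AS errors."""
    from scipy.optimize import brentq
    p = sample_promptness(mu, sigma, sigma_e, n, np.random.default_rng(seed))
    return float(brentq(lambda k0: expit(k0 + slope * p).mean() - target_rate,
                        -60.0, 60.0))


def calibrate_sigma_e(target_express: float, mu: float, sigma: float,
                      window_ms=(80.0, 120.0), valid_ms=(80.0, 1000.0),
                      hi: float = 20.0) -> float:
    """Sigma_e at which the model's express-window mass equals the target.

    Mass is the probability of a latency inside ``window_ms`` relative to
    the valid-latency window, computed from the race CDF.  Monotone in
    sigma_e, solved by bisection.
    """
    from scipy.optimize import brentq
    from .later_model import express_window_mass

    def f(se):
        return express_window_mass(mu, sigma, se, window_ms, valid_ms) - target_express

    if f(0.0) >= 0:
        return 0.0
    return float(brentq(f, 1e-6, hi))


# ---------------------------------------------------------------------------
# output writers

def config_hash(config: SimConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_children_csv(profiles: list[ChildProfile], path) -> None:
    cols = ["child_id", "group", "age", "iq", "cbcl_attention", "onset",
            "duration", "last_seizure", "on_medication"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for p in profiles:
            w.writerow([p.child_id, p.group, f"{p.age:.3f}",
                        "" if p.iq is None else f"{p.iq:.2f}",
                        f"{p.cbcl_attention:.2f}",
                        "" if p.onset is None else f"{p.onset:.3f}",
                        "" if p.duration is None else f"{p.duration:.3f}",
                        "" if p.last_seizure is None else f"{p.last_seizure:.3f}",
                        int(p.on_medication)])


def write_trials_csv(trials: list[Trial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "child_id", "task", "target_side",
                    "target_onset_ms", "target_ecc_deg", "head_movement",
                    "blink_start_ms", "blink_end_ms", "pre_gaze_x", "pre_gaze_y"])
        for tr in trials:
            b0, b1 = (tr.blinks[0] if tr.blinks else ("", ""))
            gx, gy = (tr.pre_target_gaze if tr.pre_target_gaze else ("", ""))
            w.writerow([tr.trial_id, tr.child_id, tr.task, tr.target_side,
                        tr.target_onset, tr.target_ecc, int(tr.head_movement),
                        b0, b1, gx, gy])


def write_events_csv(trials: list[Trial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "child_id", "onset_ms", "offset_ms",
                    "amp_deg_signed", "peak_vel_dps", "x_start_deg", "x_end_deg"])
        for tr in trials:
            for e in tr.events:
                w.writerow([tr.trial_id, tr.child_id, f"{e.onset:.3f}",
                            f"{e.offset:.3f}", f"{e.amp:.4f}", f"{e.peak_vel:.2f}",
                            f"{e.x_start:.4f}", f"{e.x_end:.4f}"])


def write_gaze_csv(trials: list[Trial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "t_ms", "x_deg", "y_deg", "valid_flag"])
        for tr in trials:
            if tr.samples is None:
                continue
            s = tr.samples
            for i in range(s["t"].size):
                w.writerow([tr.trial_id, f"{s['t'][i]:.1f}",
                            "nan" if not s["valid"][i] else f"{s['x'][i]:.4f}",
                            "nan" if not s["valid"][i] else f"{s['y'][i]:.4f}",
                            int(s["valid"][i])])
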