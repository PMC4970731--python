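"""Trial measures and per-child aggregates.

Reciprocal SRT (promptness, Hz), saccadic gain, peak velocity, per-child
main-sequence regression evaluated at the target eccentricity, and the
proportion measures (direction-error rate, corrected-error rate,
express-saccade rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_processing import SaccadeEvent
from .trial_classification import TrialLabel

SACCADE_TYPES = ("PS_correct", "AS_correct", "PE")


@dataclass(frozen=True)
class MainSequenceFit:
    """Per-child OLS of peak velocity on unsigned amplitude.

    ``v_at`` is the fitted line evaluated at the evaluation amplitude
    (``v_at = slope * eval_amp + intercept``).
    """

    slope: float
    intercept: float
    v_at: float
    eval_amp: float
    n: int
    r2: float


def trial_measures(label: TrialLabel, event: SaccadeEvent,
                   target_ecc: float) -> tuple[float, float, float]:
    """(reciprocal SRT in Hz, gain, peak velocity) for one valid trial."""
    if label.status != "valid" or label.srt is None:
        raise ValueError("trial_measures requires a valid labelled trial")
    recip = 1000.0 / label.srt
    gain = abs(event.amp) / target_ecc
    return recip, gain, event.peak_vel


def fit_main_sequence(events: list[SaccadeEvent], min_trials: int = 5,
                      eval_amp: float = 8.0) -> MainSequenceFit | None:
    """OLS of peak velocity on |amplitude|; None when underdetermined.

    Returns None when fewer than ``min_trials`` events are available or
    all amplitudes coincide (degenerate design).
    """
    if len(events) < min_trials:
        return None
    a = np.array([abs(e.amp) for e in events])
    v = np.array([e.peak_vel for e in events])
    if np.ptp(a) == 0:
        return None
    slope, intercept = np.polyfit(a, v, 1)
    pred = slope * a + intercept
    ss_res = float(((v - pred) ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MainSequenceFit(slope=float(slope), intercept=float(intercept),
                           v_at=float(slope * eval_amp + intercept),
                           eval_amp=eval_amp, n=len(events), r2=r2)


def summarise_child(labels: list[TrialLabel], tasks: list[str],
                    target_ecc: float = 8.0, min_trials: int = 5) -> dict:
    """Aggregate one child's labelled trials into child-level measures.

    Rates use valid-trial denominators: ``error_rate`` = PE / valid AS
    trials, ``corrected_rate`` = corrected PE / PE, ``es_rate`` = express
    / correct PS.  Fields with no eligible trials are NaN, not zero.
    """
    if len(labels) != len(tasks):
        raise ValueError("labels and tasks must align")
    out: dict = {}
    by_type: dict[str, list[TrialLabel]] = {st: [] for st in SACCADE_TYPES}
    for lab in labels:
        if lab.status == "valid":
            by_type[lab.saccade_class].append(lab)

    for st in SACCADE_TYPES:
        labs = by_type[st]
        out[f"n_{st}"] = len(labs)
        if labs:
            recips, gains, vels = zip(*(
                trial_measures(l, l.first_event, target_ecc) for l in labs))
            out[f"recip_srt_{st}"] = float(np.mean(recips))
            out[f"gain_{st}"] = float(np.mean(gains))
            out[f"peak_vel_{st}"] = float(np.mean(vels))
        else:
            out[f"recip_srt_{st}"] = out[f"gain_{st}"] = out[f"peak_vel_{st}"] = math.nan
        fit = fit_main_sequence([l.first_event for l in labs], min_trials=min_trials,
                                eval_amp=target_ecc)
        out[f"v8_{st}"] = fit.v_at if fit else math.nan
        out[f"mainseq_slope_{st}"] = fit.slope if fit else math.nan
        out[f"mainseq_r2_{st}"] = fit.r2 if fit else math.nan

    n_as_valid = out["n_AS_correct"] + out["n_PE"]
    n_pe = out["n_PE"]
    n_ps = out["n_PS_correct"]
    out["n_valid_AS"] = n_as_valid
    out["error_rate"] = n_pe / n_as_valid if n_as_valid else math.nan
    out["corrected_rate"] = (
        sum(bool(l.corrected) for l in by_type["PE"]) / n_pe if n_pe else math.nan)
    out["es_rate"] = (
        sum(l.express for l in by_type["PS_correct"]) / n_ps if n_ps else math.nan)
    return out


def labels_to_frame(records: list[dict]) -> pd.DataFrame:
    """Flatten per-trial label records (dicts) into the label table."""
    return pd.DataFrame.from_records(records)


def child_table(per_child: dict[str, dict], covariates: pd.DataFrame | None = None
                ) -> pd.DataFrame:
    """Child-level measures table, optionally joined with covariates."""
    df = pd.DataFrame.from_dict(per_child, orient="index")
    df.index.name = "child_id"
    df = df.reset_index()
    if covariates is not None:
        df = covariates.merge(df, on="child_id", how="right")
    return df
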