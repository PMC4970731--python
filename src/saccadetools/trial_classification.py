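"""Trial labelling: valid first saccade, correct/error class, express flag,
and correction detection for direction errors in the antisaccade task."""

from __future__ import annotations

from dataclasses import dataclass

from .event_processing import SaccadeEvent, Trial


@dataclass(frozen=True)
class ClassifierParams:
    min_amp: float = 1.0  # deg; applies to primary and corrective saccades
    srt_min: float = 80.0  # ms
    srt_max: float = 1000.0  # ms
    express_min: float = 80.0  # ms, inclusive
    express_max: float = 120.0  # ms, inclusive
    correction_window: float = 300.0  # ms after error offset
    direction_tie: float = 0.1  # |amp| below this cannot define a direction


@dataclass
class TrialLabel:
    """Classification outcome of one gated trial.

    ``srt`` is defined iff ``status == "valid"`` and then lies in
    [srt_min, srt_max]; ``express`` implies a correct prosaccade;
    ``corrected`` is defined only for prosaccade errors (class "PE").
    """

    status: str  # "valid" | "excluded"
    reason: str  # "none" or exclusion reason
    saccade_class: str  # "PS_correct" | "AS_correct" | "PE" | "none"
    srt: float | None = None
    express: bool = False
    corrected: bool | None = None
    first_event: SaccadeEvent | None = None
    correction_event: SaccadeEvent | None = None


def first_valid_saccade(trial: Trial, params: ClassifierParams = ClassifierParams()
                        ) -> tuple[SaccadeEvent | None, str]:
    """Find the first qualifying saccade after target onset.

    The earliest event with onset at/after target onset and horizontal
    amplitude >= ``min_amp`` is the candidate.  If its SRT falls below
    ``srt_min`` the trial is an anticipation and is invalidated; above
    ``srt_max`` it is too late.  Returns ``(event_or_None, reason)`` with
    reason in {"", "anticipation", "too_late", "no_saccade"}.
    """
    for ev in sorted(trial.events, key=lambda e: e.onset):
        if ev.onset < trial.target_onset or abs(ev.amp) < params.min_amp:
            continue
        srt = ev.onset - trial.target_onset
        if srt < params.srt_min:
            return None, "anticipation"
        if srt > params.srt_max:
            return None, "too_late"
        return ev, ""
    return None, "no_saccade"


def classify(trial: Trial, params: ClassifierParams = ClassifierParams()) -> TrialLabel:
    """Label a gated trial.

    Prosaccade task: a first saccade toward the target is correct; away
    is a task error and is excluded (too rare to analyse).  Antisaccade
    task: away is correct, toward is a prosaccade error ("PE").  Correct
    prosaccades with SRT in the express window are flagged express.  A
    first saccade whose direction cannot be resolved (|amp| below the tie
    threshold) excludes the trial.
    """
    first, why = first_valid_saccade(trial, params)
    if first is None:
        return TrialLabel(status="excluded", reason=why, saccade_class="none")
    if abs(first.amp) < params.direction_tie:
        return TrialLabel(status="excluded", reason="ambiguous_direction",
                          saccade_class="none")

    srt = first.onset - trial.target_onset
    toward = (first.amp > 0) == (trial.target_sign > 0)
    if trial.task == "PS":
        if not toward:
            return TrialLabel(status="excluded", reason="ps_direction_error",
                              saccade_class="none")
        express = params.express_min <= srt <= params.express_max
        return TrialLabel(status="valid", reason="none", saccade_class="PS_correct",
                          srt=srt, express=express, first_event=first)
    # antisaccade task
    if toward:
        label = TrialLabel(status="valid", reason="none", saccade_class="PE",
                           srt=srt, first_event=first)
        label.corrected = detect_correction(trial, label, params)
        return label
    return TrialLabel(status="valid", reason="none", saccade_class="AS_correct",
                      srt=srt, first_event=first)


def detect_correction(trial: Trial, label: TrialLabel,
                      params: ClassifierParams = ClassifierParams()) -> bool:
    """True iff a prosaccade error is followed by a corrective saccade.

    The corrective saccade must start within ``correction_window`` ms of
    the error's offset, move opposite to the target, and meet the same
    amplitude threshold as primary saccades.  Sets
    ``label.correction_event`` on success.
    """
    if label.saccade_class != "PE":
        raise ValueError("correction detection applies to PE trials only")
    err = label.first_event
    away_sign = -trial.target_sign
    for ev in sorted(trial.events, key=lambda e: e.onset):
        if ev.onset <= err.offset:
            continue
        if ev.onset - err.offset >= params.correction_window:
            break
        if abs(ev.amp) >= params.min_amp and (ev.amp > 0) == (away_sign > 0):
            label.correction_event = ev
            return True
    return False
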