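"""Gaze-file ingestion, saccade detection, and the trial-validity gate.

Domain types shared across the pipeline live here: :class:`SaccadeEvent`
and :class:`Trial`.  Gaze samples are carried as plain numpy record-style
dicts of arrays (``t`` ms, ``x``/``y`` deg, ``valid`` bool).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter


class ParseError(ValueError):
    """Malformed gaze file; message carries trial id and line number."""


@dataclass
class SaccadeEvent:
    """A detected (or simulated) saccade.

    ``amp`` is the signed horizontal displacement ``x_end - x_start`` in
    degrees (+ = rightward); ``peak_vel`` in deg/s is always positive.
    """

    onset: float
    offset: float
    amp: float
    peak_vel: float
    x_start: float
    x_end: float

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed onset")
        if self.peak_vel <= 0:
            raise ValueError("peak velocity must be positive")


@dataclass
class Trial:
    """One task trial: metadata plus samples and/or detected events."""

    child_id: str
    trial_id: int
    task: str  # "PS" | "AS"
    target_side: str  # "L" | "R"
    target_onset: float = 1000.0  # ms from trial start
    target_ecc: float = 8.0  # deg
    samples: dict | None = None  # {"t","x","y","valid"} arrays
    events: list[SaccadeEvent] = field(default_factory=list)
    blinks: list[tuple[float, float]] = field(default_factory=list)
    head_movement: bool = False  # external flag; not derivable from gaze
    pre_target_gaze: tuple[float, float] | None = None  # (x, y) mean, event-only trials

    def __post_init__(self):
        if self.task not in ("PS", "AS"):
            raise ValueError(f"task must be PS or AS, got {self.task!r}")
        if self.target_side not in ("L", "R"):
            raise ValueError(f"target_side must be L or R, got {self.target_side!r}")
        if self.target_ecc <= 0:
            raise ValueError("target eccentricity must be positive")

    @property
    def target_sign(self) -> float:
        """+1 for a rightward target, -1 for leftward."""
        return 1.0 if self.target_side == "R" else -1.0


@dataclass(frozen=True)
class DetectorParams:
    """Velocity-based detector settings (eye-tracker-parser-like defaults)."""

    vel_threshold: float = 30.0  # deg/s
    onset_threshold: float = 10.0  # deg/s; event bounds extend down to this
    acc_threshold: float = 8000.0  # deg/s^2
    min_duration_ms: float = 4.0
    min_amp: float = 0.3  # deg; drops jitter-induced micro-events
    smooth_window: int = 5  # odd sample count for the Savitzky-Golay window

    def __post_init__(self):
        if self.smooth_window % 2 == 0 or self.smooth_window < 3:
            raise ValueError("smooth_window must be an odd integer >= 3")


def _check_monotone(t: np.ndarray, trial_id, line_offset: int):
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        i = int(bad[0])
        raise ParseError(
            f"non-monotone timestamp in trial {trial_id} at line {line_offset + i + 1}"
            f" (t={t[i + 1]:g} after t={t[i]:g})"
        )


def read_gaze(path, dialect: str = "csv", meta_path=None) -> list[Trial]:
    """Read per-trial gaze samples from ``path``.

    Parameters
    ----------
    path : str or Path
        Sample file.  ``csv`` dialect expects columns
        ``trial_id,t_ms,x_deg,y_deg,valid_flag``; the ``asc-like`` dialect
        uses ``MSG <t> TRIALID <id> <task> <child_id>``,
        ``MSG <t> TARGET_ON <side>``, ``SBLINK <t>`` / ``EBLINK <t>``
        marker lines and ``<t> <x> <y>`` sample lines.
    dialect : {"csv", "asc-like"}
    meta_path : str or Path, optional
        Required for ``csv``: trial metadata CSV with columns
        ``trial_id,child_id,task,target_side,target_onset_ms,target_ecc_deg``
        (optional ``head_movement``).

    Raises
    ------
    ParseError
        Unknown dialect, missing metadata, or non-monotone timestamps
        (reported with trial id and line number).
    """
    if dialect == "csv":
        return _read_gaze_csv(path, meta_path)
    if dialect == "asc-like":
        return _read_gaze_asc(path)
    raise ParseError(f"unknown gaze dialect: {dialect!r}")


def _read_gaze_csv(path, meta_path) -> list[Trial]:
    if meta_path is None:
        raise ParseError("csv dialect requires a trial metadata file (meta_path)")
    meta = {}
    with open(meta_path, newline="") as fh:
        for row in csv.DictReader(fh):
            meta[int(row["trial_id"])] = row

    by_trial: dict[int, dict[str, list]] = {}
    first_line: dict[int, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                tid = int(row["trial_id"])
                rec = (float(row["t_ms"]), float(row["x_deg"]), float(row["y_deg"]),
                       int(row.get("valid_flag", 1)))
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"malformed sample row at line {lineno}: {exc}") from exc
            d = by_trial.setdefault(tid, {"t": [], "x": [], "y": [], "valid": []})
            if tid not in first_line:
                first_line[tid] = lineno
            d["t"].append(rec[0])
            d["x"].append(rec[1])
            d["y"].append(rec[2])
            d["valid"].append(bool(rec[3]))

    trials = []
    for tid, d in sorted(by_trial.items()):
        t = np.asarray(d["t"])
        _check_monotone(t, tid, first_line[tid])
        if tid not in meta:
            raise ParseError(f"trial {tid} present in samples but missing from metadata")
        m = meta[tid]
        trials.append(Trial(
            child_id=m["child_id"], trial_id=tid, task=m["task"],
            target_side=m["target_side"],
            target_onset=float(m.get("target_onset_ms", 1000.0)),
            target_ecc=float(m.get("target_ecc_deg", 8.0)),
            samples={"t": t, "x": np.asarray(d["x"]), "y": np.asarray(d["y"]),
                     "valid": np.asarray(d["valid"], dtype=bool)},
            head_movement=bool(int(m.get("head_movement", 0) or 0)),
        ))
    return trials


def _read_gaze_asc(path) -> list[Trial]:
    trials: list[Trial] = []
    cur = None
    cur_samples = None
    blink_open = None
    first_line = 0

    def _close(lineno):
        if cur is None:
            return
        t = np.asarray(cur_samples["t"])
        if t.size:
            _check_monotone(t, cur.trial_id, first_line)
            cur.samples = {
                "t": t, "x": np.asarray(cur_samples["x"]),
                "y": np.asarray(cur_samples["y"]),
                "valid": np.asarray(cur_samples["valid"], dtype=bool),
            }
        trials.append(cur)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if parts[0] == "MSG":
                if len(parts) >= 4 and parts[2] == "TRIALID":
                    _close(lineno)
                    tid = int(parts[3])
                    task = parts[4] if len(parts) > 4 else "PS"
                    child = parts[5] if len(parts) > 5 else "unknown"
                    cur = Trial(child_id=child, trial_id=tid, task=task,
                                target_side="R", target_onset=float(parts[1]))
                    cur_samples = {"t": [], "x": [], "y": [], "valid": []}
                    first_line = lineno
                elif len(parts) >= 4 and parts[2] == "TARGET_ON" and cur is not None:
                    cur.target_onset = float(parts[1])
                    cur.target_side = parts[3]
            elif parts[0] == "SBLINK":
                blink_open = float(parts[1])
            elif parts[0] == "EBLINK":
                if blink_open is not None and cur is not None:
                    cur.blinks.append((blink_open, float(parts[1])))
                blink_open = None
            else:
                if cur is None:
                    raise ParseError(f"sample before any TRIALID at line {lineno}")
                try:
                    t, x, y = float(parts[0]), float(parts[1]), float(parts[2])
                except (IndexError, ValueError) as exc:
                    raise ParseError(
                        f"malformed sample in trial {cur.trial_id} at line {lineno}"
                    ) from exc
                valid = blink_open is None and np.isfinite(x)
                cur_samples["t"].append(t)
                cur_samples["x"].append(x if valid else np.nan)
                cur_samples["y"].append(y if valid else np.nan)
                cur_samples["valid"].append(valid)
    _close(lineno + 1 if cur is not None else 0)

    # absolute timestamps -> trial-relative, matching the csv dialect
    for tr in trials:
        if tr.samples is not None:
            t0 = tr.samples["t"][0]
            tr.samples["t"] = tr.samples["t"] - t0
            tr.target_onset -= t0
            tr.blinks = [(a - t0, b - t0) for a, b in tr.blinks]
    return trials


def read_event_tables(trials_path, events_path) -> list[Trial]:
    """Build trials from pre-detected event tables (no raw samples).

    ``trials_path`` columns: ``trial_id,child_id,task,target_side,
    target_onset_ms,target_ecc_deg`` (optional ``head_movement``,
    ``blink_start_ms``/``blink_end_ms``, ``pre_gaze_x``/``pre_gaze_y``);
    ``events_path`` columns: ``trial_id,onset_ms,offset_ms,
    amp_deg_signed,peak_vel_dps`` (optional ``x_start_deg,x_end_deg``).
    """
    trials: dict[int, Trial] = {}
    with open(trials_path, newline="") as fh:
        for row in csv.DictReader(fh):
            tid = int(row["trial_id"])
            tr = Trial(child_id=row["child_id"], trial_id=tid, task=row["task"],
                       target_side=row["target_side"],
                       target_onset=float(row.get("target_onset_ms", 1000.0)),
                       target_ecc=float(row.get("target_ecc_deg", 8.0)),
                       head_movement=bool(int(row.get("head_movement", 0) or 0)))
            if row.get("blink_start_ms"):
                tr.blinks.append((float(row["blink_start_ms"]),
                                  float(row["blink_end_ms"])))
            if row.get("pre_gaze_x"):
                tr.pre_target_gaze = (float(row["pre_gaze_x"]),
                                      float(row.get("pre_gaze_y", 0) or 0))
            trials[tid] = tr
    with open(events_path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            tid = int(row["trial_id"])
            if tid not in trials:
                raise ParseError(f"event for unknown trial {tid} at line {lineno}")
            amp = float(row["amp_deg_signed"])
            x0 = float(row.get("x_start_deg", 0.0) or 0.0)
            trials[tid].events.append(SaccadeEvent(
                onset=float(row["onset_ms"]), offset=float(row["offset_ms"]),
                amp=amp, peak_vel=float(row["peak_vel_dps"]),
                x_start=x0, x_end=float(row.get("x_end_deg", x0 + amp) or x0 + amp)))
    for tr in trials.values():
        tr.events.sort(key=lambda e: e.onset)
    return [trials[k] for k in sorted(trials)]


def detect_saccades(samples: dict, params: DetectorParams = DetectorParams()
                    ) -> tuple[list[SaccadeEvent], list[tuple[float, float]], bool]:
    """Detect saccades in one trial's gaze samples.

    Velocity is a Savitzky-Golay smoothed derivative of horizontal
    position; an event is a maximal run of samples with ``|v| >=
    vel_threshold`` lasting at least ``min_duration_ms``.  Invalid
    (blink) samples split the trace into segments and are reported as
    blink intervals.

    Returns
    -------
    (events, blink_intervals, no_usable_samples)
        Events are disjoint and time-ordered.  ``no_usable_samples`` is
        True when every sample is invalid.
    """
    t = np.asarray(samples["t"], dtype=float)
    x = np.asarray(samples["x"], dtype=float)
    valid = np.asarray(samples.get("valid", np.isfinite(x)), dtype=bool)
    valid = valid & np.isfinite(x)
    if t.size < 10:
        raise ValueError("need at least 10 samples for detection")

    blinks = _invalid_intervals(t, valid)
    if not valid.any():
        return [], blinks, True

    events: list[SaccadeEvent] = []
    for seg in _valid_segments(valid):
        if seg.stop - seg.start < max(10, params.smooth_window):
            continue
        events.extend(_detect_in_segment(t[seg], x[seg], params))
    events.sort(key=lambda e: e.onset)
    return events, blinks, False


def _invalid_intervals(t, valid):
    iv = []
    start = None
    for i, ok in enumerate(valid):
        if not ok and start is None:
            start = i
        elif ok and start is not None:
            iv.append((float(t[start]), float(t[i - 1])))
            start = None
    if start is not None:
        iv.append((float(t[start]), float(t[-1])))
    return iv


def _valid_segments(valid):
    segs = []
    start = None
    for i, ok in enumerate(valid):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segs.append(slice(start, i))
            start = None
    if start is not None:
        segs.append(slice(start, len(valid)))
    return segs


def _detect_in_segment(t, x, params: DetectorParams) -> list[SaccadeEvent]:
    dt = float(np.median(np.diff(t)))
    w = min(params.smooth_window, x.size if x.size % 2 == 1 else x.size - 1)
    v = savgol_filter(x, w, polyorder=2, deriv=1, delta=dt / 1000.0)
    speed = np.abs(v)
    slow = speed < params.onset_threshold

    # hysteresis: a run over vel_threshold, extended out to onset_threshold
    bounds = []
    for seg in _valid_segments(speed >= params.vel_threshold):
        dur = t[seg.stop - 1] - t[seg.start]
        if dur < params.min_duration_ms:
            continue
        i0, i1 = seg.start, seg.stop - 1
        while i0 > 0 and not slow[i0 - 1]:
            i0 -= 1
        while i1 < speed.size - 1 and not slow[i1 + 1]:
            i1 += 1
        if bounds and i0 <= bounds[-1][1]:
            bounds[-1] = (bounds[-1][0], max(bounds[-1][1], i1))
        else:
            bounds.append((i0, i1))

    events = []
    for i0, i1 in bounds:
        amp = float(x[i1] - x[i0])
        pv = float(speed[i0:i1 + 1].max())
        if pv <= 0 or abs(amp) < params.min_amp:
            continue
        events.append(SaccadeEvent(
            onset=float(t[i0]), offset=float(t[i1]), amp=amp, peak_vel=pv,
            x_start=float(x[i0]), x_end=float(x[i1]),
        ))
    return events


def gate_trial(trial: Trial, fixation_radius: float = 1.5,
               fixation_window_ms: float = 50.0,
               blink_window_ms: float = 1000.0) -> tuple[bool, str]:
    """Trial validity gate: central fixation at target onset, no blinks.

    Excludes the trial when (a) mean gaze over the ``fixation_window_ms``
    before target onset lies farther than ``fixation_radius`` from the
    centre, (b) any blink overlaps ``[target_onset, target_onset +
    blink_window_ms]``, or (c) the external head-movement flag is set.

    Returns ``(passed, reason)`` with reason in
    {"none", "fixation_break", "blink", "head_movement", "no_usable_samples"}.
    """
    if trial.head_movement:
        return False, "head_movement"

    on = trial.target_onset
    blinks = list(trial.blinks)
    if trial.samples is not None:
        t = np.asarray(trial.samples["t"], dtype=float)
        x = np.asarray(trial.samples["x"], dtype=float)
        y = np.asarray(trial.samples.get("y", np.zeros_like(x)), dtype=float)
        valid = np.asarray(trial.samples.get("valid", np.isfinite(x)), dtype=bool)
        valid = valid & np.isfinite(x)
        if not valid.any():
            return False, "no_usable_samples"
        blinks = blinks + _invalid_intervals(t, valid)
        pre = (t >= on - fixation_window_ms) & (t < on) & valid
        if pre.any():
            r = float(np.hypot(np.nanmean(x[pre]), np.nanmean(y[pre])))
            if r > fixation_radius:
                return False, "fixation_break"
    elif trial.pre_target_gaze is not None:
        r = float(np.hypot(*trial.pre_target_gaze))
        if r > fixation_radius:
            return False, "fixation_break"

    for b0, b1 in blinks:
        if b0 <= on + blink_window_ms and b1 >= on:
            return False, "blink"
    return True, "none"
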