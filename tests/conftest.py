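import numpy as np
import pytest

from saccadetools.event_processing import SaccadeEvent, Trial
from saccadetools.synthetic_cohort import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, clean cohort: no blinks or fixation breaks."""
    return SimConfig(n_per_group=(6, 3, 3), trials_per_task=12,
                     blink_rate=0.0, fixation_break_rate=0.0, seed=11)


@pytest.fixture
def trial_factory():
    """Build an event-level trial: events given as (srt_ms, amp) or
    (srt_ms, amp, duration_ms) tuples relative to target onset."""

    def make(task="PS", side="R", events=(), target_onset=1000.0, **kw):
        evs = []
        for spec in events:
            srt, amp = spec[0], spec[1]
            dur = spec[2] if len(spec) > 2 else 40.0
            onset = target_onset + srt
            evs.append(SaccadeEvent(onset=onset, offset=onset + dur, amp=amp,
                                    peak_vel=30.0 * abs(amp) + 100.0,
                                    x_start=0.0, x_end=amp))
        return Trial(child_id="c0", trial_id=0, task=task, target_side=side,
                     target_onset=target_onset, events=evs, **kw)

    return make
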