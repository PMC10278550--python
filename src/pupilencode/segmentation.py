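"""Sampling-event segmentation with the 100-ms hysteresis rule.

A sampling event is a left-screen visit that lasts through the trial's
delay so the model is actually presented. Gaze is binarized at the screen
midline (left = ``[0, midline)``, right = ``[midline, width]``, so a sample
exactly at the midline is right); excursions to the opposite half shorter
than the hysteresis threshold do not end the current visit. Blink samples
inherit the current side so blinks never split an event. All intervals are
half-open ``[enter, leave)`` in integer milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import (
    AnalysisConfig,
    GeometryConfig,
    SampleSeries,
    SamplingEvent,
    TrialRecord,
)

__all__ = [
    "Visit",
    "detect_visits",
    "segment_sampling_events",
    "compute_dwell",
    "compute_build",
    "filter_events",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Visit:
    side: str  # "L" or "R"
    t_enter: int
    t_leave: int  # exclusive

    @property
    def duration_ms(self) -> int:
        return self.t_leave - self.t_enter


def _sides(s: SampleSeries, g: GeometryConfig) -> np.ndarray:
    """Left/right per sample; invalid samples inherit the current side."""
    left = s.gaze_x < g.midline_x
    side = np.where(left, 0, 1).astype(np.int8)
    invalid = ~s.valid
    if invalid.any():
        idx = np.arange(len(side))
        # forward-fill from the last valid sample
        last_valid = np.where(s.valid, idx, -1)
        np.maximum.accumulate(last_valid, out=last_valid)
        filled = np.where(last_valid >= 0, side[np.maximum(last_valid, 0)], -1)
        # leading invalid run: inherit the first valid side
        first_valid = int(np.argmax(s.valid)) if s.valid.any() else 0
        filled = np.where(filled == -1, side[first_valid], filled)
        side = filled.astype(np.int8)
    return side


def detect_visits(
    s: SampleSeries, g: GeometryConfig, hysteresis_ms: int = 100
) -> list[Visit]:
    """Partition the recording into alternating left/right visits.

    An opposite-half run shorter than ``hysteresis_ms`` is absorbed into
    the current visit; a run of at least ``hysteresis_ms`` ends it. The
    returned visits tile the recording exactly.
    """
    if hysteresis_ms <= 0:
        raise ValueError("hysteresis_ms must be positive")
    if len(s) == 0:
        raise ValueError("empty sample series")
    side = _sides(s, g)
    t = s.time
    end_time = int(t[-1]) + 1  # nominal 1-ms step past the last sample
    # run-length encode
    change = np.flatnonzero(np.diff(side)) + 1
    starts = np.concatenate(([0], change))
    run_sides = side[starts]
    run_t = t[starts]
    run_ends = np.concatenate((run_t[1:], [end_time]))

    visits: list[Visit] = []
    cur_side = int(run_sides[0])
    cur_start = int(run_t[0])
    for i in range(1, len(starts)):
        rs = int(run_sides[i])
        if rs == cur_side:
            continue
        dur = int(run_ends[i]) - int(run_t[i])
        if dur >= hysteresis_ms:
            visits.append(Visit("L" if cur_side == 0 else "R", cur_start, int(run_t[i])))
            cur_side = rs
            cur_start = int(run_t[i])
        # shorter runs are absorbed: the current visit continues
    visits.append(Visit("L" if cur_side == 0 else "R", cur_start, end_time))
    return visits


def compute_dwell(
    t_model_onset: int,
    t_visit_start: int,
    t_visit_end: int,
    trial: TrialRecord,
    cfg: AnalysisConfig,
) -> int:
    """Dwell: from the reference point to the start of the first sustained
    right-side period (= the visit's end, by hysteresis construction),
    truncated at trial end."""
    ref = t_model_onset if cfg.dwell_reference == "model_onset" else t_visit_start
    dwell_end = min(t_visit_end, trial.t_end)
    return max(dwell_end - ref, 0)


def compute_build(
    t_dwell_end: int,
    visits: Sequence[Visit],
    trial: TrialRecord,
    cfg: AnalysisConfig,
) -> tuple[int, str]:
    """Build: from dwell end to the first sustained left return or trial end.

    Sustained (>= hysteresis) left periods are exactly the left visits, so
    the build ends at the next left visit's start inside the trial.
    """
    for v in visits:
        if v.side == "L" and t_dwell_end < v.t_enter < trial.t_end:
            return v.t_enter - t_dwell_end, "gaze-return"
    return max(trial.t_end - t_dwell_end, 0), "trial-end"


def segment_sampling_events(
    s: SampleSeries,
    trials: Sequence[TrialRecord],
    cfg: AnalysisConfig | None = None,
    g: GeometryConfig | None = None,
) -> list[SamplingEvent]:
    """Detect all sampling events for one recording.

    A left visit produces an event iff its overlap with the trial covers at
    least the trial's delay (the model onset occurred); shorter left visits
    are aborted samples and yield nothing. The delay timer does not carry
    over between visits.
    """
    cfg = cfg or AnalysisConfig()
    g = g or GeometryConfig()
    visits = detect_visits(s, g, cfg.hysteresis_ms)
    my_trials = [t for t in trials if t.participant_id == s.participant_id]
    events: list[SamplingEvent] = []
    for trial in my_trials:
        overlapping = [
            v
            for v in visits
            if v.side == "L" and v.t_leave > trial.t_start and v.t_enter < trial.t_end
        ]
        if not overlapping and not any(
            v.t_leave > trial.t_start and v.t_enter < trial.t_end for v in visits
        ):
            logger.warning(
                "trial %s/%s has no samples", trial.participant_id, trial.trial_id
            )
            continue
        idx = 0
        for v in overlapping:
            eff_start = max(v.t_enter, trial.t_start)
            eff_end = min(v.t_leave, trial.t_end)
            delay = trial.condition_delay_ms
            if eff_end - eff_start < delay:
                continue  # aborted: the model never appeared
            t_onset = eff_start + delay
            dwell = compute_dwell(t_onset, eff_start, v.t_leave, trial, cfg)
            t_dwell_end = min(v.t_leave, trial.t_end)
            build, ended_by = compute_build(t_dwell_end, visits, trial, cfg)
            events.append(
                SamplingEvent(
                    participant_id=s.participant_id,
                    trial_id=trial.trial_id,
                    event_index=idx,
                    t_visit_start=eff_start,
                    t_model_onset=t_onset,
                    dwell_ms=dwell,
                    build_ms=build,
                    ended_by=ended_by,
                )
            )
            idx += 1
    events.sort(key=lambda e: e.t_visit_start)
    return events


def filter_events(
    events: Sequence[SamplingEvent],
    trials: Sequence[TrialRecord],
    cfg: AnalysisConfig | None = None,
) -> tuple[list[SamplingEvent], dict[str, int]]:
    """Apply the trial-level inclusion rules.

    Drops events from trials where any item was misplaced and events from
    delay conditions outside ``included_conditions_ms`` (by default the
    200-ms condition, whose dwells are too short for pupil estimates).
    Returns the retained events and a drop-reason tally.
    """
    cfg = cfg or AnalysisConfig()
    by_key = {(t.participant_id, t.trial_id): t for t in trials}
    kept: list[SamplingEvent] = []
    drops = {"incorrect-trial": 0, "condition": 0}
    for e in events:
        trial = by_key.get((e.participant_id, e.trial_id))
        if trial is None:
            raise KeyError(
                f"event references unknown trial {e.participant_id}/{e.trial_id}"
            )
        if not trial.all_correct:
            drops["incorrect-trial"] += 1
            continue
        if trial.condition_delay_ms not in cfg.included_conditions_ms:
            drops["condition"] += 1
            continue
        kept.append(e)
    logger.info("filter_events: kept %d, dropped %s", len(kept), drops)
    return kept, drops
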