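"""Synthetic copy-task and continuous-report generators with planted effects.

Every stage of the pipeline is testable at desk scale because the generator
returns the ground truth it planted: event boundaries, dwell and build
durations, per-event baselines and constriction amplitudes, and the linear
coefficients tying them together.

The copy task emulates a two-screen layout: the to-be-copied model sits in
the left half behind a delay gate, the response grid in the right half.
A trial is a sequence of sampling events — a left visit that survives the
delay (model onset), a dwell, then a right-side build period. The pupil
trace is a per-event tonic baseline plus an event-locked constriction
kernel plus white noise; blinks (pupil 0, invalid) and sub-100-ms gaze
"flickers" to the opposite half are injected at configurable rates.

Planted build duration follows the linear model

    build = b0 + b1*baseline + b2*|amplitude| + b3*dwell + cond + u_p + e

with a participant random intercept ``u_p`` and condition offset for the
long delay, floored at 0.1 s (durations are physical).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GeometryConfig, SampleSeries, TrialRecord

__all__ = [
    "KernelParams",
    "CopySimParams",
    "PrecisionSimParams",
    "pupil_kernel",
    "simulate_copy_task",
    "simulate_copy_events",
    "simulate_precision_task",
    "GenerationError",
]


class GenerationError(ValueError):
    """Raised for infeasible simulation timing or invalid parameters."""


#: gaze-filter window used when planting ``in_roi`` ground truth (half-open)
INCLUSION_WINDOW_MS = 1000


@dataclass(frozen=True)
class KernelParams:
    """Timing and amplitude of the pupil orienting-constriction kernel.

    The constriction begins ``onset_latency_ms`` after model onset, reaches
    its most negative point at ``time_to_trough_ms`` and returns to zero by
    ``recovery_end_ms`` (a raised-cosine dip; only timing and amplitude
    matter for median-window features). ``amplitude`` is negative for a
    constriction and is drawn per event by the generators.
    """

    onset_latency_ms: int = 250
    time_to_trough_ms: int = 650
    recovery_end_ms: int = 1000
    amplitude: float = -60.0

    def __post_init__(self) -> None:
        if not (0 <= self.onset_latency_ms < self.time_to_trough_ms < self.recovery_end_ms):
            raise GenerationError("kernel timing must satisfy onset < trough < end")
        if not np.isfinite(self.amplitude):
            raise GenerationError("kernel amplitude must be finite")


def pupil_kernel(t_ms, k: KernelParams):
    """Evaluate the constriction kernel at ``t_ms`` after model onset.

    Returns 0 before ``onset_latency_ms``, ``k.amplitude`` exactly at
    ``time_to_trough_ms``, and 0 at and after ``recovery_end_ms``.
    Accepts scalars or arrays; negative times map to 0.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    up = (t >= k.onset_latency_ms) & (t < k.time_to_trough_ms)
    down = (t >= k.time_to_trough_ms) & (t < k.recovery_end_ms)
    rise = (t[up] - k.onset_latency_ms) / (k.time_to_trough_ms - k.onset_latency_ms)
    out[up] = k.amplitude * 0.5 * (1.0 - np.cos(np.pi * rise))
    fall = (t[down] - k.time_to_trough_ms) / (k.recovery_end_ms - k.time_to_trough_ms)
    out[down] = k.amplitude * 0.5 * (1.0 + np.cos(np.pi * fall))
    out[t == k.time_to_trough_ms] = k.amplitude
    if np.isscalar(t_ms):
        return float(out)
    return out


@dataclass(frozen=True)
class CopySimParams:
    """Study conditions for the copy-task simulator.

    Defaults follow the study design: 24 participants (split half/half
    between the two stimulus-set experiments), 35 trials per delay
    condition, delays of 200/1500/3000 ms, and planted coefficients on the
    scales the analysis reports (durations in seconds, pupil in a.u.).
    """

    n_participants: int = 24
    n_trials_per_condition: int = 35
    delays_ms: tuple[int, ...] = (200, 1500, 3000)
    events_per_trial: tuple[int, int] = (2, 4)  # inclusive uniform range
    kernel: KernelParams = field(default_factory=KernelParams)
    amplitude_sd: float = 15.0
    baseline_mean: float = 3000.0
    baseline_sd_between: float = 300.0  # across participants
    baseline_sd_within: float = 150.0  # across events within participant
    baseline_exp2_offset: float = 1312.68  # darker stimuli dilate the pupil in E2
    # planted linear model for build duration (seconds)
    intercept: float = -1.0  # b0
    effect_baseline: float = 0.0009  # b1, s per a.u.
    effect_orienting: float = 0.003  # b2, s per a.u. (experiment 1)
    effect_orienting_exp2: float = 0.0001
    effect_dwell: float = 0.10  # b3, s per s (experiment 1)
    effect_dwell_exp2: float = 0.19
    effect_condition: float = 0.33  # s, long vs medium
    participant_sd: float = 0.3  # s
    residual_sd: float = 0.4  # s
    # planted dwell distribution (seconds)
    dwell_mean_s: float = 1.0
    dwell_sd_s: float = 0.5
    dwell_condition_effect_s: float = 1.64  # long vs medium
    dwell_short_s: float = 0.3  # mean dwell in the 200-ms condition
    # nuisance processes
    pupil_noise_sd: float = 4.0
    gaze_jitter_px: float = 8.0
    blink_rate_hz: float = 0.08  # blinks per second
    blink_dur_ms: tuple[int, int] = (80, 250)
    flicker_rate_hz: float = 0.05  # sub-100-ms opposite-half excursions
    flicker_dur_ms: tuple[int, int] = (30, 80)
    p_abort: float = 0.1  # extra left visits shorter than the delay
    p_roi_violation: float = 0.0  # events whose gaze leaves the model ROI
    p_all_correct: float = 0.8863  # trial-level correct-placement rate
    iti_ms: int = 500
    lead_right_ms: int = 300
    build_floor_s: float = 0.1

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials_per_condition < 1:
            raise GenerationError("counts must be >= 1")
        if self.events_per_trial[0] < 1 or self.events_per_trial[0] > self.events_per_trial[1]:
            raise GenerationError("events_per_trial range invalid")
        for sd in (self.amplitude_sd, self.baseline_sd_between, self.baseline_sd_within,
                   self.participant_sd, self.residual_sd, self.pupil_noise_sd,
                   self.gaze_jitter_px):
            if sd < 0:
                raise GenerationError("standard deviations must be >= 0")
        if min(self.delays_ms) <= 0:
            raise GenerationError("delays must be positive")

    def noiseless(self) -> "CopySimParams":
        """A copy with all nuisance variability removed (for oracle tests)."""
        return dataclasses.replace(
            self,
            pupil_noise_sd=0.0,
            gaze_jitter_px=0.0,
            blink_rate_hz=0.0,
            flicker_rate_hz=0.0,
            residual_sd=0.0,
            p_abort=0.0,
        )


def _experiment_of(i: int, n: int) -> int:
    return 1 if i < (n + 1) // 2 else 2


def _draw_amplitude(rng: np.random.Generator, mean: float, sd: float) -> float:
    # constrictions only: keep amplitudes strictly negative
    return -abs(rng.normal(mean, sd))


def simulate_copy_task(
    p: CopySimParams,
    g: GeometryConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, SampleSeries], list[TrialRecord], pd.DataFrame]:
    """Generate 1000-Hz recordings, trial records and ground truth.

    Returns ``(series_by_participant, trials, ground_truth)``. The ground
    truth table lists every planted sampling event with its boundaries,
    dwell, build, baseline, constriction amplitude and inclusion status —
    the oracle against which segmentation and feature extraction are
    checked.
    """
    g = g or GeometryConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    roi = g.model_grid_roi
    left_fix = ((roi[0] + roi[2]) / 2.0, (roi[1] + roi[3]) / 2.0)
    right_fix = ((g.midline_x + g.screen_width_px) / 2.0, g.screen_height_px / 2.0)
    margin_px = 2.0 * g.px_per_degree
    # a left-half point outside the expanded ROI (for planted filter violations)
    viol_x = min(roi[2] + margin_px + 60.0, g.midline_x - 20.0)
    if viol_x <= roi[2] + margin_px:
        viol_x = roi[0] - margin_px - 60.0
        if viol_x < 0:
            raise GenerationError("geometry leaves no room for ROI violations")
    viol_fix = (viol_x, left_fix[1])

    series: dict[str, SampleSeries] = {}
    trials: list[TrialRecord] = []
    gt_rows: list[dict] = []

    for ip in range(p.n_participants):
        pid = f"p{ip + 1:02d}"
        exp = _experiment_of(ip, p.n_participants)
        part_baseline = rng.normal(
            p.baseline_mean + (p.baseline_exp2_offset if exp == 2 else 0.0),
            p.baseline_sd_between,
        )
        u_p = rng.normal(0.0, p.participant_sd)
        b2 = p.effect_orienting if exp == 1 else p.effect_orienting_exp2
        b3 = p.effect_dwell if exp == 1 else p.effect_dwell_exp2

        delays = np.repeat(p.delays_ms, p.n_trials_per_condition)
        rng.shuffle(delays)

        gx_parts: list[np.ndarray] = []
        gy_parts: list[np.ndarray] = []
        tonic_parts: list[np.ndarray] = []
        kernel_onsets: list[tuple[int, float]] = []  # (t_onset, amplitude)
        flicker_windows: list[tuple[int, int]] = []  # absolute ms, right-side patches
        cursor = 0

        def emit(duration_ms: int, fix: tuple[float, float], tonic: float) -> None:
            nonlocal cursor
            n = int(duration_ms)
            if n <= 0:
                return
            gx_parts.append(np.full(n, fix[0]))
            gy_parts.append(np.full(n, fix[1]))
            tonic_parts.append(np.full(n, tonic))
            cursor += n

        for it, delay in enumerate(delays):
            delay = int(delay)
            trial_id = it + 1
            all_correct = bool(rng.random() < p.p_all_correct)
            n_events = int(rng.integers(p.events_per_trial[0], p.events_per_trial[1] + 1))
            t_start = cursor
            # per-event plants
            ev_baseline = rng.normal(part_baseline, p.baseline_sd_within, n_events)
            ev_amp = np.array(
                [_draw_amplitude(rng, abs(p.kernel.amplitude), p.amplitude_sd) for _ in range(n_events)]
            )
            if delay == 200:
                dwell_mean = p.dwell_short_s
            else:
                dwell_mean = p.dwell_mean_s + (
                    p.dwell_condition_effect_s if delay == 3000 else 0.0
                )
            ev_dwell_s = np.maximum(rng.normal(dwell_mean, p.dwell_sd_s, n_events), 0.15)
            cond_off = p.effect_condition if delay == 3000 else 0.0
            ev_build_s = np.maximum(
                p.intercept
                + p.effect_baseline * ev_baseline
                + b2 * np.abs(ev_amp)
                + b3 * ev_dwell_s
                + cond_off
                + u_p
                + rng.normal(0.0, p.residual_sd, n_events),
                p.build_floor_s,
            )

            emit(p.lead_right_ms, right_fix, ev_baseline[0])
            for ie in range(n_events):
                tonic = ev_baseline[ie]
                if rng.random() < p.p_abort:
                    # aborted sample: leaves before the delay elapses, no event
                    abort_ms = int(delay * rng.uniform(0.2, 0.8))
                    if abort_ms >= 1:
                        emit(abort_ms, left_fix, tonic)
                        emit(max(p.lead_right_ms, 150), right_fix, tonic)
                dwell_ms = int(round(ev_dwell_s[ie] * 1000))
                build_ms = int(round(ev_build_s[ie] * 1000))
                t_visit = cursor
                t_onset = t_visit + delay
                violated = rng.random() < p.p_roi_violation and dwell_ms >= 700
                if violated:
                    # stay in the left half but leave the expanded ROI mid-window
                    pre, out = 200, min(400, dwell_ms - 200)
                    emit(delay + pre, left_fix, tonic)
                    emit(out, viol_fix, tonic)
                    emit(dwell_ms - pre - out, left_fix, tonic)
                else:
                    emit(delay + dwell_ms, left_fix, tonic)
                # gaze stays on the model grid for the whole (half-open)
                # 1000-ms inclusion window iff the dwell covers it
                in_roi = (not violated) and dwell_ms >= INCLUSION_WINDOW_MS
                # flickers: short right excursions inside the left visit,
                # kept clear of the model-onset inclusion window and edges
                if p.flicker_rate_hz > 0:
                    visit_ms = delay + dwell_ms
                    n_fl = rng.poisson(p.flicker_rate_hz * visit_ms / 1000.0)
                    for _ in range(n_fl):
                        fl_dur = int(rng.integers(*p.flicker_dur_ms))
                        lo, hi = 150, delay - 160 - fl_dur
                        if hi <= lo:
                            continue
                        fl_start = t_visit + int(rng.integers(lo, hi))
                        flicker_windows.append((fl_start, fl_start + fl_dur))
                last = ie == n_events - 1
                emit(build_ms, right_fix, tonic)
                kernel_onsets.append((t_onset, ev_amp[ie]))
                gt_rows.append(
                    {
                        "participant": pid,
                        "trial": trial_id,
                        "event_index": ie,
                        "condition_delay_ms": delay,
                        "experiment": exp,
                        "all_correct": all_correct,
                        "t_visit_start": t_visit,
                        "t_model_onset": t_onset,
                        "dwell_ms": dwell_ms,
                        "build_ms": build_ms,
                        "ended_by": "trial-end" if last else "gaze-return",
                        "baseline": ev_baseline[ie],
                        "amplitude": ev_amp[ie],
                        "dwell_s": ev_dwell_s[ie],
                        "build_s": ev_build_s[ie],
                        "in_roi": in_roi,
                    }
                )
            t_end = cursor
            trials.append(
                TrialRecord(pid, trial_id, delay, exp, all_correct, t_start, t_end)
            )
            emit(p.iti_ms, right_fix, ev_baseline[-1])

        n_total = cursor
        time = np.arange(n_total, dtype=np.int64)
        gaze_x = np.concatenate(gx_parts)
        gaze_y = np.concatenate(gy_parts)
        pupil = np.concatenate(tonic_parts)
        for t_onset, amp in kernel_onsets:
            k = dataclasses.replace(p.kernel, amplitude=amp)
            hi = min(t_onset + k.recovery_end_ms, n_total)
            if hi <= t_onset:
                continue
            tt = np.arange(0, hi - t_onset, dtype=float)
            pupil[t_onset:hi] += pupil_kernel(tt, k)
        for a, b in flicker_windows:
            gaze_x[a:b] = right_fix[0]
            gaze_y[a:b] = right_fix[1]
        if p.gaze_jitter_px > 0:
            gaze_x = gaze_x + rng.normal(0.0, p.gaze_jitter_px, n_total)
            gaze_y = gaze_y + rng.normal(0.0, p.gaze_jitter_px, n_total)
        if p.pupil_noise_sd > 0:
            pupil = pupil + rng.normal(0.0, p.pupil_noise_sd, n_total)
        valid = np.ones(n_total, dtype=bool)
        if p.blink_rate_hz > 0:
            n_blinks = rng.poisson(p.blink_rate_hz * n_total / 1000.0)
            for _ in range(n_blinks):
                start = int(rng.integers(0, n_total))
                dur = int(rng.integers(*p.blink_dur_ms))
                valid[start : start + dur] = False
        pupil[~valid] = 0.0
        series[pid] = SampleSeries(pid, pid, time, gaze_x, gaze_y, pupil, valid)

    gt = pd.DataFrame(gt_rows)
    return series, trials, gt


def simulate_copy_events(
    p: CopySimParams, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw the planted event table directly, without sample-level synthesis.

    Produces the same linear structure as :func:`simulate_copy_task` at the
    level the mixed models consume (one row per sampling event, medium and
    long conditions). Used for replicate studies — parameter recovery and
    type-I calibration — where synthesizing 1000-Hz streams adds nothing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delays = [d for d in p.delays_ms if d in (1500, 3000)]
    if not delays:
        raise GenerationError("no medium/long delay conditions to simulate")
    events_mean = (p.events_per_trial[0] + p.events_per_trial[1]) / 2.0
    n_ev = int(round(p.n_trials_per_condition * events_mean))
    rows = []
    for ip in range(p.n_participants):
        pid = f"p{ip + 1:02d}"
        exp = _experiment_of(ip, p.n_participants)
        part_baseline = rng.normal(
            p.baseline_mean + (p.baseline_exp2_offset if exp == 2 else 0.0),
            p.baseline_sd_between,
        )
        u_p = rng.normal(0.0, p.participant_sd)
        b2 = p.effect_orienting if exp == 1 else p.effect_orienting_exp2
        b3 = p.effect_dwell if exp == 1 else p.effect_dwell_exp2
        for delay in delays:
            baseline = rng.normal(part_baseline, p.baseline_sd_within, n_ev)
            amp = np.abs(rng.normal(abs(p.kernel.amplitude), p.amplitude_sd, n_ev))
            dwell_mean = p.dwell_mean_s + (
                p.dwell_condition_effect_s if delay == 3000 else 0.0
            )
            dwell = np.maximum(rng.normal(dwell_mean, p.dwell_sd_s, n_ev), 0.15)
            cond_off = p.effect_condition if delay == 3000 else 0.0
            build = np.maximum(
                p.intercept
                + p.effect_baseline * baseline
                + b2 * amp
                + b3 * dwell
                + cond_off
                + u_p
                + rng.normal(0.0, p.residual_sd, n_ev),
                p.build_floor_s,
            )
            for i in range(n_ev):
                rows.append(
                    {
                        "participant": pid,
                        "experiment": exp,
                        "condition_delay_ms": delay,
                        "baseline_pupil": baseline[i],
                        "orienting_amplitude": amp[i],
                        "dwell_ms": dwell[i] * 1000.0,
                        "build_ms": build[i] * 1000.0,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrecisionSimParams:
    """Study conditions for the continuous-report precision simulator.

    Defaults approximate the reanalyzed dataset's scale (about 7200 trials
    over 20 participants, set sizes 1–4, prototypical/non-prototypical
    colors). Planted coefficients use the analysis scales: response error
    in degrees, pupil in a.u.; ``effect_orienting`` multiplies constriction
    *magnitude*, so a negative value plants "stronger constriction, smaller
    error".
    """

    n_participants: int = 20
    n_trials: int = 360  # per participant
    set_sizes: tuple[int, ...] = (1, 2, 3, 4)
    p_prototypical: float = 0.5
    # intercept and noise keep the [0, 180] truncation mass negligible so
    # planted slopes survive the clip (mean errors ~20-45 deg, as typical
    # for continuous colour report)
    intercept_deg: float = 15.0
    effect_setsize: float = 5.78  # degrees per item
    effect_baseline: float = 0.002  # degrees per a.u.
    effect_orienting: float = -0.004  # degrees per a.u. of constriction magnitude
    noise_sd_deg: float = 9.0
    participant_sd_deg: float = 3.0
    baseline_mean: float = 3000.0
    baseline_sd_between: float = 300.0
    baseline_sd_within: float = 150.0
    kernel: KernelParams = field(default_factory=KernelParams)
    amplitude_sd: float = 15.0
    pupil_noise_sd: float = 2.0
    epoch_ms: tuple[int, int] = (-100, 2000)
    # optional planted time-course effect: pupil offset per precision-group
    # index (precise=0 … imprecise=2) confined to a window after onset
    group_effect_au: float = 0.0
    group_effect_window_ms: tuple[int, int] = (500, 1000)

    def __post_init__(self) -> None:
        if not set(self.set_sizes) <= {1, 2, 3, 4}:
            raise GenerationError("set sizes must lie in {1..4}")
        if self.n_participants < 1 or self.n_trials < 1:
            raise GenerationError("counts must be >= 1")


def simulate_precision_task(
    p: PrecisionSimParams,
    seed: int | np.random.Generator = 0,
    bin_edges_deg: tuple[float, float] = (15.0, 30.0),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate continuous-report trials with per-trial pupil traces.

    Returns ``(trials, traces, t_rel)``: a trial table holding the planted
    ground truth (set size, prototypicality, baseline, amplitude, response
    error, precision group) and a ``(n_trials_total, n_samples)`` pupil
    trace array on the 1-ms grid ``t_rel``. Response error is

        a0 + b_ss*set_size + b_base*baseline + b_orient*|amplitude| + u_p + e

    truncated to [0, 180] degrees.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_rel = np.arange(p.epoch_ms[0], p.epoch_ms[1] + 1, dtype=np.int64)
    rows = []
    traces = np.empty((p.n_participants * p.n_trials, len(t_rel)))
    kern_unit = pupil_kernel(np.clip(t_rel, 0, None).astype(float), dataclasses.replace(p.kernel, amplitude=1.0))
    kern_unit[t_rel < 0] = 0.0
    lo_edge, hi_edge = bin_edges_deg
    win = p.group_effect_window_ms
    win_mask = (t_rel >= win[0]) & (t_rel < win[1])  # half-open, like all intervals
    i = 0
    for ip in range(p.n_participants):
        pid = f"p{ip + 1:02d}"
        part_baseline = rng.normal(p.baseline_mean, p.baseline_sd_between)
        u_p = rng.normal(0.0, p.participant_sd_deg)
        for it in range(p.n_trials):
            set_size = int(rng.choice(p.set_sizes))
            proto = bool(rng.random() < p.p_prototypical)
            baseline = rng.normal(part_baseline, p.baseline_sd_within)
            amp = -abs(rng.normal(abs(p.kernel.amplitude), p.amplitude_sd))
            err = (
                p.intercept_deg
                + p.effect_setsize * set_size
                + p.effect_baseline * baseline
                + p.effect_orienting * abs(amp)
                + u_p
                + rng.normal(0.0, p.noise_sd_deg)
            )
            err = float(np.clip(err, 0.0, 180.0))
            group = (
                "precise" if err <= lo_edge else "intermediate" if err <= hi_edge else "imprecise"
            )
            trace = baseline + amp * kern_unit
            if p.group_effect_au != 0.0:
                gidx = {"precise": 0, "intermediate": 1, "imprecise": 2}[group]
                trace = trace + np.where(win_mask, p.group_effect_au * gidx, 0.0)
            if p.pupil_noise_sd > 0:
                trace = trace + rng.normal(0.0, p.pupil_noise_sd, len(t_rel))
            traces[i] = trace
            rows.append(
                {
                    "participant": pid,
                    "trial": it + 1,
                    "set_size": set_size,
                    "prototypical": proto,
                    "baseline": baseline,
                    "amplitude": amp,
                    "response_error": err,
                    "precision_group": group,
                }
            )
            i += 1
    return pd.DataFrame(rows), traces, t_rel
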