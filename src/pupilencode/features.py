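"""Per-event pupil metrics: baseline, orienting amplitude, control metric,
gaze-deviation inclusion filter and robust z-scores.

All metrics are medians or extrema over fixed windows relative to model
onset: baseline is the median over ``[-100, 0)`` ms; the orienting
amplitude is the (sign-flipped) median of the baseline-corrected trace
over ``[500, 1000]`` ms, so positive values mean a stronger constriction;
the control metric is max over ``[0, 300]`` minus min over ``[500, 1000]``.
A metric is absent when fewer than half of the window's samples were
actually measured (blinks interpolated away do not count as measured).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    AnalysisConfig,
    GeometryConfig,
    PupilEpoch,
    SampleSeries,
    SamplingEvent,
)

__all__ = [
    "preprocess_pupil",
    "extract_epoch",
    "baseline_size",
    "baseline_correct",
    "orienting_amplitude",
    "orienting_signed_median",
    "orienting_control",
    "gaze_inclusion",
    "robust_z",
    "annotate_events",
]


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where valid is False."""
    padded = np.concatenate(([True], valid, [True]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == -1)
    stops = np.flatnonzero(diff == 1)
    return list(zip(starts, stops))


def preprocess_pupil(s: SampleSeries, pad_ms: int | None = None) -> SampleSeries:
    """Linearly interpolate blink/track-loss runs with padding.

    Each invalid run is widened by ``pad_ms`` samples on both sides (the
    pupil trace is deformed around a blink, not only inside it) and the
    widened span is replaced by the line between its valid neighbors.
    Runs touching either edge of the recording have no anchor and stay
    invalid. Interpolated samples are valid but flagged ``reconstructed``.
    """
    if pad_ms is None:
        pad_ms = AnalysisConfig().interp_pad_ms
    if not s.valid.any():
        raise ValueError(f"{s.recording_id}: all samples invalid, nothing to anchor on")
    n = len(s)
    to_fill = np.zeros(n, dtype=bool)
    edge = np.zeros(n, dtype=bool)
    for start, stop in _invalid_runs(s.valid):
        a = start - pad_ms
        b = stop + pad_ms
        if a < 0 or b > n:
            edge[max(a, 0) : min(b, n)] = True
        else:
            to_fill[a:b] = True
    to_fill &= ~edge
    pupil = s.pupil.copy()
    valid = s.valid.copy()
    recon = np.zeros(n, dtype=bool)
    if to_fill.any():
        anchors = ~to_fill & ~edge & s.valid
        # padding may abut another blink's padding; anchor on what remains
        idx = np.arange(n)
        pupil[to_fill] = np.interp(idx[to_fill], idx[anchors], pupil[anchors])
        valid[to_fill] = True
        recon[to_fill] = True
    valid[edge] = False
    return SampleSeries(
        s.participant_id, s.recording_id, s.time, s.gaze_x, s.gaze_y, pupil, valid, recon
    )


def extract_epoch(
    s: SampleSeries, t_onset: int, t_min: int = -100, t_max: int = 1000
) -> PupilEpoch:
    """Cut an onset-locked epoch covering ``[t_min, t_max]`` ms (closed)."""
    lo = int(np.searchsorted(s.time, t_onset + t_min, side="left"))
    hi = int(np.searchsorted(s.time, t_onset + t_max, side="right"))
    if lo >= hi:
        raise ValueError(f"epoch [{t_min}, {t_max}] around t={t_onset} is empty")
    sl = slice(lo, hi)
    return PupilEpoch(
        t_rel=s.time[sl] - t_onset,
        pupil=s.pupil[sl],
        valid=s.valid[sl],
        measured=s.measured[sl],
    )


def _window_median(
    e: PupilEpoch, lo: int, hi: int, closed: bool, min_fraction: float
) -> float | None:
    mask = e.window_mask(lo, hi, closed=closed)
    if not mask.any():
        return None
    measured_frac = float(np.mean(e.measured[mask]))
    if measured_frac < min_fraction:
        return None
    use = mask & e.valid
    if not use.any():
        return None
    return float(np.median(e.pupil[use]))


def baseline_size(e: PupilEpoch, cfg: AnalysisConfig | None = None) -> float | None:
    """Median pupil size over the pre-onset baseline window ``[-100, 0)``."""
    cfg = cfg or AnalysisConfig()
    a, b = cfg.baseline_window_ms
    return _window_median(e, a, b, closed=False, min_fraction=cfg.min_valid_fraction)


def baseline_correct(e: PupilEpoch, b: float) -> PupilEpoch:
    """Subtract the baseline from the whole epoch (subtractive correction)."""
    return PupilEpoch(e.t_rel, e.pupil - b, e.valid, e.measured)


def orienting_signed_median(
    e: PupilEpoch, cfg: AnalysisConfig | None = None
) -> float | None:
    """Median of the corrected trace over the orienting window (signed)."""
    cfg = cfg or AnalysisConfig()
    a, b = cfg.orienting_window_ms
    return _window_median(e, a, b, closed=True, min_fraction=cfg.min_valid_fraction)


def orienting_amplitude(
    e: PupilEpoch, cfg: AnalysisConfig | None = None
) -> float | None:
    """Constriction magnitude: minus the orienting-window median.

    Positive when the pupil constricted below baseline, so regression
    coefficients read "stronger orienting response, longer build".
    """
    m = orienting_signed_median(e, cfg)
    return None if m is None else -m


def orienting_control(
    e: PupilEpoch, cfg: AnalysisConfig | None = None
) -> float | None:
    """Control metric: max over [0, 300] minus min over [500, 1000] ms.

    Insensitive to the small pre-constriction dilation that the median
    amplitude could fold in; positive when the pupil falls.
    """
    cfg = cfg or AnalysisConfig()
    a0, b0 = cfg.control_early_window_ms
    a1, b1 = cfg.orienting_window_ms
    early = e.window_mask(a0, b0) & e.valid
    late = e.window_mask(a1, b1) & e.valid
    min_fr = cfg.min_valid_fraction
    for mask, win in ((e.window_mask(a0, b0), (a0, b0)), (e.window_mask(a1, b1), (a1, b1))):
        if not mask.any() or float(np.mean(e.measured[mask])) < min_fr:
            return None
    if not early.any() or not late.any():
        return None
    return float(np.max(e.pupil[early]) - np.min(e.pupil[late]))


def gaze_inclusion(
    s: SampleSeries,
    event: SamplingEvent,
    g: GeometryConfig | None = None,
    cfg: AnalysisConfig | None = None,
) -> bool:
    """Gaze-deviation filter: did gaze stay on the model grid after onset?

    True iff every valid sample in the half-open window
    ``[onset, onset + inclusion_window_ms)`` lies inside the model-grid ROI
    expanded by ``inclusion_margin_deg`` on all sides (closed boundary).
    With ``inclusion_continuous=False`` the criterion instead requires the
    cumulative in-ROI time to reach the window length (permitting brief
    interruptions within a longer stay).
    """
    g = g or GeometryConfig()
    cfg = cfg or AnalysisConfig()
    margin = cfg.inclusion_margin_deg * g.px_per_degree
    x0, y0, x1, y1 = g.model_grid_roi
    x0, y0, x1, y1 = x0 - margin, y0 - margin, x1 + margin, y1 + margin
    t0 = event.t_model_onset
    if cfg.inclusion_continuous:
        lo = int(np.searchsorted(s.time, t0, side="left"))
        hi = int(np.searchsorted(s.time, t0 + cfg.inclusion_window_ms, side="left"))
    else:
        lo, hi = 0, len(s)
    sl = slice(lo, hi)
    v = s.valid[sl]
    inside = (
        (s.gaze_x[sl] >= x0)
        & (s.gaze_x[sl] <= x1)
        & (s.gaze_y[sl] >= y0)
        & (s.gaze_y[sl] <= y1)
    )
    if cfg.inclusion_continuous:
        return bool(np.all(inside[v])) if v.any() else False
    after = s.time >= t0
    return int(np.sum(inside & s.valid & after)) >= cfg.inclusion_window_ms


def robust_z(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray | None = None
) -> np.ndarray:
    """Robust z-scores: subtract the median, divide by the unscaled MAD.

    With ``groups`` given, centering and scaling are per participant. The
    output has median 0 and MAD 1 within each group. A zero MAD (fewer than
    two distinct values) raises, naming the participant.
    """
    x = np.asarray(values, dtype=float)
    if groups is None:
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            raise ValueError("MAD is zero: values are (nearly) constant")
        return (x - med) / mad
    groups = np.asarray(groups)
    out = np.empty_like(x)
    for gval in pd.unique(groups):
        m = groups == gval
        med = np.median(x[m])
        mad = np.median(np.abs(x[m] - med))
        if mad == 0:
            raise ValueError(f"MAD is zero for participant {gval!r}")
        out[m] = (x[m] - med) / mad
    return out


def trace_features(
    traces: np.ndarray, t_rel: np.ndarray, cfg: AnalysisConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and orienting magnitude for a stack of onset-locked traces.

    Vectorized equivalent of ``baseline_size`` + ``baseline_correct`` +
    ``orienting_amplitude`` for fully valid traces (one row per trial):
    subtracting the baseline commutes with the window median, so the
    orienting magnitude is ``-(median_orienting - baseline)``.
    """
    cfg = cfg or AnalysisConfig()
    a, b = cfg.baseline_window_ms
    base_mask = (t_rel >= a) & (t_rel < b)
    a, b = cfg.orienting_window_ms
    or_mask = (t_rel >= a) & (t_rel <= b)
    baseline = np.median(traces[:, base_mask], axis=1)
    orienting = -(np.median(traces[:, or_mask], axis=1) - baseline)
    return baseline, orienting


def annotate_events(
    s: SampleSeries,
    events: list[SamplingEvent],
    cfg: AnalysisConfig | None = None,
    g: GeometryConfig | None = None,
    preprocess: bool = True,
) -> list[SamplingEvent]:
    """Fill pupil metrics and the gaze filter flag on each event (in place).

    The series is blink-interpolated first unless ``preprocess=False``.
    Events whose windows are unusable keep ``None`` metrics; they are
    flagged, never dropped here.
    """
    cfg = cfg or AnalysisConfig()
    g = g or GeometryConfig()
    sp = preprocess_pupil(s, cfg.interp_pad_ms) if preprocess else s
    lo = min(cfg.baseline_window_ms[0], 0)
    hi = max(cfg.orienting_window_ms[1], cfg.inclusion_window_ms)
    for e in events:
        if e.participant_id != s.participant_id:
            continue
        epoch = extract_epoch(sp, e.t_model_onset, lo, hi)
        b = baseline_size(epoch, cfg)
        e.baseline_pupil = b
        if b is not None:
            corrected = baseline_correct(epoch, b)
            e.orienting_signed = orienting_signed_median(corrected, cfg)
            e.orienting_amplitude = (
                None if e.orienting_signed is None else -e.orienting_signed
            )
            e.orienting_control = orienting_control(corrected, cfg)
        e.included_gaze_filter = gaze_inclusion(sp, e, g, cfg)
    return events
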