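"""Readers and writers for the pipeline's tabular formats.

The canonical interchange formats are plain TSV/CSV tables:

* sample table: ``time_ms, gaze_x, gaze_y, pupil[, valid]``
* trial table:  ``participant, trial, condition_delay_ms, experiment,
  all_correct, t_start, t_end``
* event table:  one row per :class:`~pupilencode.types.SamplingEvent`

A minimal EyeLink ASC subset (numeric sample lines plus SBLINK/EBLINK
markers) is supported for sample streams; it is not a full ASC parser.
Configuration is a flat YAML file mapping 1:1 onto
:class:`~pupilencode.types.GeometryConfig` and
:class:`~pupilencode.types.AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    GeometryConfig,
    SampleSeries,
    SampleSeriesError,
    SamplingEvent,
    TrialRecord,
)

__all__ = [
    "read_samples",
    "write_samples",
    "read_trials",
    "write_trials",
    "read_events",
    "write_events",
    "load_config",
    "save_config",
    "ParseError",
    "ValidationError",
]

EVENT_COLUMNS = [
    "participant",
    "trial",
    "event_index",
    "t_visit_start",
    "t_model_onset",
    "dwell_ms",
    "build_ms",
    "ended_by",
    "included_gaze_filter",
    "baseline_pupil",
    "orienting_amplitude",
    "orienting_signed",
    "orienting_control",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain constraint."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _check_numeric(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if df[c].isna().any() or bad.any():
            # +2: header line plus 1-based numbering
            row = int((df[c].isna() | bad).idxmax())
            raise ParseError(f"{path}: malformed value in column '{c}' at line {row + 2}")
        df[c] = coerced


def read_samples(
    path: str | Path,
    dialect: str = "plain-table",
    participant_id: str | None = None,
    recording_id: str | None = None,
) -> SampleSeries:
    """Read a gaze/pupil sample stream.

    ``dialect`` is ``"plain-table"`` (TSV/CSV) or ``"eyelink-asc-subset"``.
    Samples with pupil size 0 or a recorder blink flag get ``valid=False``
    (EyeLink emits 0 pupil during blinks); they are kept in the stream,
    never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pid = participant_id or path.stem
    rid = recording_id or path.stem
    if dialect == "plain-table":
        df = _read_table(path, ["gaze_x", "gaze_y", "pupil"])
        tcol = "time_ms" if "time_ms" in df.columns else "time"
        if tcol not in df.columns:
            raise ParseError(f"{path}: missing time column (time_ms or time)")
        _check_numeric(df, [tcol, "gaze_x", "gaze_y", "pupil"], path)
        time = df[tcol].to_numpy(dtype=np.int64)
        if np.any(np.diff(time) <= 0):
            i = int(np.argmax(np.diff(time) <= 0)) + 1
            raise ParseError(f"{path}: time not strictly increasing at line {i + 2}")
        pupil = df["pupil"].to_numpy(dtype=float)
        if "valid" in df.columns:
            valid = df["valid"].astype(bool).to_numpy()
        else:
            valid = np.ones(len(df), dtype=bool)
        valid = valid & (pupil > 0)
        return SampleSeries(pid, rid, time, df["gaze_x"].to_numpy(float),
                            df["gaze_y"].to_numpy(float), pupil, valid)
    if dialect == "eyelink-asc-subset":
        return _read_asc_subset(path, pid, rid)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_asc_subset(path: Path, pid: str, rid: str) -> SampleSeries:
    """Parse numeric sample lines plus SBLINK/EBLINK markers from an ASC file.

    Sample lines are ``<time> <x> <y> <pupil>``; missing fields appear as a
    dot. EBLINK gives the blink span ``<start> <end>``; both endpoints are
    marked invalid (inclusive span, matching the recorder's convention).
    """
    times: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    ps: list[float] = []
    blink_spans: list[tuple[int, int]] = []
    open_blink: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "SBLINK":
                open_blink = int(tok[-1])
                continue
            if tok[0] == "EBLINK":
                try:
                    start, end = int(tok[-2]), int(tok[-1])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: malformed EBLINK at line {lineno}") from exc
                blink_spans.append((start, end))
                open_blink = None
                continue
            if tok[0][0].isdigit():
                try:
                    t = int(tok[0])
                    x = float("nan") if tok[1] == "." else float(tok[1])
                    y = float("nan") if tok[2] == "." else float(tok[2])
                    p = 0.0 if tok[3] == "." else float(tok[3])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: malformed sample at line {lineno}") from exc
                times.append(t)
                xs.append(x)
                ys.append(y)
                ps.append(p)
            # any other line (MSG, EFIX, ...) is outside the subset: ignored
    if not times:
        raise ParseError(f"{path}: no sample lines found")
    time = np.asarray(times, dtype=np.int64)
    if np.any(np.diff(time) <= 0):
        raise ParseError(f"{path}: sample times not strictly increasing")
    pupil = np.asarray(ps, dtype=float)
    valid = (pupil > 0) & ~np.isnan(xs) & ~np.isnan(ys)
    if open_blink is not None:
        blink_spans.append((open_blink, int(time[-1])))
    for start, end in blink_spans:
        valid[(time >= start) & (time <= end)] = False
    gx = np.nan_to_num(np.asarray(xs, dtype=float))
    gy = np.nan_to_num(np.asarray(ys, dtype=float))
    return SampleSeries(pid, rid, time, gx, gy, pupil, valid)


def write_samples(series: SampleSeries, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ms": series.time,
            "gaze_x": series.gaze_x,
            "gaze_y": series.gaze_y,
            "pupil": series.pupil,
            "valid": series.valid.astype(int),
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


TRIAL_COLUMNS = [
    "participant",
    "trial",
    "condition_delay_ms",
    "experiment",
    "all_correct",
    "t_start",
    "t_end",
]


def read_trials(
    path: str | Path, cfg: AnalysisConfig | None = None
) -> list[TrialRecord]:
    """Read the trial table; validates delays and per-participant overlap."""
    path = Path(path)
    cfg = cfg or AnalysisConfig()
    df = _read_table(path, TRIAL_COLUMNS)
    _check_numeric(df, ["condition_delay_ms", "experiment", "t_start", "t_end"], path)
    records = [
        TrialRecord(
            participant_id=str(r.participant),
            trial_id=int(r.trial),
            condition_delay_ms=int(r.condition_delay_ms),
            experiment=int(r.experiment),
            all_correct=bool(int(r.all_correct)),
            t_start=int(r.t_start),
            t_end=int(r.t_end),
        )
        for r in df.itertuples()
    ]
    for rec in records:
        if rec.condition_delay_ms not in cfg.delay_conditions_ms:
            raise ValidationError(
                f"{path}: unknown delay {rec.condition_delay_ms} ms in trial "
                f"{rec.trial_id} (allowed: {sorted(cfg.delay_conditions_ms)})"
            )
    records.sort(key=lambda r: (r.participant_id, r.t_start))
    prev: dict[str, TrialRecord] = {}
    for rec in records:
        p = prev.get(rec.participant_id)
        if p is not None and rec.t_start < p.t_end:
            raise ValidationError(
                f"{path}: trials {p.trial_id} and {rec.trial_id} overlap for "
                f"participant {rec.participant_id}"
            )
        prev[rec.participant_id] = rec
    return records


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "participant": t.participant_id,
                "trial": t.trial_id,
                "condition_delay_ms": t.condition_delay_ms,
                "experiment": t.experiment,
                "all_correct": int(t.all_correct),
                "t_start": t.t_start,
                "t_end": t.t_end,
            }
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_events(events: Sequence[SamplingEvent], path: str | Path) -> None:
    """Write the event table; round-trips bit-exactly through read_events."""
    path = Path(path)
    rows = [e.as_dict() for e in events]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def read_events(path: str | Path) -> list[SamplingEvent]:
    path = Path(path)
    df = _read_table(path, EVENT_COLUMNS)
    out = []
    for r in df.itertuples():
        inc = r.included_gaze_filter
        if not pd.isna(inc) and not isinstance(inc, (bool, np.bool_)):
            inc = str(inc).strip().lower() == "true"  # mixed column read as text
        out.append(
            SamplingEvent(
                participant_id=str(r.participant),
                trial_id=int(r.trial),
                event_index=int(r.event_index),
                t_visit_start=int(r.t_visit_start),
                t_model_onset=int(r.t_model_onset),
                dwell_ms=int(r.dwell_ms),
                build_ms=None if pd.isna(r.build_ms) else int(r.build_ms),
                ended_by=str(r.ended_by),
                included_gaze_filter=None if pd.isna(inc) else bool(inc),
                baseline_pupil=_opt_float(r.baseline_pupil),
                orienting_amplitude=_opt_float(r.orienting_amplitude),
                orienting_signed=_opt_float(r.orienting_signed),
                orienting_control=_opt_float(r.orienting_control),
            )
        )
    return out


_GEOM_FIELDS = {f.name for f in dataclasses.fields(GeometryConfig)}
_ANALYSIS_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}
_TUPLE_FIELDS = {
    "model_grid_roi",
    "baseline_window_ms",
    "orienting_window_ms",
    "control_early_window_ms",
    "precision_bin_edges_deg",
}
_SET_FIELDS = {"delay_conditions_ms", "included_conditions_ms"}


def load_config(
    path: str | Path, strict: bool = False
) -> tuple[GeometryConfig, AnalysisConfig]:
    """Load a flat YAML config into (GeometryConfig, AnalysisConfig).

    Unknown keys raise; omitted keys take the documented defaults unless
    ``strict`` is set (the pipeline requires a complete config so that a
    run manifest is self-contained), in which case missing keys raise
    before any computation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    if strict:
        missing = sorted((_GEOM_FIELDS | _ANALYSIS_FIELDS) - set(raw))
        if missing:
            raise ValidationError(f"{path}: missing config keys {missing}")
    geom_kwargs: dict = {}
    ana_kwargs: dict = {}
    for key, value in raw.items():
        if key in _TUPLE_FIELDS:
            value = tuple(value)
        elif key in _SET_FIELDS:
            value = frozenset(int(v) for v in value)
        if key in _GEOM_FIELDS:
            geom_kwargs[key] = value
        elif key in _ANALYSIS_FIELDS:
            ana_kwargs[key] = value
        else:
            raise ValidationError(f"{path}: unknown config key {key!r}")
    return GeometryConfig(**geom_kwargs), AnalysisConfig(**ana_kwargs)


def save_config(geom: GeometryConfig, cfg: AnalysisConfig, path: str | Path) -> None:
    data: dict = {}
    for obj in (geom, cfg):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, frozenset):
                v = sorted(v)
            elif isinstance(v, tuple):
                v = list(v)
            data[f.name] = v
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
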