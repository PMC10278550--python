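"""Core data containers for the copy-task pupillometry pipeline.

Conventions used throughout the package:

* time is integer milliseconds sampled nominally at 1000 Hz;
* gaze coordinates are screen pixels, origin top-left, x rightward
  (EyeLink convention); degrees of visual angle enter only through
  ``GeometryConfig.px_per_degree``;
* pupil size is kept in the recorder's arbitrary units (a.u.) end to end —
  regression coefficients involving pupil size are per-a.u.;
* intervals are half-open ``[enter, leave)`` unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SampleSeries",
    "GeometryConfig",
    "AnalysisConfig",
    "TrialRecord",
    "SamplingEvent",
    "PupilEpoch",
    "FitResult",
    "SampleSeriesError",
]


class SampleSeriesError(ValueError):
    """Raised when a sample stream violates its invariants."""


@dataclass
class SampleSeries:
    """A uniformly sampled gaze/pupil stream for one recording.

    ``valid`` is False for blink / track-loss samples. ``reconstructed``
    (set by :func:`pupilencode.features.preprocess_pupil`) marks samples
    whose pupil value was replaced by interpolation; such samples are
    usable (``valid`` True) but were not measured.
    """

    participant_id: str
    recording_id: str
    time: np.ndarray  # int ms, strictly increasing
    gaze_x: np.ndarray  # px
    gaze_y: np.ndarray  # px
    pupil: np.ndarray  # a.u.
    valid: np.ndarray  # bool
    reconstructed: Optional[np.ndarray] = None  # bool

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.reconstructed is not None:
            self.reconstructed = np.asarray(self.reconstructed, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.time)
        for name in ("gaze_x", "gaze_y", "pupil", "valid"):
            if len(getattr(self, name)) != n:
                raise SampleSeriesError(
                    f"array length mismatch: {name} has {len(getattr(self, name))}"
                    f" samples, time has {n}"
                )
        if n == 0:
            raise SampleSeriesError("empty sample series")
        if np.any(np.diff(self.time) <= 0):
            i = int(np.argmax(np.diff(self.time) <= 0))
            raise SampleSeriesError(f"time not strictly increasing at index {i + 1}")
        if np.any(self.pupil[self.valid] <= 0):
            raise SampleSeriesError("non-positive pupil size on a valid sample")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def measured(self) -> np.ndarray:
        """Samples that are valid and were actually recorded (not interpolated)."""
        if self.reconstructed is None:
            return self.valid
        return self.valid & ~self.reconstructed


@dataclass(frozen=True)
class GeometryConfig:
    """Screen geometry needed to operationalize screen halves and ROI margins."""

    screen_width_px: int = 1920
    screen_height_px: int = 1080
    midline_x: int = 960
    # model grid ROI as (x0, y0, x1, y1) in px, inclusive bounds
    model_grid_roi: tuple[float, float, float, float] = (280.0, 290.0, 780.0, 790.0)
    px_per_degree: float = 35.0

    def __post_init__(self) -> None:
        if not (0 < self.midline_x < self.screen_width_px):
            raise ValueError("midline_x must lie strictly inside the screen")
        if self.px_per_degree <= 0:
            raise ValueError("px_per_degree must be positive")
        x0, y0, x1, y1 = self.model_grid_roi
        if not (0 <= x0 < x1 <= self.screen_width_px and 0 <= y0 < y1 <= self.screen_height_px):
            raise ValueError("model_grid_roi must lie within the screen")


@dataclass(frozen=True)
class AnalysisConfig:
    """All fixed analysis constants in one place.

    Windows are milliseconds relative to model onset. The baseline window is
    half-open ``[-100, 0)``; the orienting window is closed ``[500, 1000]``.
    """

    hysteresis_ms: int = 100
    baseline_window_ms: tuple[int, int] = (-100, 0)  # half-open [a, b)
    orienting_window_ms: tuple[int, int] = (500, 1000)  # closed [a, b]
    control_early_window_ms: tuple[int, int] = (0, 300)  # closed, for the control metric
    inclusion_window_ms: int = 1000
    inclusion_margin_deg: float = 2.0
    delay_conditions_ms: frozenset[int] = frozenset({200, 1500, 3000})
    included_conditions_ms: frozenset[int] = frozenset({1500, 3000})
    t_threshold: float = 1.96
    timecourse_bin_ms: int = 10
    precision_bin_edges_deg: tuple[float, float] = (15.0, 30.0)
    # paper-gap knobs (see docs/methods.md)
    dwell_reference: str = "model_onset"  # or "visit_start"
    inclusion_continuous: bool = True  # continuous containment vs cumulative time
    interp_pad_ms: int = 50
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.hysteresis_ms <= 0:
            raise ValueError("hysteresis_ms must be positive")
        for name in ("baseline_window_ms", "orienting_window_ms", "control_early_window_ms"):
            a, b = getattr(self, name)
            if a >= b:
                raise ValueError(f"{name} is empty: {(a, b)}")
        lo, hi = self.precision_bin_edges_deg
        if not lo < hi:
            raise ValueError("precision_bin_edges_deg must be ascending")
        if self.dwell_reference not in ("model_onset", "visit_start"):
            raise ValueError("dwell_reference must be 'model_onset' or 'visit_start'")
        if not self.included_conditions_ms <= self.delay_conditions_ms:
            raise ValueError("included_conditions_ms must be a subset of delay_conditions_ms")


@dataclass(frozen=True)
class TrialRecord:
    """One copy-task trial: condition, experiment, correctness and time bounds."""

    participant_id: str
    trial_id: int
    condition_delay_ms: int
    experiment: int
    all_correct: bool
    t_start: int  # ms
    t_end: int  # ms, exclusive

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError(
                f"trial {self.trial_id}: t_start {self.t_start} >= t_end {self.t_end}"
            )
        if self.experiment not in (1, 2):
            raise ValueError(f"experiment must be 1 or 2, got {self.experiment}")


@dataclass
class SamplingEvent:
    """One left-screen visit that culminated in model presentation.

    ``dwell_ms`` runs from the dwell reference point (model onset by default)
    to the start of the first sustained right-side period; ``build_ms`` runs
    from dwell end to the first sustained left return or trial end.
    Pupil metrics are absent (None) until features are computed, and remain
    absent when their window had too few measured samples.
    """

    participant_id: str
    trial_id: int
    event_index: int
    t_visit_start: int
    t_model_onset: int
    dwell_ms: int
    build_ms: Optional[int]
    ended_by: str  # "gaze-return" | "trial-end"
    included_gaze_filter: Optional[bool] = None
    baseline_pupil: Optional[float] = None
    orienting_amplitude: Optional[float] = None
    orienting_signed: Optional[float] = None
    orienting_control: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dwell_ms < 0:
            raise ValueError("dwell_ms must be >= 0")
        if self.build_ms is not None and self.build_ms < 0:
            raise ValueError("build_ms must be >= 0 when present")
        if self.ended_by not in ("gaze-return", "trial-end"):
            raise ValueError(f"unknown ended_by: {self.ended_by}")

    def as_dict(self) -> dict:
        return {
            "participant": self.participant_id,
            "trial": self.trial_id,
            "event_index": self.event_index,
            "t_visit_start": self.t_visit_start,
            "t_model_onset": self.t_model_onset,
            "dwell_ms": self.dwell_ms,
            "build_ms": self.build_ms,
            "ended_by": self.ended_by,
            "included_gaze_filter": self.included_gaze_filter,
            "baseline_pupil": self.baseline_pupil,
            "orienting_amplitude": self.orienting_amplitude,
            "orienting_signed": self.orienting_signed,
            "orienting_control": self.orienting_control,
        }


@dataclass
class PupilEpoch:
    """A pupil trace locked to model/stimulus onset (1-ms grid).

    ``t_rel`` is time relative to onset; ``valid`` marks usable samples
    (including interpolated ones); ``measured`` marks originally recorded
    samples, used for the per-window validity threshold.
    """

    t_rel: np.ndarray  # int ms
    pupil: np.ndarray  # a.u.
    valid: np.ndarray  # bool
    measured: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, dtype=np.int64)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.measured is None:
            self.measured = self.valid.copy()
        else:
            self.measured = np.asarray(self.measured, dtype=bool)

    def window_mask(self, lo: int, hi: int, closed: bool = True) -> np.ndarray:
        if closed:
            return (self.t_rel >= lo) & (self.t_rel <= hi)
        return (self.t_rel >= lo) & (self.t_rel < hi)


@dataclass
class FitResult:
    """A fitted mixed-model summary.

    ``coefficients`` maps fixed-effect term names to ``(beta, se, t)``;
    ``significant`` flags ``|t| > t_threshold`` (normal approximation, no
    df correction). ``aic`` is comparable across candidates only when the
    fits used maximum likelihood on identical observations.
    """

    formula: str
    coefficients: dict[str, tuple[float, float, float]]
    significant: dict[str, bool]
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str = "reml"

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def beta(self, term: str) -> float:
        return self.coefficients[term][0]

    def se(self, term: str) -> float:
        return self.coefficients[term][1]

    def tvalue(self, term: str) -> float:
        return self.coefficients[term][2]

    def conf_int(self, term: str, z: float = 1.96) -> tuple[float, float]:
        b, s, _ = self.coefficients[term]
        return (b - z * s, b + z * s)


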