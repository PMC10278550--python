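"""Mixed-effects model stack for the copy-task and precision analyses.

All models are linear mixed-effects fits with participant-level random
intercepts and random slopes for the delay condition (or the set-size ×
prototypicality design in the precision analyses), estimated with
statsmodels ``MixedLM``. Significance uses the normal approximation
``|t| > 1.96`` with no degrees-of-freedom correction. REML is used for
reported fits; maximum likelihood when AICs are compared across
fixed-effect structures.

Scale conventions: durations enter in seconds, pupil metrics in raw
recorder units (a.u.), so coefficients are directly comparable across
datasets recorded on the same device.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .types import AnalysisConfig, FitResult, SamplingEvent, TrialRecord

__all__ = [
    "DegenerateFitError",
    "events_to_frame",
    "fit_condition_model",
    "fit_build_model",
    "fit_per_experiment",
    "aic_select",
    "assign_precision_groups",
    "make_timecourse_frame",
    "timecourse_lme",
    "TimecourseResult",
    "fit_precision_trial_model",
    "validate_build_proxy",
]

logger = logging.getLogger(__name__)

CONDITION_LABELS = {200: "short", 1500: "medium", 3000: "long"}
_OUTCOME_COLUMNS = {
    "dwell": "dwell_s",
    "build": "build_s",
    "baseline": "baseline_pupil",
    "orienting": "orienting_amplitude",
}


class DegenerateFitError(ValueError):
    """Raised when the outcome carries no usable variance."""


def events_to_frame(
    events: Sequence[SamplingEvent], trials: Sequence[TrialRecord]
) -> pd.DataFrame:
    """Event table on analysis scales: durations in s, condition labelled."""
    by_key = {(t.participant_id, t.trial_id): t for t in trials}
    rows = []
    for e in events:
        t = by_key[(e.participant_id, e.trial_id)]
        rows.append(
            {
                "participant": e.participant_id,
                "trial": e.trial_id,
                "condition": CONDITION_LABELS.get(
                    t.condition_delay_ms, str(t.condition_delay_ms)
                ),
                "condition_delay_ms": t.condition_delay_ms,
                "experiment": t.experiment,
                "dwell_s": e.dwell_ms / 1000.0,
                "build_s": None if e.build_ms is None else e.build_ms / 1000.0,
                "baseline_pupil": e.baseline_pupil,
                "orienting_amplitude": e.orienting_amplitude,
                "orienting_control": e.orienting_control,
                "included_gaze_filter": e.included_gaze_filter,
            }
        )
    df = pd.DataFrame(rows)
    return _with_condition_categories(df)


def _with_condition_categories(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    present = [c for c in ("medium", "long", "short") if c in set(df["condition"])]
    df["condition"] = pd.Categorical(df["condition"], categories=present)
    return df


def _clean_term(term: str) -> str:
    term = re.sub(r"C\((\w+)[^)]*\)", r"\1", term)
    term = re.sub(r"\[T\.([^\]]+)\]", r"[\1]", term)
    return term


def _fit_mixedlm(
    formula: str,
    data: pd.DataFrame,
    re_formula: str,
    groups: str = "participant",
    reml: bool = True,
    t_threshold: float = 1.96,
) -> FitResult:
    y_col = formula.split("~")[0].strip()
    y = pd.to_numeric(data[y_col], errors="coerce")
    if float(np.nanvar(y)) < 1e-12:
        raise DegenerateFitError(f"outcome '{y_col}' is (nearly) constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        fit = model.fit(reml=reml)
        if not fit.converged:
            # same model, different optimizers; the random structure is
            # never simplified behind the caller's back
            for method in ("lbfgs", "cg", "powell"):
                try:
                    retry = model.fit(reml=reml, method=method)
                except Exception:
                    continue
                if retry.converged:
                    fit = retry
                    break
    fe = fit.fe_params
    bse = fit.bse[fe.index]
    tv = fit.tvalues[fe.index]
    coefficients = {
        _clean_term(term): (float(fe[term]), float(bse[term]), float(tv[term]))
        for term in fe.index
    }
    significant = {k: abs(v[2]) > t_threshold for k, v in coefficients.items()}
    k_params = len(fit.params)  # fixed effects + covariance parameters
    aic = float(-2.0 * fit.llf + 2.0 * k_params)
    return FitResult(
        formula=f"{formula} + ({re_formula.lstrip('~')}|{groups})",
        coefficients=coefficients,
        significant=significant,
        aic=aic,
        n_obs=int(fit.nobs),
        n_groups=int(data[groups].nunique()),
        converged=bool(fit.converged),
        method="reml" if reml else "ml",
    )


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")


def fit_condition_model(
    events: pd.DataFrame,
    outcome: str,
    cfg: AnalysisConfig | None = None,
    reml: bool = True,
) -> FitResult:
    """Condition contrast: ``outcome ~ condition + experiment`` with a
    participant random intercept and condition slope.

    ``outcome`` is one of ``dwell``, ``build``, ``baseline``, ``orienting``.
    """
    cfg = cfg or AnalysisConfig()
    col = _OUTCOME_COLUMNS.get(outcome, outcome)
    _require_columns(events, [col, "condition", "experiment", "participant"])
    data = events.dropna(subset=[col]).copy()
    if data["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    if data["condition"].nunique() < 2:
        raise ValueError("need both delay conditions present")
    data = _with_condition_categories(data)
    return _fit_mixedlm(
        f"{col} ~ condition + C(experiment)",
        data,
        re_formula="~condition",
        reml=reml,
        t_threshold=cfg.t_threshold,
    )


BUILD_FEATURES = ["baseline_pupil", "orienting_amplitude", "dwell_s", "build_s"]


def fit_build_model(
    events: pd.DataFrame, cfg: AnalysisConfig | None = None, reml: bool = True
) -> FitResult:
    """Trial-level encoding-depth model across both experiments:

    ``build ~ baseline×experiment + orienting×experiment + dwell×experiment
    + condition`` with ``(1 + condition | participant)``.
    """
    cfg = cfg or AnalysisConfig()
    _require_columns(events, BUILD_FEATURES + ["condition", "experiment", "participant"])
    data = events.dropna(subset=BUILD_FEATURES).copy()
    if data["experiment"].nunique() < 2:
        raise ValueError("both experiments must be present; use fit_per_experiment")
    data = _with_condition_categories(data)
    return _fit_mixedlm(
        "build_s ~ baseline_pupil * C(experiment) + orienting_amplitude * C(experiment)"
        " + dwell_s * C(experiment) + condition",
        data,
        re_formula="~condition",
        reml=reml,
        t_threshold=cfg.t_threshold,
    )


def fit_per_experiment(
    events: pd.DataFrame,
    experiment: int,
    cfg: AnalysisConfig | None = None,
    reml: bool = True,
) -> FitResult:
    """Follow-up model within one experiment (no interaction terms)."""
    cfg = cfg or AnalysisConfig()
    _require_columns(events, BUILD_FEATURES + ["condition", "experiment", "participant"])
    data = events[events["experiment"] == experiment].dropna(subset=BUILD_FEATURES).copy()
    if len(data) == 0:
        raise ValueError(f"no events for experiment {experiment}")
    data = _with_condition_categories(data)
    return _fit_mixedlm(
        "build_s ~ baseline_pupil + orienting_amplitude + dwell_s + condition",
        data,
        re_formula="~condition",
        reml=reml,
        t_threshold=cfg.t_threshold,
    )


def aic_select(candidates: Sequence[FitResult]) -> FitResult:
    """Pick the candidate with minimal AIC; ties go to fewer parameters.

    Candidates must be fit on identical observations (checked via n_obs);
    the result does not depend on the order of the candidates.
    """
    if not candidates:
        raise ValueError("no candidates")
    n_set = {c.n_obs for c in candidates}
    if len(n_set) > 1:
        raise ValueError(f"candidates fit on different observations: n_obs {sorted(n_set)}")
    return min(candidates, key=lambda c: (c.aic, c.n_params, c.formula))


def assign_precision_groups(
    trials: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Partition trials by angular response error into precision groups.

    precise: error <= 15°; intermediate: 15° < error <= 30°; imprecise:
    error > 30° (boundaries per the closed bin edges).
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.precision_bin_edges_deg
    err = trials["response_error"].to_numpy(dtype=float)
    if np.any(err < 0):
        raise ValueError("negative response error")
    group = np.where(err <= lo, "precise", np.where(err <= hi, "intermediate", "imprecise"))
    out = trials.copy()
    out["precision_group"] = pd.Categorical(
        group, categories=["precise", "intermediate", "imprecise"]
    )
    return out


def make_timecourse_frame(
    trials: pd.DataFrame,
    traces: np.ndarray,
    t_rel: np.ndarray,
    cfg: AnalysisConfig | None = None,
    t_min: int | None = None,
    t_max: int | None = None,
) -> pd.DataFrame:
    """Per-trial 10-ms bin means of the pupil trace, in long format."""
    cfg = cfg or AnalysisConfig()
    bin_ms = cfg.timecourse_bin_ms
    t_min = int(t_rel[0]) if t_min is None else t_min
    t_max = int(t_rel[-1]) + 1 if t_max is None else t_max
    frames = []
    edges = np.arange(t_min, t_max + 1, bin_ms)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (t_rel >= lo) & (t_rel < hi)
        if not mask.any():
            continue
        f = trials[["participant", "trial", "set_size", "prototypical", "precision_group"]].copy()
        f["bin_ms"] = int(lo)
        f["pupil"] = traces[:, mask].mean(axis=1)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class TimecourseResult:
    """Per-bin fits plus contiguous significant runs of the group effect."""

    bins_ms: list[int]
    fits: dict[int, FitResult]
    significant_bins: list[int]
    runs_ms: list[tuple[int, int]]  # [start, end) in ms
    skipped_bins: list[int]


_PRECISION_FORMULA = (
    "pupil ~ precision_group * set_size * prototypical"
)
_PRECISION_RE = "~set_size * prototypical"


def _exact_linear_fit(
    data: pd.DataFrame, formula: str, t_threshold: float
) -> FitResult | None:
    """Zero-residual fallback: with no noise the LME likelihood degenerates,
    but the fixed effects are an exact linear solve. t is ±inf for nonzero
    coefficients and 0 for structural zeros, so the significance flags stay
    a pure function of (beta, se, threshold)."""
    import patsy

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    yv = y.to_numpy().ravel()
    Xm = X.to_numpy()
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        return None  # rank-deficient design: leave it to the mixed model
    beta, _, _, _ = np.linalg.lstsq(Xm, yv, rcond=None)
    resid = yv - Xm @ beta
    scale = max(float(np.std(yv)), 1.0)
    if float(np.std(resid)) > 1e-9 * scale:
        return None
    tol = 1e-9 * scale
    coefficients = {}
    for name, b in zip(X.columns, beta):
        b = float(b)
        if abs(b) > tol:
            coefficients[_clean_term(name)] = (b, 0.0, float("inf") if b > 0 else float("-inf"))
        else:
            coefficients[_clean_term(name)] = (0.0, 0.0, 0.0)
    significant = {k: abs(v[2]) > t_threshold for k, v in coefficients.items()}
    return FitResult(
        formula=formula + " [exact]",
        coefficients=coefficients,
        significant=significant,
        aic=float("-inf"),
        n_obs=len(data),
        n_groups=int(data["participant"].nunique()),
        converged=True,
        method="exact",
    )


def timecourse_lme(
    tc: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    reml: bool = True,
) -> TimecourseResult:
    """Fit the precision-group LME in every 10-ms bin and find runs.

    Model per bin: ``pupil ~ precision_group × set_size × prototypicality``
    with ``(1 + set_size × prototypicality | participant)``. A bin is
    significant when any precision-group main-effect term exceeds the t
    threshold (uncorrected, mirroring run-based reporting). Bins with
    fewer than two precision groups present are skipped and logged. Bins
    whose outcome is an exact function of the design (noise-free synthetic
    data) are solved exactly rather than by likelihood iteration.
    """
    cfg = cfg or AnalysisConfig()
    bins = sorted(tc["bin_ms"].unique())
    fits: dict[int, FitResult] = {}
    skipped: list[int] = []
    sig: list[int] = []
    for b in bins:
        sub = tc[tc["bin_ms"] == b]
        if sub["precision_group"].nunique() < 2:
            logger.info("timecourse bin %d ms skipped: <2 precision groups", b)
            skipped.append(int(b))
            continue
        res = _exact_linear_fit(sub, _PRECISION_FORMULA, cfg.t_threshold)
        if res is None:
            res = _fit_mixedlm(
                _PRECISION_FORMULA,
                sub,
                re_formula=_PRECISION_RE,
                reml=reml,
                t_threshold=cfg.t_threshold,
            )
        fits[int(b)] = res
        group_terms = [
            k for k in res.coefficients if k.startswith("precision_group[") and ":" not in k
        ]
        if any(res.significant[k] for k in group_terms):
            sig.append(int(b))
    runs: list[tuple[int, int]] = []
    if sig:
        start = prev = sig[0]
        for b in sig[1:]:
            if b - prev > cfg.timecourse_bin_ms:
                runs.append((start, prev + cfg.timecourse_bin_ms))
                start = b
            prev = b
        runs.append((start, prev + cfg.timecourse_bin_ms))
    return TimecourseResult(
        bins_ms=[int(b) for b in bins if int(b) not in skipped],
        fits=fits,
        significant_bins=sig,
        runs_ms=runs,
        skipped_bins=skipped,
    )


def fit_precision_trial_model(
    trials: pd.DataFrame, cfg: AnalysisConfig | None = None, reml: bool = True
) -> FitResult:
    """Trial-by-trial precision model:

    ``response_error ~ baseline + orienting + set_size × prototypicality``
    with ``(1 + set_size × prototypicality | participant)``.
    """
    cfg = cfg or AnalysisConfig()
    _require_columns(
        trials,
        ["response_error", "baseline_pupil", "orienting_amplitude", "set_size",
         "prototypical", "participant"],
    )
    data = trials.dropna(subset=["baseline_pupil", "orienting_amplitude"]).copy()
    return _fit_mixedlm(
        "response_error ~ baseline_pupil + orienting_amplitude + set_size * prototypical",
        data,
        re_formula="~set_size * prototypical",
        reml=reml,
        t_threshold=cfg.t_threshold,
    )


def validate_build_proxy(
    placements: Sequence[float], build_ms: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of correct placements vs build duration.

    The sanity check behind using build duration as an encoding-depth
    proxy: in a task where per-event placement counts are available, the
    two should be strongly monotonically related.
    """
    placements = np.asarray(placements, dtype=float)
    build_ms = np.asarray(build_ms, dtype=float)
    if len(placements) != len(build_ms) or len(placements) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(placements) == 0 or np.ptp(build_ms) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(placements, build_ms)
    return float(rho), float(p)
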