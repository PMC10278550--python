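"""End-to-end orchestration: simulate/load → segment → features → fit.

A run is fully determined by its manifest (config snapshot, seed, input
hashes); re-running with the same manifest reproduces identical outputs.
A single seed feeds a splittable stream so each stochastic stage draws
from an independent, reproducible substream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .features import annotate_events
from .io_formats import (
    load_config,
    read_samples,
    read_trials,
    save_config,
    write_events,
    write_trials,
)
from .models import (
    events_to_frame,
    fit_build_model,
    fit_condition_model,
    fit_per_experiment,
)
from .segmentation import filter_events, segment_sampling_events
from .synthetic import CopySimParams, simulate_copy_task
from .types import AnalysisConfig, FitResult, GeometryConfig

__all__ = ["run_pipeline", "PipelineError", "fit_results_frame"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and cause."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def fit_results_frame(results: dict[str, FitResult]) -> pd.DataFrame:
    """Flatten fitted models into one coefficients table."""
    rows = []
    for name, r in results.items():
        for term, (beta, se, t) in r.coefficients.items():
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "significant": r.significant[term],
                    "aic": r.aic,
                    "n_obs": r.n_obs,
                    "converged": r.converged,
                    "formula": r.formula,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    out_dir: str | Path,
    mode: str = "synthetic",
    config_path: str | Path | None = None,
    seed: int = 0,
    sim_params: CopySimParams | None = None,
    sample_paths: Sequence[str | Path] | None = None,
    trials_path: str | Path | None = None,
    write_samples_tables: bool = False,
) -> Path:
    """Run the full copy-task pipeline and write all outputs to ``out_dir``.

    In ``synthetic`` mode, recordings come from :func:`simulate_copy_task`
    under ``sim_params``; in ``external-data`` mode from ``sample_paths``
    (one sample table per recording) plus ``trials_path``. Outputs:
    ``events.tsv`` (segmented + feature-annotated), ``fits.tsv``,
    ``drop_log.json`` and ``manifest.json``. Raises :class:`PipelineError`
    naming the failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config_path is not None:
        geom, cfg = load_config(config_path, strict=True)
    else:
        geom, cfg = GeometryConfig(), AnalysisConfig()

    manifest: dict = {
        "tool": "pupilencode",
        "version": __version__,
        "mode": mode,
        "seed": seed,
        "config": json.loads(json.dumps(_config_snapshot(geom, cfg))),
        "inputs": {},
        "stages": {},
    }

    # --- acquire -----------------------------------------------------------
    try:
        if mode == "synthetic":
            params = sim_params or CopySimParams()
            rng = np.random.default_rng(np.random.SeedSequence(seed))
            series, trials, gt = simulate_copy_task(params, geom, rng)
            gt.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            manifest["sim_params"] = dataclasses.asdict(params)
        elif mode == "external-data":
            if not sample_paths or trials_path is None:
                raise PipelineError("external-data mode needs sample_paths and trials_path")
            series = {}
            for p in sample_paths:
                s = read_samples(p)
                series[s.participant_id] = s
                manifest["inputs"][str(p)] = _sha256(Path(p))
            trials = read_trials(trials_path, cfg)
            manifest["inputs"][str(trials_path)] = _sha256(Path(trials_path))
        else:
            raise PipelineError(f"unknown mode {mode!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'acquire' failed: {exc}") from exc
    manifest["stages"]["acquire"] = {
        "recordings": len(series),
        "trials": len(trials),
        "samples": int(sum(len(s) for s in series.values())),
    }
    write_trials(trials, out / "trials.tsv")
    if write_samples_tables:
        from .io_formats import write_samples

        for pid, s in series.items():
            write_samples(s, out / f"samples_{pid}.tsv")

    # --- segment -----------------------------------------------------------
    try:
        events = []
        for pid in sorted(series):
            events.extend(segment_sampling_events(series[pid], trials, cfg, geom))
    except Exception as exc:
        raise PipelineError(f"stage 'segment' failed: {exc}") from exc
    manifest["stages"]["segment"] = {"events": len(events)}

    # --- features ----------------------------------------------------------
    try:
        for pid in sorted(series):
            mine = [e for e in events if e.participant_id == pid]
            annotate_events(series[pid], mine, cfg, geom)
    except Exception as exc:
        raise PipelineError(f"stage 'features' failed: {exc}") from exc

    # --- filter ------------------------------------------------------------
    kept, drops = filter_events(events, trials, cfg)
    gaze_kept = [e for e in kept if e.included_gaze_filter]
    drops["gaze-filter"] = len(kept) - len(gaze_kept)
    manifest["stages"]["filter"] = {"kept": len(gaze_kept), "drops": drops}
    write_events(events, out / "events.tsv")
    write_events(gaze_kept, out / "events_included.tsv")
    with open(out / "drop_log.json", "w") as fh:
        json.dump(drops, fh, indent=2)

    # --- fit ---------------------------------------------------------------
    results: dict[str, FitResult] = {}
    try:
        df = events_to_frame(gaze_kept, trials)
        for outcome in ("dwell", "build", "baseline", "orienting"):
            results[f"condition_{outcome}"] = fit_condition_model(df, outcome, cfg)
        results["build_full"] = fit_build_model(df, cfg)
        for exp in sorted(df["experiment"].unique()):
            results[f"build_exp{exp}"] = fit_per_experiment(df, int(exp), cfg)
    except Exception as exc:
        raise PipelineError(f"stage 'fit' failed: {exc}") from exc
    fits = fit_results_frame(results)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    fits.to_json(out / "fits.json", orient="records", indent=2)
    manifest["stages"]["fit"] = {
        "models": list(results),
        "n_model_obs": int(fits["n_obs"].iloc[0]) if len(fits) else 0,
    }

    save_config(geom, cfg, out / "config_used.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete: %s", out)
    return out


def _config_snapshot(geom: GeometryConfig, cfg: AnalysisConfig) -> dict:
    snap = {}
    for obj in (geom, cfg):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, frozenset):
                v = sorted(v)
            snap[f.name] = v
    return snap
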