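import dataclasses
import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from pupilencode import (
    aic_select,
    assign_precision_groups,
    fit_build_model,
    fit_condition_model,
    fit_per_experiment,
    fit_precision_trial_model,
    make_timecourse_frame,
    simulate_copy_events,
    simulate_precision_task,
    timecourse_lme,
    validate_build_proxy,
)
from pupilencode.models import CONDITION_LABELS, DegenerateFitError
from pupilencode.synthetic import CopySimParams, PrecisionSimParams
from pupilencode.types import FitResult


def event_frame(seed=0, **overrides):
    p = dataclasses.replace(CopySimParams(), **overrides)
    df = simulate_copy_events(p, seed=seed)
    df["condition"] = df.condition_delay_ms.map(CONDITION_LABELS)
    df["dwell_s"] = df.dwell_ms / 1000.0
    df["build_s"] = df.build_ms / 1000.0
    return p, df


class TestConditionModel:
    def test_recovers_planted_condition_effect(self):
        # planted +0.33 s on build and +1.64 s on dwell for the long delay
        p, df = event_frame(seed=12)
        r = fit_condition_model(df, "dwell")
        lo, hi = r.conf_int("condition[long]")
        assert lo <= p.dwell_condition_effect_s <= hi
        assert r.significant["condition[long]"]

    def test_degenerate_outcome_rejected(self):
        _, df = event_frame(seed=0, n_participants=4, n_trials_per_condition=3)
        df["build_s"] = 2.0
        with pytest.raises(DegenerateFitError):
            fit_condition_model(df, "build")

    def test_two_participants_required(self):
        _, df = event_frame(seed=0, n_participants=4, n_trials_per_condition=3)
        with pytest.raises(ValueError, match="participants"):
            fit_condition_model(df[df.participant == "p01"], "build")


class TestBuildModel:
    def test_missing_columns_named(self):
        _, df = event_frame(seed=0, n_participants=4, n_trials_per_condition=3)
        with pytest.raises(ValueError, match="orienting_amplitude"):
            fit_build_model(df.drop(columns=["orienting_amplitude"]))

    def test_single_experiment_redirected(self):
        _, df = event_frame(seed=0, n_participants=4, n_trials_per_condition=3)
        with pytest.raises(ValueError, match="fit_per_experiment"):
            fit_build_model(df[df.experiment == 1])

    def test_per_experiment_empty_subset_rejected(self):
        _, df = event_frame(seed=0, n_participants=4, n_trials_per_condition=3)
        with pytest.raises(ValueError, match="experiment 2"):
            fit_per_experiment(df[df.experiment == 1], 2)

    def test_experiment_specific_dwell_slopes_detected(self):
        # planted dwell slopes 0.10 (E1) vs 0.19 (E2): the interaction term
        # must come out significant at the study's size
        p, df = event_frame(seed=21)
        r = fit_build_model(df)
        term = "dwell_s:experiment[2]"
        assert r.significant[term]
        lo, hi = r.conf_int(term)
        assert lo <= p.effect_dwell_exp2 - p.effect_dwell <= hi

    def test_lme4_cross_check(self, tmp_path):
        """Fixed effects from statsmodels MixedLM match an independent
        lme4 fit of the same formula on the same data."""
        _, df = event_frame(seed=42, n_participants=10, n_trials_per_condition=12)
        r = fit_condition_model(df, "build")
        csv = tmp_path / "events.csv"
        df.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$condition <- relevel(factor(d$condition), ref="medium")
        d$experiment <- factor(d$experiment)
        m <- lmer(build_s ~ condition + experiment + (1 + condition | participant),
                  data=d, REML=TRUE)
        fe <- fixef(m); se <- sqrt(diag(vcov(m)))
        cat(jsonlite::toJSON(list(terms=names(fe), beta=unname(fe), se=unname(se))))
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr[-500:]
        ref = json.loads(out.stdout)
        lme4 = dict(zip(ref["terms"], zip(ref["beta"], ref["se"])))
        pairs = {
            "Intercept": "(Intercept)",
            "condition[long]": "conditionlong",
            "experiment[2]": "experiment2",
        }
        for ours, theirs in pairs.items():
            assert r.beta(ours) == pytest.approx(lme4[theirs][0], rel=1e-3, abs=1e-6)
        # the within-participant contrast's SE should also agree closely
        assert r.se("condition[long]") == pytest.approx(
            lme4["conditionlong"][1], rel=0.05
        )


def _fit(aic, n_params, n_obs=100, name="m"):
    coefs = {f"b{i}": (0.0, 1.0, 0.0) for i in range(n_params)}
    return FitResult(name, coefs, {k: False for k in coefs}, aic, n_obs, 10, True, "ml")


class TestAicSelect:
    def test_single_candidate(self):
        m = _fit(10.0, 3)
        assert aic_select([m]) is m

    def test_minimum_wins(self):
        ms = [_fit(12.0, 3, name="a"), _fit(9.0, 5, name="b")]
        assert aic_select(ms).formula == "b"

    def test_tie_goes_to_smaller_model(self):
        ms = [_fit(10.0, 5, name="big"), _fit(10.0, 3, name="small")]
        assert aic_select(ms).formula == "small"
        assert aic_select(ms[::-1]).formula == "small"

    def test_mismatched_observations_rejected(self):
        with pytest.raises(ValueError, match="n_obs"):
            aic_select([_fit(10.0, 3, n_obs=100), _fit(9.0, 3, n_obs=90)])

    def test_reduced_model_wins_on_null_term(self):
        # with a planted-zero orienting effect, ML-AIC should usually prefer
        # the model without the term
        _, df = event_frame(seed=33, effect_orienting=0.0, effect_orienting_exp2=0.0,
                            n_participants=12, n_trials_per_condition=12)
        sub = df[df.experiment == 1]
        full = fit_per_experiment(sub, 1, reml=False)
        from pupilencode.models import _fit_mixedlm, _with_condition_categories

        red = _fit_mixedlm(
            "build_s ~ baseline_pupil + dwell_s + condition",
            _with_condition_categories(sub),
            re_formula="~condition",
            reml=False,
        )
        assert aic_select([full, red]) is red


class TestPrecisionGroups:
    @pytest.mark.parametrize(
        "error,group",
        [(15.0, "precise"), (30.0, "intermediate"), (30.0001, "imprecise"),
         (0.0, "precise"), (14.9, "precise"), (15.1, "intermediate"),
         (179.0, "imprecise")],
    )
    def test_boundaries(self, error, group):
        df = pd.DataFrame({"response_error": [error]})
        assert assign_precision_groups(df).precision_group.iloc[0] == group

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            assign_precision_groups(pd.DataFrame({"response_error": [-1.0]}))

    def test_partition_is_total(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"response_error": rng.uniform(0, 180, 500)})
        out = assign_precision_groups(df)
        assert not out.precision_group.isna().any()


class TestTimecourse:
    def test_single_bin(self):
        p = PrecisionSimParams(n_participants=6, n_trials=60, epoch_ms=(0, 9))
        trials, traces, t_rel = simulate_precision_task(p, seed=2)
        trials = assign_precision_groups(trials)
        tc = make_timecourse_frame(trials, traces, t_rel)
        res = timecourse_lme(tc)
        assert len(res.bins_ms) == 1

    def test_planted_window_recovered_exactly_in_noiseless_limit(self):
        p = PrecisionSimParams(
            n_participants=8, n_trials=100,
            baseline_sd_between=0.0, baseline_sd_within=0.0, amplitude_sd=0.0,
            pupil_noise_sd=0.0, group_effect_au=30.0, epoch_ms=(0, 1199),
        )
        trials, traces, t_rel = simulate_precision_task(p, seed=11)
        trials = assign_precision_groups(trials)
        tc = make_timecourse_frame(trials, traces, t_rel)
        res = timecourse_lme(tc)
        assert res.runs_ms == [(500, 1000)]


class TestPrecisionTrialModel:
    def test_identical_errors_rejected(self):
        p = PrecisionSimParams(n_participants=3, n_trials=20, effect_setsize=0.0,
                               effect_baseline=0.0, effect_orienting=0.0,
                               noise_sd_deg=0.0, participant_sd_deg=0.0)
        trials, _, _ = simulate_precision_task(p, seed=0)
        trials["baseline_pupil"] = trials.baseline
        trials["orienting_amplitude"] = -trials.amplitude
        with pytest.raises(DegenerateFitError):
            fit_precision_trial_model(trials)


class TestBuildProxy:
    def test_perfect_monotone(self):
        rho, _ = validate_build_proxy([1, 2, 3, 4, 5], [100, 400, 900, 1600, 2500])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_reversed_monotone(self):
        rho, _ = validate_build_proxy([1, 2, 3, 4, 5], [2500, 1600, 900, 400, 100])
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_small_fixture_matches_rank_formula(self):
        placements = [2, 5, 1, 4, 6, 3]
        build = [900, 2200, 1500, 2100, 3000, 1200]
        rho, _ = validate_build_proxy(placements, build)
        # brute-force Spearman: Pearson correlation of the rank vectors
        from scipy.stats import rankdata

        rp, rb = rankdata(placements), rankdata(build)
        expected = float(np.corrcoef(rp, rb)[0, 1])
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            validate_build_proxy([1, 1, 1], [1, 2, 3])
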