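"""Fit the encoding-depth models on a planted-effect event table.

Generates the study-sized event table (24 participants, 35 trials per
delay condition), fits the trial-level mixed model predicting build
duration from baseline pupil size, orienting amplitude and dwell time,
and compares recovered coefficients with the planted ones.
"""

import warnings

from pupilencode import fit_build_model, fit_condition_model, simulate_copy_events
from pupilencode.models import CONDITION_LABELS
from pupilencode.synthetic import CopySimParams

warnings.filterwarnings("ignore")

p = CopySimParams()
df = simulate_copy_events(p, seed=5)
df["condition"] = df.condition_delay_ms.map(CONDITION_LABELS)
df["dwell_s"] = df.dwell_ms / 1000.0
df["build_s"] = df.build_ms / 1000.0

full = fit_build_model(df)
print(f"build-duration model  (n={full.n_obs} events, {full.n_groups} participants)")
plants = {
    "baseline_pupil": p.effect_baseline,
    "orienting_amplitude": p.effect_orienting,
    "dwell_s": p.effect_dwell,
    "condition[long]": p.effect_condition,
}
for term, plant in plants.items():
    beta, se, t = full.coefficients[term]
    flag = "*" if full.significant[term] else " "
    print(f"  {term:22s} beta={beta:9.5f} +/- {se:.5f}  t={t:6.2f}{flag}"
          f"   planted {plant}")

cond = fit_condition_model(df, "dwell")
beta, se, t = cond.coefficients["condition[long]"]
print(f"\ndwell by condition: long - medium = {beta:.2f} s (planted "
      f"{p.dwell_condition_effect_s}) — longer waits buy longer encoding looks")
# Positive baseline/orienting/dwell coefficients mean: higher tonic arousal,
# stronger stimulus-locked constriction and longer looking all predict more
# time spent reproducing the pattern, i.e. deeper working-memory encoding.
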