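"""Relate microbiota maturity and diversity to AGP/CRP inflammation.

Fits concurrent (6->6, 18->18) and predictive (6->18, 12->18) models for
each predictor: linear on ln AGP / ln CRP (back-transformed to ratios) and
logistic on the high-AGP (>1.0 g/L) and high-CRP (>5.0 mg/L) indicators.
Writes results/inflammation.tsv.

Run after 01: python analysis/04_inflammation_models.py [seed]
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from _common import cohort_config  # noqa: E402

from microgrowth.associations import describe_percent_change  # noqa: E402
from microgrowth.pipeline import run_pipeline  # noqa: E402

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
run_pipeline(cohort_config(seed, run_inflammation=True))

df = pd.read_csv("results/inflammation.tsv", sep="\t", comment="#")
concurrent18 = df[(df["predictor_visit"] == "18mo") & (df["outcome_visit"] == "18mo")]
print("concurrent 18-month models (ratio per unit predictor):")
for r in concurrent18.itertuples():
    print(f"  {r.predictor:>7} -> {r.outcome:>8}: ratio = {r.back_transformed:.2f} "
          f"({r.bt_ci_low:.2f}, {r.bt_ci_high:.2f}), p = {r.p_value:.3f}  "
          f"[{describe_percent_change(r.back_transformed)}]")
n_pred = len(df[(df['predictor_visit'] != df['outcome_visit'])])
print(f"plus {n_pred} predictive-model rows in results/inflammation.tsv")
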