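"""Relate microbiota maturity and diversity to interval growth.

Runs the two-interval repeated-measures ANCOVA for each predictor (MAZ,
Shannon) and anthropometric index (LAZ, WAZ, WLZ, HCZ): the interval x
predictor interaction decides whether the pooled coefficient or per-interval
cross-sectional models are reported. Writes results/growth_longitudinal.tsv
and results/growth_by_interval.tsv.

Run after 01: python analysis/03_growth_models.py [seed]
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from _common import cohort_config  # noqa: E402

from microgrowth.pipeline import run_pipeline  # noqa: E402

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
run_pipeline(cohort_config(seed, run_growth=True))

long = pd.read_csv("results/growth_longitudinal.tsv", sep="\t", comment="#")
print("longitudinal models (pooled coefficient from the no-interaction fit):")
for r in long.itertuples():
    flag = " -> stratified" if r.stratified else ""
    print(f"  {r.predictor:>7} vs d{r.outcome.upper()}: beta = "
          f"{r.beta_no_interaction:+.3f} ({r.ci_low:+.3f}, {r.ci_high:+.3f}), "
          f"interaction p = {r.interaction_p:.3f}{flag}")

strat = pd.read_csv("results/growth_by_interval.tsv", sep="\t", comment="#")
if len(strat):
    print("per-interval cross-sectional models (significant interactions):")
    for r in strat.itertuples():
        print(f"  {r.predictor:>7} vs d{r.outcome.upper()} [{r.interval} mo]: "
              f"beta = {r.beta:+.3f} ({r.ci_low:+.3f}, {r.ci_high:+.3f}), "
              f"p = {r.p_value:.3f}, n = {r.n}")
else:
    print("no interaction reached significance; no stratified models fitted")
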