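"""Exploratory per-OTU association scan with BH-FDR at 0.15.

Scans the 6-month samples against ln AGP (6 mo) and the 18-month samples
against ln CRP (18 mo) — the outcomes the primary models flagged — after the
5%-prevalence / 0.1%-abundance filters, using both the presence/absence and
the three-category (absent / below-median / at-or-above-median) encodings.
Writes results/taxa_scan.tsv with pre- and post-FDR significance flags.

Run after 01: python analysis/05_taxa_scan.py [seed]
"""

import sys

import pandas as pd

sys.path.insert(0, "analysis")
from _common import cohort_config  # noqa: E402

from microgrowth.pipeline import run_pipeline  # noqa: E402

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
run_pipeline(cohort_config(seed, run_taxa_scan=True))

df = pd.read_csv("results/taxa_scan.tsv", sep="\t", comment="#")
for (outcome, enc), g in df.groupby(["outcome", "encoding"]):
    fitted = g[~g["failed"]]
    pre = int(fitted["significant_pre_fdr"].sum())
    post = int(fitted["significant_post_fdr"].sum())
    print(f"{outcome} [{enc}]: {len(fitted)} OTUs tested, "
          f"{pre} significant before FDR, {post} after BH at 0.15")
top = df[~df["failed"]].nsmallest(5, "raw_p")
print("strongest associations:")
for r in top.itertuples():
    print(f"  {r.otu_id} ({r.encoding}) vs {r.outcome}: beta = {r.beta:+.3f}, "
          f"raw p = {r.raw_p:.2e}, BH p = {r.bh_adjusted_p:.3f}, {r.direction}")
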