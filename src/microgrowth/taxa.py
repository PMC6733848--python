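"""Exploratory per-OTU association scan.

OTU abundances in infant stool are zero-inflated and far from normal, so
each OTU enters its regression through a reduced encoding rather than raw
counts: either a presence/absence indicator, or three categories (absent /
present below the median positive count / present at or above it). One fully
adjusted linear model is fitted per OTU; raw p-values are Benjamini-Hochberg
adjusted within one family per (outcome x encoding), at an FDR of 0.15 by
default, and both pre- and post-FDR significance flags are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .otu import OtuTable

__all__ = [
    "OtuEncoding",
    "scan_filter",
    "encode_otu",
    "bh_adjust",
    "run_scan",
]


@dataclass
class OtuEncoding:
    """Zero-inflation-aware encodings of one OTU's counts.

    ``tri_level`` holds 0 = absent, 1 = present below the median positive
    count, 2 = present at or above it (ties at the median go up, so the high
    class is never empty for discrete counts).
    """

    otu_id: str
    binary: np.ndarray  # bool, present/absent
    tri_level: np.ndarray  # int {0, 1, 2}
    median_positive_count: float


def scan_filter(
    table: OtuTable,
    min_prevalence: float = 0.05,
    min_abundance: float = 0.001,
) -> OtuTable:
    """Apply the scan's two filters in sequence.

    First, within each sample, counts whose relative abundance is below
    ``min_abundance`` are zeroed (the filter is per cell, not per OTU); then
    OTUs detected in fewer than ``min_prevalence`` of the participants are
    removed. Expects one sample per participant at the scanned visit.
    """
    rel = table.relative_abundances()
    counts = np.where(rel < min_abundance, 0, table.counts)
    prevalence = (counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    filtered = OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        counts=counts,
        taxonomy=list(table.taxonomy),
    )
    return filtered.select_otus(keep)


def encode_otu(counts, otu_id: str = "") -> OtuEncoding:
    """Binary and three-level encodings of one OTU's per-sample counts."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    present = c > 0
    if not present.any():
        raise ValueError(
            f"OTU {otu_id or '?'} absent in every sample; filter before encoding"
        )
    med = float(np.median(c[present]))
    tri = np.zeros(len(c), dtype=int)
    tri[present & (c < med)] = 1
    tri[present & (c >= med)] = 2  # ties at the median go to the upper class
    return OtuEncoding(
        otu_id=otu_id, binary=present, tri_level=tri, median_positive_count=med
    )


def bh_adjust(pvalues, q: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Sort the m p-values ascending, reject the largest i with
    p_(i) <= (i/m) q and all smaller; the adjusted value at rank i is
    min_{j >= i} (m/j) p_(j), capped at 1. Returns (adjusted, rejected)
    in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) / m * q)
    k = passing.max() + 1 if len(passing) else 0
    rejected_sorted = np.zeros(m, dtype=bool)
    rejected_sorted[:k] = True
    adjusted = np.empty(m)
    rejected = np.empty(m, dtype=bool)
    adjusted[order] = adjusted_sorted
    rejected[order] = rejected_sorted
    return adjusted, rejected


def _fit_one(
    y: np.ndarray, X: pd.DataFrame, terms: list[str]
) -> tuple[float, float, float, float]:
    """OLS fit; returns (beta, ci_low, ci_high, p) where p is the joint Wald
    test over *terms* (1 df for binary, 2 df for the tri-level contrasts) and
    beta is the last term's coefficient (the high-vs-absent contrast)."""
    res = sm.OLS(y, X).fit()
    term = terms[-1]
    ci = res.conf_int()
    if len(terms) == 1:
        p = float(res.pvalues[term])
    else:
        contrast = np.zeros((len(terms), X.shape[1]))
        for i, t in enumerate(terms):
            contrast[i, X.columns.get_loc(t)] = 1.0
        p = float(res.f_test(contrast).pvalue)
    return (
        float(res.params[term]),
        float(ci.loc[term, 0]),
        float(ci.loc[term, 1]),
        p,
    )


def run_scan(
    table: OtuTable,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    encoding: str = "binary",
    fdr_q: float = 0.15,
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Fully adjusted per-OTU linear models with BH-FDR flags.

    ``outcome`` and ``covariates`` must be indexed by (or aligned to) the
    table's sample ids. All OTUs fitted in one call form one BH family;
    callers scope families per (outcome x encoding). OTUs whose model fails
    are recorded with ``failed=True`` and excluded from the family.
    """
    if encoding not in ("binary", "tri_level"):
        raise ValueError("encoding must be 'binary' or 'tri_level'")
    y_all = outcome.reindex(table.sample_ids) if outcome.index.is_unique else outcome
    y_all = np.asarray(y_all, dtype=float)
    if covariates is not None:
        cov = covariates.reindex(table.sample_ids)
    else:
        cov = pd.DataFrame(index=pd.Index(table.sample_ids))

    from .associations import _design_matrix

    rows = []
    for j, otu in enumerate(table.otu_ids):
        rec = {
            "otu_id": otu,
            "outcome": outcome_name,
            "encoding": encoding,
            "failed": False,
        }
        try:
            enc = encode_otu(table.counts[:, j], otu_id=otu)
            df = cov.copy()
            if encoding == "binary":
                df["otu_present"] = enc.binary.astype(float)
                terms = ["otu_present"]
            else:
                df["otu_low"] = (enc.tri_level == 1).astype(float)
                df["otu_high"] = (enc.tri_level == 2).astype(float)
                terms = ["otu_low", "otu_high"]
            ok = np.isfinite(y_all)
            for c in df.columns:
                if df[c].dtype != object:
                    ok &= np.isfinite(df[c].astype(float).to_numpy())
                else:
                    ok &= df[c].notna().to_numpy()
            X = _design_matrix(df.loc[ok], list(cov.columns) + terms)
            if any(X[t].nunique() < 2 for t in terms if t in X):
                raise ValueError("degenerate encoding after filtering")
            beta, lo, hi, p = _fit_one(y_all[ok], X, terms)
            rec.update(
                beta=beta,
                ci_low=lo,
                ci_high=hi,
                raw_p=p,
                median_positive_count=enc.median_positive_count,
                direction="positive" if beta >= 0 else "negative",
                n_used=int(ok.sum()),
            )
        except Exception as exc:  # model failure: record and continue
            rec.update(
                beta=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                raw_p=np.nan,
                median_positive_count=np.nan,
                direction="",
                n_used=0,
                failed=True,
                failure=str(exc),
            )
        rows.append(rec)

    out = pd.DataFrame(rows)
    fitted = out[~out["failed"]].index
    out["bh_adjusted_p"] = np.nan
    out["significant_pre_fdr"] = False
    out["significant_post_fdr"] = False
    if len(fitted):
        adj, rej = bh_adjust(out.loc[fitted, "raw_p"].to_numpy(), q=fdr_q)
        out.loc[fitted, "bh_adjusted_p"] = adj
        out.loc[fitted, "significant_pre_fdr"] = (
            out.loc[fitted, "raw_p"] < 0.05
        )
        out.loc[fitted, "significant_post_fdr"] = rej
    return out
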