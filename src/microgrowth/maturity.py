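"""Microbiota age and microbiota-for-age Z-scores (MAZ).

A regression forest is trained on a healthy reference cohort to predict
chronological age (months) from OTU relative abundances; the top-k
age-discriminatory OTUs are selected by permutation importance and the forest
is refit on them. A stool sample's predicted age is its *microbiota age*, and

    MAZ = (microbiota age - median reference microbiota age at that
           chronological age) / SD of reference microbiota age at that age,

where the reference median and SD come from out-of-bag predictions of the
reference children, pooled into age bins. Out-of-bag statistics avoid the
optimism of in-bag predictions, which would shrink the reference SD and
inflate |MAZ|.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .otu import OtuTable

__all__ = [
    "ReferenceModel",
    "AgeOutOfRangeError",
    "fit_reference_model",
    "predict_microbiota_age",
    "compute_maz",
    "save_reference_model",
    "load_reference_model",
]


class AgeOutOfRangeError(ValueError):
    """Chronological age falls outside the reference model's age bins."""


@dataclass
class ReferenceModel:
    """Fitted microbiota-age predictor with reference bin statistics.

    ``bin_edges`` has length ``n_bins + 1`` (months); bin ``b`` covers
    ``[bin_edges[b], bin_edges[b+1])``, with the last bin closed on the right.
    ``bin_median`` / ``bin_sd`` are the reference cohort's out-of-bag
    microbiota-age median and SD per bin.
    """

    selected_otu_ids: list[str]
    predictor: RandomForestRegressor
    bin_edges: np.ndarray
    bin_median: np.ndarray
    bin_sd: np.ndarray
    training_seed: int
    oob_predictions: np.ndarray | None = None
    oob_r2: float | None = None

    def bin_of(self, chrono_age_months) -> np.ndarray:
        """Bin index for each age; raises AgeOutOfRangeError when uncovered."""
        ages = np.atleast_1d(np.asarray(chrono_age_months, dtype=float))
        idx = np.searchsorted(self.bin_edges, ages, side="right") - 1
        n_bins = len(self.bin_median)
        # right edge of the last bin is inclusive
        idx[ages == self.bin_edges[-1]] = n_bins - 1
        bad = (idx < 0) | (idx >= n_bins)
        if bad.any():
            raise AgeOutOfRangeError(
                f"age(s) {ages[bad].tolist()} months outside reference bins "
                f"[{self.bin_edges[0]}, {self.bin_edges[-1]}]"
            )
        return idx


def _relative_abundance_matrix(table: OtuTable, otu_ids: list[str]) -> np.ndarray:
    """Relative abundances for the requested OTUs, against each sample's full
    library; OTUs absent from the table are imputed as zero abundance."""
    rel = table.relative_abundances()
    col = {o: j for j, o in enumerate(table.otu_ids)}
    out = np.zeros((table.n_samples, len(otu_ids)))
    for j, o in enumerate(otu_ids):
        if o in col:
            out[:, j] = rel[:, col[o]]
    return out


def _pool_bins(
    ages: np.ndarray, min_per_bin: int
) -> np.ndarray:
    """1-month-wide bins over the age range, pooled left-to-right with
    neighbours until every bin holds at least ``min_per_bin`` reference
    children."""
    lo = float(np.floor(ages.min()))
    hi = float(np.ceil(ages.max()))
    edges = list(np.arange(lo, hi + 1.0))
    if edges[-1] < hi:
        edges.append(hi)

    def counts(e):
        idx = np.clip(np.searchsorted(e, ages, side="right") - 1, 0, len(e) - 2)
        return np.bincount(idx, minlength=len(e) - 1)

    merged = True
    while merged and len(edges) > 2:
        merged = False
        c = counts(np.asarray(edges))
        for b in range(len(c)):
            if c[b] < min_per_bin:
                # merge with the smaller neighbour
                if b == 0:
                    del edges[1]
                elif b == len(c) - 1:
                    del edges[-2]
                elif c[b - 1] <= c[b + 1]:
                    del edges[b]
                else:
                    del edges[b + 1]
                merged = True
                break
    return np.asarray(edges, dtype=float)


def fit_reference_model(
    ref_table: OtuTable,
    ref_ages_months,
    k: int = 25,
    n_trees: int = 1000,
    seed: int = 0,
    min_per_bin: int = 20,
) -> ReferenceModel:
    """Two-pass fit of the microbiota-age model on a healthy reference.

    Pass 1 fits a regression forest of chronological age on all OTU relative
    abundances; OTUs are ranked by permutation importance and the top ``k``
    kept. Pass 2 refits on those ``k`` OTUs with out-of-bag scoring; the OOB
    predictions of the reference children give the per-age-bin median and SD
    used by :func:`compute_maz`.
    """
    ages = np.asarray(ref_ages_months, dtype=float)
    if len(ages) != ref_table.n_samples:
        raise ValueError("ref_ages_months length must match table samples")
    if k > ref_table.n_otus:
        raise ValueError(
            f"k={k} exceeds the {ref_table.n_otus} OTUs in the reference table"
        )
    if np.ptp(ages) == 0:
        raise ValueError("reference ages are all equal; age range required")

    X_all = ref_table.relative_abundances()
    rf1 = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1, oob_score=True
    )
    rf1.fit(X_all, ages)
    # importance only needs a stable ranking; a subsample keeps it cheap
    rng = np.random.default_rng(seed)
    if len(ages) > 300:
        idx = rng.choice(len(ages), 300, replace=False)
    else:
        idx = np.arange(len(ages))
    imp = permutation_importance(
        rf1, X_all[idx], ages[idx], n_repeats=3, random_state=seed, n_jobs=1
    )
    order = np.argsort(imp.importances_mean)[::-1]
    selected = [ref_table.otu_ids[j] for j in order[:k]]

    X_sel = _relative_abundance_matrix(ref_table, selected)
    rf2 = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1, oob_score=True
    )
    rf2.fit(X_sel, ages)
    oob = rf2.oob_prediction_

    edges = _pool_bins(ages, min_per_bin=min_per_bin)
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    medians = np.empty(len(edges) - 1)
    sds = np.empty(len(edges) - 1)
    for b in range(len(edges) - 1):
        vals = oob[idx == b]
        medians[b] = np.median(vals)
        sds[b] = np.std(vals, ddof=1)
    if (sds <= 0).any():
        raise ValueError("degenerate reference bin with zero SD")

    return ReferenceModel(
        selected_otu_ids=selected,
        predictor=rf2,
        bin_edges=edges,
        bin_median=medians,
        bin_sd=sds,
        training_seed=seed,
        oob_predictions=oob,
        oob_r2=float(rf2.oob_score_),
    )


def predict_microbiota_age(model: ReferenceModel, table: OtuTable) -> pd.DataFrame:
    """Predict microbiota age (months) for every sample in *table*.

    Predictions depend only on relative abundances of the model's selected
    OTUs (absent OTUs are treated as zero abundance). Samples with zero
    abundance on every selected OTU get the forest's baseline prediction and
    are flagged ``degenerate``.
    """
    X = _relative_abundance_matrix(table, model.selected_otu_ids)
    preds = model.predictor.predict(X)
    degenerate = (X.sum(axis=1) == 0) | (table.sample_sums() == 0)
    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "microbiota_age_months": preds,
            "degenerate": degenerate,
        }
    ).set_index("sample_id")


def compute_maz(model: ReferenceModel, microbiota_age, chrono_age) -> pd.DataFrame:
    """Standardise microbiota age against age-matched reference statistics.

    MAZ = (microbiota_age - bin_median(chrono_age)) / bin_sd(chrono_age).
    Accepts scalars or aligned arrays; chronological ages must fall inside the
    model's bins.
    """
    mic = np.atleast_1d(np.asarray(microbiota_age, dtype=float))
    chrono = np.atleast_1d(np.asarray(chrono_age, dtype=float))
    if mic.shape != chrono.shape:
        raise ValueError("microbiota_age and chrono_age must align")
    b = model.bin_of(chrono)
    maz = (mic - model.bin_median[b]) / model.bin_sd[b]
    return pd.DataFrame(
        {
            "chrono_age_months": chrono,
            "microbiota_age_months": mic,
            "maz": maz,
        }
    )


def save_reference_model(model: ReferenceModel, outdir) -> None:
    """Persist the model as a directory: selected OTUs (TSV), bin statistics
    (TSV) and the serialized forest (joblib binary)."""
    import joblib

    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame(
        {"rank": range(1, len(model.selected_otu_ids) + 1),
         "otu_id": model.selected_otu_ids}
    ).to_csv(os.path.join(outdir, "selected_otus.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {
            "bin_low_months": model.bin_edges[:-1],
            "bin_high_months": model.bin_edges[1:],
            "median_microbiota_age": model.bin_median,
            "sd_microbiota_age": model.bin_sd,
        }
    ).to_csv(os.path.join(outdir, "bin_stats.tsv"), sep="\t", index=False)
    joblib.dump(
        {"predictor": model.predictor, "training_seed": model.training_seed},
        os.path.join(outdir, "predictor.joblib"),
    )


def load_reference_model(indir) -> ReferenceModel:
    import joblib

    sel = pd.read_csv(os.path.join(indir, "selected_otus.tsv"), sep="\t")
    bins = pd.read_csv(os.path.join(indir, "bin_stats.tsv"), sep="\t")
    blob = joblib.load(os.path.join(indir, "predictor.joblib"))
    edges = np.append(
        bins["bin_low_months"].to_numpy(), bins["bin_high_months"].iloc[-1]
    )
    return ReferenceModel(
        selected_otu_ids=list(sel["otu_id"]),
        predictor=blob["predictor"],
        bin_edges=edges,
        bin_median=bins["median_microbiota_age"].to_numpy(),
        bin_sd=bins["sd_microbiota_age"].to_numpy(),
        training_seed=int(blob["training_seed"]),
    )
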