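"""Seeded synthetic longitudinal infant cohort with microbiome, growth and
inflammation structure.

The generator emulates a three-visit (6/12/18 months) cohort of several
hundred children:

* zero-inflated, library-size-varying OTU counts in which a designated subset
  of "age-discriminatory" OTUs has mean relative abundance monotone in age
  (some increasing, some decreasing), so a regression forest can learn
  microbiota age;
* a latent per-child-visit maturity score (``maz_true``) that shifts the
  microbiome along the age axis and drives the planted growth effect;
* anthropometric z-scores whose day-normalised 6-to-12-month change in WAZ
  depends on maturity at 6 months, with a separately configurable (default
  zero) effect in the 12-to-18-month interval;
* log-normal AGP and CRP in which ln(CRP) at 18 months depends on concurrent
  Shannon diversity.

Every injected effect is recorded in the returned truth record so recovery
tests can compare downstream estimates against it. All randomness flows from
one integer seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = [
    "CohortConfig",
    "CohortConfigError",
    "DataShapeError",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_otu_counts",
    "simulate_outcomes",
    "expected_proportions",
    "write_cohort",
    "COVARIATE_COLUMNS",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
VISIT_LABELS = {6: "6mo", 12: "12mo", 18: "18mo"}

#: Covariates entering the fully adjusted models (child-constant unless noted).
COVARIATE_COLUMNS = [
    "intervention_group",  # categorical, 3 trial arms
    "age_days",            # child age on day of stool collection (per visit)
    "maternal_age",
    "maternal_height",
    "maternal_bmi",
    "parity",
    "maternal_education",
    "hiv_positive",
    "hemoglobin",
    "assets_z",
    "food_insecure",
    "water_tap",
    "residential_urban",
    "sanitary_facility",
    "season_rainy",        # season at stool collection (per visit)
    "delivery_vaginal",
    "delivery_site_facility",
    "child_sex_male",
]

ANTHRO_COLUMNS = ["laz", "waz", "wlz", "hcz"]


class CohortConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


class DataShapeError(ValueError):
    """Inputs to an outcome generator are misaligned."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Effects are on the scale the downstream models estimate: z-units of
    day-normalised 6-month change per unit of maturity score, and natural-log
    units of CRP per unit of Shannon index.
    """

    n_children: int = 650
    visit_months: tuple[int, ...] = (6, 12, 18)
    age_jitter_sd_days: float = 12.0
    n_otus: int = 100
    n_age_discriminatory: int = 25
    library_size_log_mean: float = float(np.log(30_000))
    library_size_log_sd: float = 0.4
    zero_inflation_prob: float = 0.15
    nb_dispersion: float = 0.4
    effect_maz_on_dwaz_6_12: float = 0.03
    effect_maz_on_dwaz_12_18: float = 0.0
    effect_shannon_on_log_crp_18: float = float(np.log(0.64))
    dropout_prob_per_visit: float = 0.05
    late_visit_prob: float = 0.02
    seed: int = 0
    # secondary shape parameters (rarely changed)
    maturity_scale_months: float = 1.5
    trend_logit_per_month: float = 0.14
    baseline_z_feedback: float = -0.2
    outcome_noise_sd: float = 0.45
    bmi_assets_rho: float = 0.3

    def validate(self) -> None:
        if self.n_children <= 0:
            raise CohortConfigError("n_children must be positive")
        if not self.visit_months:
            raise CohortConfigError("visit_months must be non-empty")
        if self.age_jitter_sd_days < 0:
            raise CohortConfigError("age_jitter_sd_days must be non-negative")
        if self.n_otus <= 0:
            raise CohortConfigError("n_otus must be positive")
        if not 0 <= self.n_age_discriminatory <= self.n_otus:
            raise CohortConfigError(
                "n_age_discriminatory must be between 0 and n_otus"
            )
        for prob_field in (
            "zero_inflation_prob", "dropout_prob_per_visit", "late_visit_prob"
        ):
            v = getattr(self, prob_field)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{prob_field} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise CohortConfigError("nb_dispersion must be positive")
        if self.library_size_log_sd < 0:
            raise CohortConfigError("library_size_log_sd must be non-negative")
        if self.outcome_noise_sd < 0:
            raise CohortConfigError("outcome_noise_sd must be non-negative")
        if not -1.0 <= self.bmi_assets_rho <= 1.0:
            raise CohortConfigError("bmi_assets_rho must be in [-1, 1]")


@dataclass
class SimulatedCohort:
    """One realisation of the synthetic cohort.

    ``visits`` holds one row per retained child-visit (metadata, covariates,
    anthropometry, biomarkers and the latent truths ``maz_true`` and
    ``shannon_true``); ``otu_table`` holds the matching stool samples; ``truth``
    records every injected parameter for recovery tests.
    """

    visits: pd.DataFrame
    otu_table: OtuTable
    truth: dict = field(default_factory=dict)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the global seed."""
    tag = int.from_bytes(name.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _trend_signs(config: CohortConfig) -> np.ndarray:
    """Per-OTU direction of the age trend: +1 increasing, -1 decreasing, 0 none.

    The first ``n_age_discriminatory`` OTUs alternate increasing/decreasing,
    deterministically in the OTU index so truth is derivable from the config.
    """
    signs = np.zeros(config.n_otus, dtype=int)
    k = config.n_age_discriminatory
    signs[:k] = np.where(np.arange(k) % 2 == 0, 1, -1)
    return signs


def _base_logits(config: CohortConfig) -> np.ndarray:
    """Cohort-level composition logits, drawn once per seed.

    Decreasing age-discriminatory OTUs are staggered early dominants (like the
    milk-adapted taxa of the young infant gut) and increasing ones start rare,
    so early communities are uneven (low Shannon) and diversity rises
    monotonically with age over the cohort's age range, as in real infant gut
    succession. With the default geometry the expected Shannon index runs
    ~1.9 at 6 months to ~2.9 at 18 months.
    """
    rng = _substream(config.seed, "composition")
    signs = _trend_signs(config)
    base = np.zeros(config.n_otus)
    dec_idx = np.flatnonzero(signs == -1)
    base[dec_idx] = 4.5 - 0.8 * np.arange(len(dec_idx))
    base[signs == 1] = -2.6
    base[signs == 0] = rng.normal(-1.2, 1.8, size=int((signs == 0).sum()))
    return base


def expected_proportions(ages_days: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Noise-free expected relative abundances for samples at the given ages.

    Each age-discriminatory OTU's logit moves linearly in age (months) at
    ``trend_logit_per_month`` with its designed sign; other OTUs are flat.
    """
    ages_months = np.asarray(ages_days, dtype=float) / DAYS_PER_MONTH
    base = _base_logits(config)
    slopes = _trend_signs(config) * config.trend_logit_per_month
    logits = base[None, :] + slopes[None, :] * (ages_months[:, None] - 12.0)
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def _draw_compositions(
    ages_days: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Each sample's true underlying composition: expected proportions from
    :func:`expected_proportions` perturbed by gamma weights with shape
    ``1 / nb_dispersion`` (negative-binomial-like overdispersion) and a
    per-cell Bernoulli dropout mask, renormalised. A fully zeroed sample
    stays all-zero."""
    props = expected_proportions(ages_days, config)
    shape = 1.0 / config.nb_dispersion
    w = rng.gamma(shape, scale=props / shape)
    keep = rng.random(w.shape) >= config.zero_inflation_prob
    w = np.where(keep, w, 0.0)
    tot = w.sum(axis=1, keepdims=True)
    return np.divide(w, tot, out=np.zeros_like(w), where=tot > 0)


def simulate_otu_counts(
    ages_days,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
    return_compositions: bool = False,
):
    """Draw zero-inflated overdispersed OTU counts for samples at given ages.

    Per sample, a true composition is drawn by :func:`_draw_compositions` and
    one multinomial draw at the sample's log-normal library size produces the
    counts — so row sums equal the drawn library sizes exactly while marginal
    per-OTU counts are overdispersed and zero-inflated.

    With ``return_compositions`` the (n_samples, n_otus) matrix of true
    compositions is returned alongside the table.
    """
    config.validate()
    ages_days = np.asarray(ages_days, dtype=float)
    if (ages_days < 0).any():
        raise ValueError("ages must be non-negative")
    if rng is None:
        rng = _substream(config.seed, "otu-counts")
    n = len(ages_days)
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]

    q = _draw_compositions(ages_days, config, rng)
    libsizes = np.maximum(
        1,
        np.round(
            rng.lognormal(
                config.library_size_log_mean, config.library_size_log_sd, size=n
            )
        ).astype(np.int64),
    )
    counts = np.zeros((n, config.n_otus), dtype=np.int64)
    for i in range(n):
        if q[i].sum() > 0:
            counts[i] = rng.multinomial(libsizes[i], q[i])
    taxonomy = [
        f"k__Bacteria; g__SynthGenus{j}; s__otu{j}" for j in range(config.n_otus)
    ]
    table = OtuTable(
        sample_ids=list(sample_ids),
        otu_ids=[f"OTU{j:04d}" for j in range(config.n_otus)],
        counts=counts,
        taxonomy=taxonomy,
    )
    return (table, q) if return_compositions else table


def _expected_shannon(props: np.ndarray) -> np.ndarray:
    p = np.where(props > 0, props, 1.0)
    return -(props * np.log(p)).sum(axis=1)


# visit-level means of the z-score and biomarker marginals
_Z6_MEANS = {"laz": -1.3, "waz": -0.57, "wlz": 0.0, "hcz": -0.5}
_Z6_SDS = {"laz": 1.1, "waz": 1.2, "wlz": 1.1, "hcz": 1.1}
_Z_DRIFT = {"laz": -0.35, "waz": -0.25, "wlz": -0.1, "hcz": -0.15}
_LN_AGP_MEANS = {"6mo": np.log(1.15), "12mo": np.log(1.05), "18mo": np.log(0.95)}
_LN_CRP_MEANS = {"6mo": np.log(2.6), "12mo": np.log(2.0), "18mo": np.log(1.6)}
_LN_AGP_SD = 0.35
_LN_CRP_SD = 1.1
STANDARD_DAYS = 182.625  # one 6-month interval, 365.25 / 2


def simulate_outcomes(
    visits: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill anthropometric z-scores and biomarkers on a complete visit grid.

    ``visits`` must contain one row per (child_id, visit_label) for every
    configured visit, with ``age_days``, ``maz_true`` and ``shannon_true``
    columns. The day-normalised change in WAZ over 6→12 months is
    ``drift + effect_maz_on_dwaz_6_12 * maz_true(6mo) + feedback * waz(6mo)``
    plus Gaussian noise (12→18 analogously with its own effect); ln(CRP) at
    18 months includes ``effect_shannon_on_log_crp_18 * shannon_true(18mo)``.
    AGP and CRP are marginally log-normal.
    """
    config.validate()
    required = {"child_id", "visit_label", "age_days", "maz_true", "shannon_true"}
    missing = required - set(visits.columns)
    if missing:
        raise DataShapeError(f"visits frame lacks columns: {sorted(missing)}")
    if visits.duplicated(["child_id", "visit_label"]).any():
        raise DataShapeError("duplicate (child_id, visit_label) rows")
    labels = [VISIT_LABELS[m] for m in config.visit_months]
    counts_per_child = visits.groupby("child_id")["visit_label"].nunique()
    if (counts_per_child != len(labels)).any():
        raise DataShapeError(
            "every child must have one row per configured visit before dropout"
        )
    if rng is None:
        rng = _substream(config.seed, "outcomes")

    wide = {
        lab: visits[visits["visit_label"] == lab]
        .set_index("child_id")
        .sort_index()
        for lab in labels
    }
    children = wide[labels[0]].index
    n = len(children)

    z = {lab: {} for lab in labels}
    for idx in ANTHRO_COLUMNS:
        z[labels[0]][idx] = rng.normal(_Z6_MEANS[idx], _Z6_SDS[idx], size=n)
    effects = {
        (idx, i): 0.0 for idx in ANTHRO_COLUMNS for i in range(len(labels) - 1)
    }
    effects[("waz", 0)] = config.effect_maz_on_dwaz_6_12
    if len(labels) > 2:
        effects[("waz", 1)] = config.effect_maz_on_dwaz_12_18

    for i in range(len(labels) - 1):
        lab0, lab1 = labels[i], labels[i + 1]
        maz0 = wide[lab0]["maz_true"].to_numpy()
        days = (
            wide[lab1]["age_days"].to_numpy() - wide[lab0]["age_days"].to_numpy()
        )
        if (days <= 0).any():
            raise DataShapeError("non-increasing age_days across visits")
        for idx in ANTHRO_COLUMNS:
            z0 = z[lab0][idx]
            dz_std = (
                _Z_DRIFT[idx]
                + effects[(idx, i)] * maz0
                + config.baseline_z_feedback * (z0 - _Z6_MEANS[idx])
                + rng.normal(0.0, config.outcome_noise_sd, size=n)
            )
            z[lab1][idx] = z0 + dz_std * days / STANDARD_DAYS

    agp = {}
    crp = {}
    for lab in labels:
        sh = wide[lab]["shannon_true"].to_numpy()
        ln_agp = rng.normal(_LN_AGP_MEANS[lab], _LN_AGP_SD, size=n)
        ln_crp = rng.normal(_LN_CRP_MEANS[lab], _LN_CRP_SD, size=n)
        if lab == "18mo":
            ln_crp = ln_crp + config.effect_shannon_on_log_crp_18 * (
                sh - sh.mean()
            )
        agp[lab] = np.exp(ln_agp)
        crp[lab] = np.exp(ln_crp)

    out = visits.copy()
    for idx in ANTHRO_COLUMNS:
        out[idx] = np.nan
    out["agp"] = np.nan
    out["crp"] = np.nan
    for lab in labels:
        mask = out["visit_label"] == lab
        order = out.loc[mask, "child_id"].to_numpy()
        pos = pd.Index(children).get_indexer(order)
        for idx in ANTHRO_COLUMNS:
            out.loc[mask, idx] = z[lab][idx][pos]
        out.loc[mask, "agp"] = agp[lab][pos]
        out.loc[mask, "crp"] = crp[lab][pos]
    return out


def _simulate_covariates(
    n: int, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Child-level covariates; means/SDs follow the cohort description where
    reported, other distributions are fixed realistic defaults."""
    rho = config.bmi_assets_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    bmi_assets = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return pd.DataFrame(
        {
            "intervention_group": rng.choice(["LNS", "MMN", "IFA"], size=n),
            "maternal_age": rng.normal(25.2, 5.9, size=n),
            "maternal_height": rng.normal(156.1, 5.7, size=n),
            "maternal_bmi": 22.0 + 2.8 * bmi_assets[:, 0],
            "assets_z": -0.08 + 1.0 * bmi_assets[:, 1],
            "parity": 1 + rng.poisson(1.5, size=n),
            "maternal_education": np.clip(rng.normal(3.8, 3.5, size=n), 0, None),
            "hiv_positive": (rng.random(n) < 0.119).astype(int),
            "hemoglobin": rng.normal(11.2, 1.5, size=n),
            "food_insecure": (rng.random(n) < 0.389).astype(int),
            "water_tap": (rng.random(n) < 0.30).astype(int),
            "residential_urban": (rng.random(n) < 0.20).astype(int),
            "sanitary_facility": (rng.random(n) < 0.096).astype(int),
            "delivery_vaginal": (rng.random(n) < 0.949).astype(int),
            "delivery_site_facility": (rng.random(n) < 0.90).astype(int),
            "child_sex_male": (rng.random(n) < 0.5).astype(int),
        }
    )


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate one synthetic cohort realisation.

    Returns visit records (one per retained child-visit), the matching OTU
    table (one stool sample per retained visit) and a truth record with every
    injected parameter. Identical config (including seed) gives identical
    output.
    """
    if config is None:
        config = CohortConfig()
    config.validate()

    rng_visits = _substream(config.seed, "visits")
    rng_maturity = _substream(config.seed, "maturity")
    rng_counts = _substream(config.seed, "otu-counts")
    rng_outcomes = _substream(config.seed, "outcomes")
    rng_cov = _substream(config.seed, "covariates")
    rng_drop = _substream(config.seed, "dropout")

    n = config.n_children
    child_ids = [f"C{i:04d}" for i in range(n)]
    birth_offsets = rng_visits.integers(0, 365, size=n)
    epoch = date(2015, 1, 1)

    labels = [VISIT_LABELS[m] for m in config.visit_months]
    rows = []
    for i, cid in enumerate(child_ids):
        prev_age = -1.0
        for m in config.visit_months:
            age = m * DAYS_PER_MONTH + rng_visits.normal(
                0.0, config.age_jitter_sd_days
            )
            # a small fraction of visits happen well past schedule, as in
            # field cohorts; these feed the age-window exclusions downstream
            if rng_visits.random() < config.late_visit_prob:
                age += rng_visits.uniform(60.0, 120.0)
            age = max(age, prev_age + 1.0)  # visits strictly ordered in time
            prev_age = age
            age_days = int(round(age))
            rows.append(
                {
                    "child_id": cid,
                    "visit_label": VISIT_LABELS[m],
                    "age_days": age_days,
                    "stool_date": epoch
                    + timedelta(days=int(birth_offsets[i]) + age_days),
                }
            )
    visits = pd.DataFrame(rows)
    visits["sample_id"] = [
        f"{r.child_id}.{r.visit_label}" for r in visits.itertuples()
    ]

    # latent maturity: child-level component plus visit-level wobble, unit-ish
    # variance overall so planted effects are per maturity z-unit
    child_m = rng_maturity.normal(0.0, 0.8, size=n)
    visit_m = rng_maturity.normal(0.0, 0.6, size=len(visits))
    child_pos = pd.Index(child_ids).get_indexer(visits["child_id"])
    visits["maz_true"] = child_m[child_pos] + visit_m

    # maturity shifts the microbiome along the age axis
    effective_age_days = (
        visits["age_days"].to_numpy()
        + config.maturity_scale_months * DAYS_PER_MONTH * visits["maz_true"].to_numpy()
    )
    effective_age_days = np.clip(effective_age_days, 30.0, None)
    table, compositions = simulate_otu_counts(
        effective_age_days,
        config,
        rng=rng_counts,
        sample_ids=list(visits["sample_id"]),
        return_compositions=True,
    )
    # truth for the diversity effect: entropy of the sample's underlying
    # composition (what rarefied Shannon estimates, minus counting noise)
    visits["shannon_true"] = _expected_shannon(compositions)

    visits = simulate_outcomes(visits, config, rng=rng_outcomes)

    covs = _simulate_covariates(n, config, rng_cov)
    covs.insert(0, "child_id", child_ids)
    visits = visits.merge(covs, on="child_id", how="left")
    # season at stool collection: Nov-Apr is the rainy season
    visits["season_rainy"] = (
        pd.to_datetime(visits["stool_date"]).dt.month.isin([11, 12, 1, 2, 3, 4])
    ).astype(int)

    keep = rng_drop.random(len(visits)) >= config.dropout_prob_per_visit
    visits = visits.loc[keep].reset_index(drop=True)
    table = table.select_samples(np.flatnonzero(keep))

    truth = {
        "config": asdict(config),
        "effect_maz_on_dwaz_6_12": config.effect_maz_on_dwaz_6_12,
        "effect_maz_on_dwaz_12_18": config.effect_maz_on_dwaz_12_18,
        "effect_shannon_on_log_crp_18": config.effect_shannon_on_log_crp_18,
        "trend_signs": _trend_signs(config).tolist(),
        "age_discriminatory_otus": [
            f"OTU{j:04d}" for j in range(config.n_age_discriminatory)
        ],
        "standard_days": STANDARD_DAYS,
        "baseline_z_feedback": config.baseline_z_feedback,
        "z_drift": dict(_Z_DRIFT),
        "substreams": [
            "visits",
            "maturity",
            "otu-counts",
            "outcomes",
            "covariates",
            "dropout",
        ],
    }
    return SimulatedCohort(visits=visits, otu_table=table, truth=truth)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write the cohort as plain-text tables.

    Classic tab-delimited OTU table, UTF-8 TSVs for metadata / anthropometry /
    biomarkers, and a flat ``key = value`` truth record. Returns the paths.
    """
    import os

    from .otu import write_otu_table

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    paths["otu_table"] = os.path.join(outdir, "otu_table.tsv")
    write_otu_table(cohort.otu_table, paths["otu_table"])

    v = cohort.visits
    meta_cols = [
        "sample_id",
        "child_id",
        "visit_label",
        "age_days",
        "stool_date",
        "maz_true",
        "shannon_true",
        *[c for c in COVARIATE_COLUMNS if c not in ("age_days",)],
    ]
    paths["metadata"] = os.path.join(outdir, "metadata.tsv")
    v[meta_cols].to_csv(paths["metadata"], sep="\t", index=False)

    paths["anthropometry"] = os.path.join(outdir, "anthropometry.tsv")
    v[["child_id", "visit_label", "age_days", "stool_date", *ANTHRO_COLUMNS]].to_csv(
        paths["anthropometry"], sep="\t", index=False
    )

    paths["biomarkers"] = os.path.join(outdir, "biomarkers.tsv")
    v[["child_id", "visit_label", "age_days", "agp", "crp"]].to_csv(
        paths["biomarkers"], sep="\t", index=False
    )

    paths["true_params"] = os.path.join(outdir, "true_params.txt")
    with open(paths["true_params"], "w", encoding="utf-8") as fh:
        flat = dict(cohort.truth)
        cfg = flat.pop("config")
        for k, val in cfg.items():
            fh.write(f"config.{k} = {val}\n")
        for k, val in flat.items():
            fh.write(f"{k} = {val}\n")
    return paths
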