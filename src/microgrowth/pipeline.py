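"""End-to-end orchestration of the analysis stages.

simulate (optional) -> OTU processing (low-fraction filter, rarefaction) ->
maturity (microbiota age, MAZ) and Shannon diversity -> interval growth
models -> inflammation models -> per-taxon scan.

Every output table carries a ``# config_hash=`` header line, and a rerun with
the same configuration and inputs is byte-identical. The run report accounts
for every sample entering and leaving each stage, in the spirit of a study
flow diagram.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .otu import (
    OtuTable,
    read_otu_table,
    filter_low_fraction_otus,
    rarefy,
    shannon_series,
)
from .simulate import (
    CohortConfig,
    simulate_cohort,
    write_cohort,
    COVARIATE_COLUMNS,
    DAYS_PER_MONTH,
)
from .maturity import fit_reference_model, compute_maz
from .growth import apply_age_windows
from .associations import run_growth_analysis, run_inflammation_analysis
from .taxa import scan_filter, run_scan

log = logging.getLogger("microgrowth")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_inputs"]

ANTHRO_INDICES = ("laz", "waz", "wlz", "hcz")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    With ``simulate=True`` the synthetic cohort generator provides the inputs;
    otherwise the four input paths must point at existing tables.
    """

    output_dir: str = "results"
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    otu_table_path: str | None = None
    metadata_path: str | None = None
    anthropometry_path: str | None = None
    biomarkers_path: str | None = None
    rarefaction_depth: int = 5000
    min_fraction: float = 0.001
    min_fraction_samples: int = 2
    k_age_discriminatory: int = 25
    n_trees: int = 200
    min_per_bin: int = 20
    standard_days: float = 182.625
    alpha: float = 0.05
    fdr_q: float = 0.15
    winsor_lower_pct: float = 2.5
    winsor_upper_pct: float = 97.5
    seed: int = 0
    run_growth: bool = True
    run_inflammation: bool = True
    run_taxa_scan: bool = True
    write_simulated_inputs: bool = False

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("output_dir")  # where results land does not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info
        log.info("stage %s: %s", stage, info)

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "seed": self.seed,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                default=str,
            )


def _write_table(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def load_inputs(config: PipelineConfig) -> tuple[OtuTable, pd.DataFrame]:
    """Read the OTU table and join metadata + anthropometry + biomarkers into
    one visit frame keyed by (child_id, visit_label)."""
    for name in ("otu_table_path", "metadata_path", "anthropometry_path",
                 "biomarkers_path"):
        p = getattr(config, name)
        if p is None or not os.path.exists(p):
            raise FileNotFoundError(f"{name} not found: {p}")
    table = read_otu_table(config.otu_table_path)
    meta = pd.read_csv(config.metadata_path, sep="\t")
    anthro = pd.read_csv(config.anthropometry_path, sep="\t")
    bio = pd.read_csv(config.biomarkers_path, sep="\t")
    keys = ["child_id", "visit_label"]
    visits = meta.merge(
        anthro.drop(columns=[c for c in ("age_days", "stool_date") if c in anthro],
                    errors="ignore"),
        on=keys, how="left",
    ).merge(
        bio.drop(columns=[c for c in ("age_days",) if c in bio], errors="ignore"),
        on=keys, how="left",
    )
    return table, visits


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; returns the run report (also written to
    ``output_dir/run_report.json``)."""
    os.makedirs(config.output_dir, exist_ok=True)
    chash = config.config_hash()
    report = RunReport(config_hash=chash, version=__version__, seed=config.seed)
    report.stages["config"] = asdict(config)

    try:
        # ------------------------------------------------------ inputs
        if config.simulate:
            cohort_cfg = config.cohort
            if cohort_cfg.seed != config.seed:
                cohort_cfg = CohortConfig(**{**asdict(cohort_cfg), "seed": config.seed})
            cohort = simulate_cohort(cohort_cfg)
            table, visits = cohort.otu_table, cohort.visits
            if config.write_simulated_inputs:
                write_cohort(cohort, os.path.join(config.output_dir, "inputs"))
            report.record(
                "simulate",
                n_children=cohort_cfg.n_children,
                n_visit_records=len(visits),
                n_otus=table.n_otus,
            )
        else:
            table, visits = load_inputs(config)
            report.record(
                "load", n_visit_records=len(visits), n_samples=table.n_samples,
                n_otus=table.n_otus,
            )

        # ------------------------------------------------- OTU processing
        n0 = table.n_otus
        table = filter_low_fraction_otus(
            table, config.min_fraction, config.min_fraction_samples
        )
        rarefied, dropped = rarefy(
            table, config.rarefaction_depth, seed=config.seed
        )
        report.record(
            "otu_processing",
            otus_in=n0,
            otus_retained=table.n_otus,
            otus_removed=n0 - table.n_otus,
            samples_in=table.n_samples,
            samples_below_depth=len(dropped),
            samples_retained=rarefied.n_samples,
        )

        # --------------------------------------- diversity and maturity
        shannon = shannon_series(rarefied)
        sample_rows = visits.set_index("sample_id").loc[
            [s for s in rarefied.sample_ids]
        ]
        ages_months = sample_rows["age_days"].to_numpy(dtype=float) / DAYS_PER_MONTH
        model = fit_reference_model(
            rarefied,
            ages_months,
            k=min(config.k_age_discriminatory, rarefied.n_otus),
            n_trees=config.n_trees,
            seed=config.seed,
            min_per_bin=config.min_per_bin,
        )
        # cohort children are their own healthy reference: use out-of-bag
        # microbiota age so reference SDs are not optimistic
        maz = compute_maz(model, model.oob_predictions, ages_months)
        maz.insert(0, "sample_id", rarefied.sample_ids)
        div = pd.DataFrame(
            {"sample_id": rarefied.sample_ids, "shannon": shannon.to_numpy()}
        )
        _write_table(
            maz, os.path.join(config.output_dir, "maz.tsv"), chash
        )
        _write_table(
            div, os.path.join(config.output_dir, "diversity.tsv"), chash
        )
        report.record(
            "maturity",
            n_selected_otus=len(model.selected_otu_ids),
            oob_r2=model.oob_r2,
            n_bins=len(model.bin_median),
            n_scored=len(maz),
        )

        visits = visits.merge(
            maz[["sample_id", "maz"]], on="sample_id", how="left"
        ).merge(div, on="sample_id", how="left")

        # -------------------------------------------- age-window exclusion
        visits_in, excl = apply_age_windows(visits)
        report.record(
            "age_windows",
            visits_in=len(visits),
            excluded=len(excl),
            retained=len(visits_in),
        )
        if len(excl):
            _write_table(
                excl, os.path.join(config.output_dir, "age_exclusions.tsv"), chash
            )

        covariates = [c for c in COVARIATE_COLUMNS if c in visits_in.columns]

        # ------------------------------------------------------ growth
        if config.run_growth:
            pooled_rows, strat_rows = [], []
            for predictor in ("maz", "shannon"):
                for index in ANTHRO_INDICES:
                    res = run_growth_analysis(
                        visits_in,
                        predictor,
                        index,
                        covariates=covariates,
                        alpha=config.alpha,
                        winsor_pcts=(
                            config.winsor_lower_pct, config.winsor_upper_pct
                        ),
                    )
                    pooled_rows.append(
                        {
                            "predictor": predictor,
                            "outcome": index,
                            "n": res.pooled.n_used,
                            "interaction_p": res.interaction_p,
                            "beta_no_interaction": res.pooled.beta,
                            "ci_low": res.pooled.ci_low,
                            "ci_high": res.pooled.ci_high,
                            "p_value": res.pooled.p_value,
                            "stratified": res.stratified,
                            "beta_no_winsor": (
                                res.sensitivity_pooled.beta
                                if res.sensitivity_pooled
                                else np.nan
                            ),
                        }
                    )
                    if res.per_interval:
                        for interval, r in res.per_interval.items():
                            strat_rows.append(
                                {
                                    "predictor": predictor,
                                    "outcome": index,
                                    "interval": interval,
                                    "n": r.n_used,
                                    "beta": r.beta,
                                    "ci_low": r.ci_low,
                                    "ci_high": r.ci_high,
                                    "p_value": r.p_value,
                                }
                            )
            _write_table(
                pd.DataFrame(pooled_rows),
                os.path.join(config.output_dir, "growth_longitudinal.tsv"),
                chash,
            )
            _write_table(
                pd.DataFrame(
                    strat_rows,
                    columns=[
                        "predictor", "outcome", "interval", "n", "beta",
                        "ci_low", "ci_high", "p_value",
                    ],
                ),
                os.path.join(config.output_dir, "growth_by_interval.tsv"),
                chash,
            )
            report.record(
                "growth",
                models=len(pooled_rows),
                stratified=sum(r["stratified"] for r in pooled_rows),
            )

        # ------------------------------------------------- inflammation
        if config.run_inflammation:
            configs = [
                ("6mo", "6mo"), ("18mo", "18mo"), ("6mo", "18mo"), ("12mo", "18mo"),
            ]
            rows = []
            for predictor in ("maz", "shannon"):
                for pv, ov in configs:
                    try:
                        res = run_inflammation_analysis(
                            visits_in, predictor, pv, ov,
                            covariates=covariates, strict=False,
                        )
                    except ValueError as exc:
                        log.warning(
                            "inflammation %s %s->%s skipped: %s",
                            predictor, pv, ov, exc,
                        )
                        continue
                    for key, r in res.items():
                        if r is None:
                            log.warning(
                                "inflammation %s %s->%s %s: model failed",
                                predictor, pv, ov, key,
                            )
                            continue
                        rows.append(
                            {
                                "predictor": predictor,
                                "predictor_visit": pv,
                                "outcome_visit": ov,
                                "outcome": key,
                                "n": r.n_used,
                                "beta": r.beta,
                                "back_transformed": r.back_transformed,
                                "bt_ci_low": r.bt_ci_low,
                                "bt_ci_high": r.bt_ci_high,
                                "p_value": r.p_value,
                            }
                        )
            _write_table(
                pd.DataFrame(rows),
                os.path.join(config.output_dir, "inflammation.tsv"),
                chash,
            )
            report.record("inflammation", models=len(rows))

        # ----------------------------------------------------- taxa scan
        if config.run_taxa_scan:
            scan_frames = []
            for visit, outcome_col in (("6mo", "agp"), ("18mo", "crp")):
                sub = visits_in[visits_in["visit_label"] == visit]
                sub = sub[sub[outcome_col] > 0]
                ids = [s for s in sub["sample_id"] if s in rarefied.sample_ids]
                if len(ids) < 30:
                    continue
                pos = [rarefied.sample_ids.index(s) for s in ids]
                vt = rarefied.select_samples(np.array(pos))
                vt_f = scan_filter(vt)
                sub = sub.set_index("sample_id").loc[ids]
                y = pd.Series(
                    np.log(sub[outcome_col].to_numpy(dtype=float)), index=ids,
                    name=f"ln_{outcome_col}",
                )
                cov = sub[[c for c in covariates if c != "age_days"] + ["age_days"]]
                for enc in ("binary", "tri_level"):
                    sr = run_scan(
                        vt_f, y, cov, encoding=enc, fdr_q=config.fdr_q,
                        outcome_name=f"ln_{outcome_col}_{visit}",
                    )
                    scan_frames.append(sr)
            scan_out = (
                pd.concat(scan_frames, ignore_index=True)
                if scan_frames
                else pd.DataFrame()
            )
            _write_table(
                scan_out, os.path.join(config.output_dir, "taxa_scan.tsv"), chash
            )
            report.record(
                "taxa_scan",
                families=len(scan_frames),
                models=len(scan_out),
                post_fdr_hits=int(scan_out["significant_post_fdr"].sum())
                if len(scan_out)
                else 0,
            )
    except Exception as exc:
        report.record("failure", error=str(exc))
        report.write(os.path.join(config.output_dir, "run_report.json"))
        raise

    report.write(os.path.join(config.output_dir, "run_report.json"))
    return report
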