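"""Shared configuration for the numbered analysis drivers: read the cohort
written by 01_simulate_cohort.py and run selected pipeline stages."""

from microgrowth.pipeline import PipelineConfig


def cohort_config(seed: int, **stage_toggles) -> PipelineConfig:
    cfg = PipelineConfig(
        output_dir="results",
        simulate=False,
        otu_table_path="results/cohort/otu_table.tsv",
        metadata_path="results/cohort/metadata.tsv",
        anthropometry_path="results/cohort/anthropometry.tsv",
        biomarkers_path="results/cohort/biomarkers.tsv",
        seed=seed,
        run_growth=False,
        run_inflammation=False,
        run_taxa_scan=False,
    )
    for name, value in stage_toggles.items():
        setattr(cfg, name, value)
    return cfg
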