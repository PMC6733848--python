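import numpy as np
import pytest

from microgrowth.otu import OtuTable, filter_low_fraction_otus, rarefy
from microgrowth.simulate import CohortConfig, simulate_cohort, DAYS_PER_MONTH
from microgrowth.maturity import fit_reference_model


def make_table(counts, sample_prefix="s", otu_prefix="o", taxonomy=None):
    counts = np.asarray(counts)
    return OtuTable(
        sample_ids=[f"{sample_prefix}{i}" for i in range(counts.shape[0])],
        otu_ids=[f"{otu_prefix}{j}" for j in range(counts.shape[1])],
        counts=counts,
        taxonomy=taxonomy or [],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (deterministic seed)."""
    cfg = CohortConfig(n_children=150, n_otus=80, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def reference_fit(small_cohort):
    """Rarefied table, reference ages and a fitted microbiota-age model."""
    table = filter_low_fraction_otus(small_cohort.otu_table)
    rarefied, _ = rarefy(table, depth=5000, seed=7)
    visits = small_cohort.visits.set_index("sample_id").loc[rarefied.sample_ids]
    ages = visits["age_days"].to_numpy(dtype=float) / DAYS_PER_MONTH
    model = fit_reference_model(rarefied, ages, k=25, n_trees=150, seed=7)
    return rarefied, ages, model
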