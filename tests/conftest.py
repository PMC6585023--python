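import numpy as np
import pandas as pd
import pytest

from rareburden import (
    SimulationConfig,
    generate_cohort,
    generate_gene_universe,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small, fully exercised cohort: mixed classes, some common panel
    frequencies, moderate CADD pass rate."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        n_cases=50,
        n_controls=40,
        baseline_rate=0.002,
        frac_indel=0.1,
        frac_panel_common=0.1,
        cadd_pass_prob=0.3,
        frac_brain_silent=0.2,
    )


@pytest.fixture(scope="session")
def small_genes(small_config) -> pd.DataFrame:
    return generate_gene_universe(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_genes):
    return generate_cohort(small_config, small_genes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
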