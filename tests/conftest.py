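import numpy as np
import pandas as pd
import pytest

from mrdenrich.synthetic_data import SimConfig, simulate_counts, simulate_panel


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale dilution series: 40 probes, three VAF levels plus blanks."""
    return SimConfig(
        n_probes=40,
        vaf_levels=(0.1, 0.01, 0.001, 0.0),
        replicates_per_level=3,
        dropout_probability=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = simulate_panel(small_config)
    return panel, truth


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    panel, truth = small_panel
    counts, controls, truth = simulate_counts(panel, truth, small_config)
    return panel, counts, controls, truth
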