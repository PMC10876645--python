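import numpy as np
import pytest
from hypothesis import settings

import coabund as cb
from coabund import ingest, synth

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def simulate_log_matrix(config: synth.SynthConfig):
    """Simulate -> reference ratios -> merge -> complete-case -> log2."""
    plexes, truth = synth.simulate_dataset(config)
    design = config.design
    tables = {
        p: ingest.reference_ratios(t, design.reference_channel_by_plex[p])
        for p, t in plexes.items()
    }
    merged = ingest.merge_plexes(tables, design)
    return ingest.log_transform(ingest.filter_missing(merged, 0.0)), truth


@pytest.fixture(scope="session")
def small_dataset():
    """600-protein, 2-module dataset shared by fast tests."""
    config = synth.SynthConfig(
        n_proteins=600,
        module_spec=[
            ("mA", 60, "progressive-down-partial-recovery"),
            ("mB", 40, "transient-early-up"),
        ],
        seed=7,
    )
    log_matrix, truth = simulate_log_matrix(config)
    return config, log_matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
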