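import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from comirnet import (
    SyntheticConfig,
    generate_annotations,
    generate_expression_pair,
)


@pytest.fixture(scope="session")
def small_config():
    # small enough to be fast, with N large enough relative to the ortholog
    # count that planted pairs can clear the Bonferroni threshold
    # (1/N^2 < alpha / C(K, 2))
    return SyntheticConfig(
        n_mirnas_per_species=150,
        n_orthologs=24,
        n_samples_human=40,
        n_samples_mouse=40,
        n_planted_conserved=6,
        n_planted_single_species=2,
        n_genes=600,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_expression_pair(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_data):
    _, _, _, truth = small_data
    return generate_annotations(
        small_config, truth, target_set_size=40, disease_core_size=10
    )
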