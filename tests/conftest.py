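import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from tncall import SyntheticConfig, generate_reads, generate_references


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: every product class represented,
    error-free so each stage can be checked by exact recovery."""
    return SyntheticConfig(
        genome_length=20_000,
        plasmid_backbone_length=1_500,
        mini_tn_length=600,
        target_site_position=10_000,
        read_length_mean=3_200,
        read_length_sd=100.0,
        substitution_rate=0.0,
        indel_rate=0.0,
        class_proportions={
            "simple_insertion": 0.45,
            "cointegrate": 0.25,
            "plasmid": 0.15,
            "off_target_simple": 0.10,
            "concatemer_cointegrate": 0.05,
        },
        span_fraction=1.0,
        n_reads=80,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_refs(small_config):
    return generate_references(small_config)


@pytest.fixture(scope="session")
def small_run(small_config, small_refs):
    reads, manifest = generate_reads(small_config, small_refs)
    return reads, manifest
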