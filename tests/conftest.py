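import pytest

from mirframe.io_formats import load_fixture_tables
from mirframe.mirna_discovery import discover
from mirframe.synthetic_data import (
    SimulationConfig,
    make_expression,
    make_go,
    make_transcriptome,
)

# flank used for synthetic discovery: covers the engineered precursor
# (~69 nt 3' of the mature) while keeping fold windows near 180 nt
SYNTH_FLANK = 80

ALL_PROFILES = (
    ("miR-101", "all_pass"),
    ("miR-102", "fail_mfe"),
    ("miR-103", "fail_arm"),
    ("miR-104", "fail_mismatches"),
    ("miR-105", "fail_loop"),
)


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def planted_sim():
    """One transcriptome carrying every compliance profile plus a planted
    perfect target site, with its truth table."""
    config = SimulationConfig(
        seed=7,
        n_transcripts=7,
        planted_precursors=ALL_PROFILES,
        planted_target_sites=("miR-101",),
    )
    return config, make_transcriptome(config)


@pytest.fixture(scope="session")
def planted_candidates(planted_sim):
    """Discovery output over the planted transcriptome (folds once)."""
    _, data = planted_sim
    return discover(data["transcripts"], data["mature"], flank=SYNTH_FLANK)


@pytest.fixture(scope="session")
def correlated_expression():
    """Replicate FPKM table with a planted rho = 0.95 pair at n = 50."""
    config = SimulationConfig(
        seed=11,
        n_genes=12,
        n_replicates=50,
        coexpressed_groups=((("gene001", "gene002"), 0.95),),
    )
    return config, make_expression(config)


@pytest.fixture(scope="session")
def synthetic_go():
    config = SimulationConfig(seed=3, n_go_terms=20, dag_depth=3, n_annotations=30)
    dag, annotations, truth = make_go(config)
    return dag, annotations, truth
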