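import numpy as np
import pytest

from crisprstat import (
    ArrayRecord,
    CasOperon,
    SimulationConfig,
    simulate_dataset,
    write_array_table,
    write_cas_table,
)


def make_array(**kwargs) -> ArrayRecord:
    defaults = dict(
        accession="ACC1.1",
        organism="Test organism",
        replicon_kind="chromosome",
        replicon_length=2_000_000,
        array_id="arr1",
        start_bp=1000,
        end_bp=3000,
        n_spacers=10,
        strand="+",
        questionable=False,
    )
    defaults.update(kwargs)
    return ArrayRecord(**defaults)


def make_operon(**kwargs) -> CasOperon:
    defaults = dict(
        accession="ACC1.1",
        system_class=1,
        system_type="I",
        subtype="I-E",
        operon_start_bp=10_000,
        operon_end_bp=20_000,
        strand="+",
        has_cas1=True,
    )
    defaults.update(kwargs)
    return CasOperon(**defaults)


@pytest.fixture
def three_arrays():
    return [
        make_array(array_id="arr1", start_bp=1000, end_bp=3000, n_spacers=5),
        make_array(array_id="arr2", start_bp=50_000, end_bp=52_000, n_spacers=30,
                   strand="-"),
        make_array(accession="ACC2.1", array_id="arr1", start_bp=100, end_bp=400,
                   n_spacers=2, strand="?", questionable=True),
    ]


@pytest.fixture
def array_table_path(tmp_path, three_arrays):
    path = tmp_path / "arrays.tsv"
    write_array_table(three_arrays, path)
    return path


@pytest.fixture
def cas_table_path(tmp_path):
    operons = [
        make_operon(accession="ACC1.1", subtype="I-E"),
        make_operon(accession="ACC1.1", subtype="I-F", operon_start_bp=500_000,
                    operon_end_bp=510_000),
        make_operon(accession="ACC2.1", system_type="III", subtype=None,
                    operon_start_bp=1000, operon_end_bp=9000),
    ]
    path = tmp_path / "cas.tsv"
    write_cas_table(operons, path)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-genome synthetic dataset shared across tests (seeded)."""
    cfg = SimulationConfig(n_genomes=120, seed=42, proximal_bias=0.8)
    return simulate_dataset(cfg)
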