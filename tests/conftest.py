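import pytest

from raretarget import (PipelineConfig, SimulationParams, simulate_inputs)
from raretarget.io_formats import load_table1_fixture, load_table2_fixture


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def table1_rows():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2_rows():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def small_params():
    """A compact simulation for fast structural tests."""
    return SimulationParams(n_chroms=2, chrom_length=1_000_000, n_genes=60,
                            n_tads_per_chrom=4, n_true_targets=10,
                            n_null_peaks=40, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return simulate_inputs(small_params)
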