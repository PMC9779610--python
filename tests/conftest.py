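import pytest

from vdjtrace.germline import load_toy_db
from vdjtrace.primers import load_toy_panel
from vdjtrace.sim import SimConfig, simulate_reads, simulate_sample


@pytest.fixture(scope="session")
def db():
    return load_toy_db()


@pytest.fixture(scope="session")
def panel():
    return load_toy_panel()


@pytest.fixture(scope="session")
def small_sample(db):
    """One 100-cell sample at 80% clonality, shared across read-level tests."""
    cfg = SimConfig(n_cells=100, clonal_fraction=0.8, seed=1234)
    cells, truth, reads = simulate_reads(db, cfg)
    return dict(config=cfg, cells=cells, truth=truth, reads=reads)


@pytest.fixture(scope="session")
def polyclonal_cells(db):
    cfg = SimConfig(n_cells=60, clonal_fraction=0.0, seed=99)
    cells, truth = simulate_sample(db, cfg)
    return cells, truth
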