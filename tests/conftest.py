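import numpy as np
import pytest

from isbh.cytoquant import calibrate_gateset
from isbh.fixtures import FixtureSpec, make_cytometry_tables, make_panel
from isbh.fold.model import EnergyModel
from isbh.seqcore import NucSeq


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def spacer():
    return NucSeq("sp1", "GACUGGAGCAGCUCUUCGGA")


@pytest.fixture(scope="session")
def panel():
    """Seeded 5x5 cognate design/trigger panel."""
    return make_panel(FixtureSpec(seed=11, n_spacers=5))


@pytest.fixture(scope="session")
def cyto_tables():
    """Untransfected / reporter / ON-sample event tables, n = 100,000."""
    spec = FixtureSpec(seed=5, n_events=100_000, on_fraction=0.25)
    return spec, make_cytometry_tables(spec)


@pytest.fixture(scope="session")
def calibrated_gates(cyto_tables):
    _, (untrans, reporter, _) = cyto_tables
    return calibrate_gateset(untrans, reporter, fraction=0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
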