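import pytest
from hypothesis import settings

from orichron.cell_cycle import CellCycleParams
from orichron import dnaa_cycle as dc

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cc() -> CellCycleParams:
    """Reference growth condition: C=42, D=33, tau=40 minutes."""
    return CellCycleParams(C=42.0, D=33.0, tau=40.0)


@pytest.fixture(scope="session")
def calibrated(cc):
    """Calibrated wild-type regulatory parameters plus the raw wild-type
    origins-per-mass baseline (shared across the model tests: calibration
    and baseline simulation are the expensive steps)."""
    reg = dc.calibrate(cc, seed=0)
    base = dc.raw_phenotype(dc.wild_type(), reg, cc, n_cells=150, seed=1)
    return reg, base
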