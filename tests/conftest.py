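import numpy as np
import pytest

from eacspec.media import build_intralipid_medium
from eacspec.optics import RefractivePair, ScattererSpec

#: working state of the 3% Intralipid analysis at 1000 nm
INTRALIPID_PHI = 0.03237
INTRALIPID_RADIUS_UM = 0.5
N_IN_1000 = 1.468
N_EX_1000 = 1.327


@pytest.fixture(scope="session")
def intralipid_spec() -> ScattererSpec:
    return ScattererSpec(
        radius_um=INTRALIPID_RADIUS_UM, volume_fraction=INTRALIPID_PHI
    )


@pytest.fixture(scope="session")
def refractive_1000() -> RefractivePair:
    return RefractivePair(n_in=N_IN_1000, n_ex=N_EX_1000)


@pytest.fixture(scope="session")
def full_grid() -> np.ndarray:
    return np.arange(1000.0, 1661.0, 10.0)


@pytest.fixture(scope="session")
def medium_3pct(full_grid):
    return build_intralipid_medium(3.0, full_grid)
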