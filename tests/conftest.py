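import numpy as np
import pytest

from permkin import (
    CellGeometry,
    DiffusionParams,
    DonorSpec,
    MembraneSpec,
)

@pytest.fixture
def membrane() -> MembraneSpec:
    return MembraneSpec(thickness_L=0.12, area_S=3.14)


@pytest.fixture
def donor() -> DonorSpec:
    return DonorSpec(concentration_Cd=1000.0)


@pytest.fixture
def params() -> DiffusionParams:
    return DiffusionParams(D=0.05, K=0.5)


@pytest.fixture
def geometry() -> CellGeometry:
    return CellGeometry(receptor_volume=12.5, sample_volume=0.25, area_S=3.14)


@pytest.fixture
def half_hour_schedule() -> np.ndarray:
    return np.arange(1, 13) * 0.5
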