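import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from braidfe.config import RunConfig
from braidfe.hexfem import box_mesh
from braidfe.materials import (
    BridgingParams,
    IsotropicMaterial,
    TransverselyIsotropicMaterial,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pcu() -> IsotropicMaterial:
    """Polycarbonate polyurethane matrix, MPa."""
    return IsotropicMaterial(E=57.0, v=0.43)


@pytest.fixture(scope="session")
def kevlar() -> TransverselyIsotropicMaterial:
    """Kevlar fiber, MPa; v23 follows from E22 and G23 by transverse isotropy."""
    return TransverselyIsotropicMaterial(
        E11=128700.0, E22=12870.0, v12=0.3, v23=12870.0 / (2 * 12870.0) - 1.0,
        G12=12870.0,
    )


@pytest.fixture(scope="session")
def study_params() -> BridgingParams:
    return BridgingParams(Vf=0.70, alpha=0.30, beta=0.30)


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def unit_cube():
    return box_mesh((1.0, 1.0, 1.0), (1, 1, 1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230716)
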