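import logging

import numpy as np
import pytest

from coroflow import BoundaryConditions, VesselProfile


@pytest.fixture(autouse=True)
def _quiet_advisories():
    """Keep Reynolds advisories out of test output; caplog re-enables."""
    logger = logging.getLogger("coroflow")
    old = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(old)


@pytest.fixture
def uniform_tube() -> VesselProfile:
    """Straight 3 mm x 30 mm tube: the Poiseuille closed-form reference."""
    return VesselProfile(np.array([0.0, 30.0]), np.array([3.0, 3.0]), label="tube")


@pytest.fixture
def stenosed_profile() -> VesselProfile:
    """Three-sample vessel with mid-vessel stenosis and downstream recovery."""
    return VesselProfile(np.array([0.0, 5.0, 10.0]), np.array([4.0, 2.0, 3.8]))


@pytest.fixture
def pressure_pair() -> BoundaryConditions:
    return BoundaryConditions(pa=100.0, pd=90.0)


def poiseuille_q_ml_min(d_mm: float, length_mm: float, dp_mmhg: float,
                        mu: float = 0.0035) -> float:
    """Independent closed-form Poiseuille flow for a straight tube, mL/min."""
    d = d_mm * 1e-3
    L = length_mm * 1e-3
    dp = dp_mmhg * 133.322
    q_si = np.pi * d**4 * dp / (128.0 * mu * L)
    return q_si * 6e7
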