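import numpy as np
import pytest

from arcuate import ScanGeometry, SimulationSpec, NoiseSpec


@pytest.fixture(scope="session")
def geometry() -> ScanGeometry:
    """Default right-eye scan geometry matching the model frame exactly
    (zero relative FD angle, BMO at the assumed ONH eccentricity)."""
    return ScanGeometry()


@pytest.fixture(scope="session")
def spec_superior() -> SimulationSpec:
    """Noise-free superior arcuate between initial angles 100 and 130 deg."""
    return SimulationSpec(beta_true=-1.9, phi0_pair=(100.0, 130.0), seed=7)


@pytest.fixture(scope="session")
def spec_inferior() -> SimulationSpec:
    """Noise-free inferior arcuate (internal angles -130 and -100 deg)."""
    return SimulationSpec(beta_true=0.7, phi0_pair=(-130.0, -100.0), seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20220707)
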