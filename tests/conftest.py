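import math

import numpy as np
import pytest

import bandgrad as bg

#: molar self-concentration of pure H2O with rounded inputs, mol/L
C_I = 55.56


@pytest.fixture(scope="session")
def geom() -> bg.CellGeometry:
    """12 mm Epon band-forming cell: 2.5 deg sector, bottom radius 7.166 cm."""
    return bg.CellGeometry(r_b=7.166, theta=math.radians(2.5), l=1.2)


@pytest.fixture(scope="session")
def overlay(geom) -> bg.OverlayState:
    """10 uL H2O overlay with the post-overlay meniscus at 6.5 cm."""
    return bg.make_overlay_state(geom, V_O=0.010, c_i=C_I, r_m=6.5)


@pytest.fixture(scope="session")
def diff() -> bg.DiffusionParams:
    """Mutual H2O/D2O diffusion coefficient at 20 C."""
    return bg.DiffusionParams(D=1.8e-5)


@pytest.fixture(scope="session")
def eig(overlay, geom) -> bg.EigenSystem:
    return bg.eigen_system(overlay.r_m, geom.r_b, 5000.0)


@pytest.fixture(scope="session")
def radii(overlay, geom) -> np.ndarray:
    return np.linspace(overlay.r_m, geom.r_b, 2001)
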