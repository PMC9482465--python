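"""Shared fixtures.

The expensive objects — the liquid droplet ensemble basis and the rendered
scenario bundles — are session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

import uedkit as u


@pytest.fixture(scope="session")
def glycerol():
    return u.build_glycerol()


@pytest.fixture(scope="session")
def s_grid():
    return u.default_s_grid()


@pytest.fixture(scope="session")
def gas_curves(glycerol, s_grid):
    """Atomic, molecular and total gas-phase glycerol curves on [0, 10]."""
    atomic = u.atomic_intensity(glycerol, s_grid)
    molecular = u.molecular_intensity(glycerol, s_grid)
    total = u.total_intensity(glycerol, s_grid)
    return atomic, molecular, total


@pytest.fixture(scope="session")
def wide_grid():
    """Grid covering the default detector's corners."""
    return u.default_s_grid(15.0, 0.02)


@pytest.fixture(scope="session")
def gas_basis(wide_grid):
    return u.gas_basis_curve(wide_grid)


@pytest.fixture(scope="session")
def liquid_basis(wide_grid):
    """Ensemble liquid basis at the study conditions (200 molecules,
    1.26 g/cm3, 3.2 Å contact, 10 seeds); per-molecule normalized."""
    return u.liquid_basis_curve(wide_grid)


@pytest.fixture(scope="session")
def noiseless_bundle(gas_basis, liquid_basis):
    config = u.ScenarioConfig(image_seeds=None)
    return u.generate_scenario(config, bases=(gas_basis, liquid_basis))


@pytest.fixture(scope="session")
def noisy_bundle(gas_basis, liquid_basis):
    config = u.ScenarioConfig()
    return u.generate_scenario(config, bases=(gas_basis, liquid_basis))


@pytest.fixture(scope="session")
def small_detector():
    """Quarter-size detector with the same s coverage, for cheap rendering."""
    return u.DetectorGeometry(
        pixel_pitch=0.12, n_pixels=(512, 512), beam_center=(255.5, 255.5)
    )


def rel_rms(a, b):
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2)))
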