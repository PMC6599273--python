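"""Shared fixtures: small phantom cohorts and simple synthetic volumes."""

import numpy as np
import pytest

from mwradiomics.phantoms import PhantomConfig, generate_cohort
from mwradiomics.radiomics import RadiomicsExtractor


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient, 2-timepoint phantom cohort reused across tests."""
    cfg = PhantomConfig(n_patients=12, seed=11)
    cohort, truth, clinical = generate_cohort(cfg)
    return cfg, cohort, truth, clinical


@pytest.fixture(scope="session")
def extractor():
    return RadiomicsExtractor()


@pytest.fixture()
def part_solid_volume():
    """A simple part-solid nodule: solid core (HU 40) inside a ground-glass
    shell (HU -500) on parenchyma background (-850), no noise."""
    vol = np.full((32, 32, 32), -850.0)
    z, y, x = np.ogrid[:32, :32, :32]
    r2 = (z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2
    vol[r2 <= 100] = -500.0  # rim, radius 10
    vol[r2 <= 25] = 40.0     # core, radius 5
    return vol


@pytest.fixture()
def sphere_mask():
    """Uniform sphere of radius 10 voxels in a 32^3 grid, with its volume."""
    z, y, x = np.ogrid[:32, :32, :32]
    mask = ((z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2) <= 100
    return mask
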