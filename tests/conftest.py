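"""Shared builders for small, hand-constructed volumes and masks."""

import numpy as np
import pytest

from petseg import ImageGrid, ROIMask, SUVVolume
from petseg.phantom import Lesion, PhantomConfig, generate_phantom


def make_grid(shape=(5, 5, 5), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ImageGrid(shape=shape, spacing=spacing, origin=origin)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return SUVVolume(make_grid(values.shape, spacing), values)


def make_mask(grid, indices):
    ind = np.zeros(grid.shape, dtype=bool)
    for idx in indices:
        ind[tuple(idx)] = True
    return ROIMask(grid, ind)


def full_mask(grid):
    return ROIMask(grid, np.ones(grid.shape, dtype=bool))


@pytest.fixture
def uniform_sphere_case():
    """Noiseless, unblurred uniform sphere (SUV 10) on zero background."""
    grid = ImageGrid((41, 41, 41), (2.73, 2.73, 3.27))
    centre = tuple((n - 1) / 2 * s for n, s in zip(grid.shape, grid.spacing))
    cfg = PhantomConfig(
        grid=grid,
        lesions=(Lesion(centre, (15.0, 15.0, 15.0), 10.0),),
        background_suv=0.0,
        psf_fwhm_mm=0.0,
        noise_sd_suv=0.0,
    )
    return generate_phantom(cfg, case_id="uniform-sphere")
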