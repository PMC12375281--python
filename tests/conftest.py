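import numpy as np
import pytest

from segunc.grids import ImageGrid, LabelVolume
from segunc.synthetic_study import StudyConfig


@pytest.fixture
def unit_grid():
    """16^3 grid at 1 mm isotropic spacing."""
    return ImageGrid(shape=(16, 16, 16), spacing_mm=(1.0, 1.0, 1.0))


@pytest.fixture
def tiny_cfg():
    """Scaled-down study for fast end-to-end tests (anatomy shrunk to fit)."""
    return StudyConfig(
        n_cases=2,
        K=4,
        shape=(20, 32, 32),
        spacing_mm=(2.5, 0.9, 0.9),
        prostate_radii_mm=((6.0, 7.0), (5.0, 6.0), (6.0, 7.0)),
        rectum_radius_mm=3.5,
        rectum_sway_mm=2.0,
        boundary_softness_mm=1.0,
        field_sd_mm=3.0,
        field_corr_mm=6.0,
        bias_sd_mm=1.5,
        bias_corr_mm=10.0,
        agreement_corr_mm=10.0,
        block_rows=3,
        seed=11,
    )


def make_label(grid: ImageGrid, mask: np.ndarray) -> LabelVolume:
    return LabelVolume(grid=grid, voxels=mask.astype(np.uint8))


def random_mask(shape, p, rng) -> np.ndarray:
    return (rng.random(shape) < p).astype(np.uint8)


def cube_mask(shape, lo, hi) -> np.ndarray:
    m = np.zeros(shape, dtype=np.uint8)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return m
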