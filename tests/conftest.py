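import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radiomod import PhantomSpec, PlantedDesign, gen_cohort, gen_phantom
from radiomod.preprocess import VolumeWithMask, discretize


@pytest.fixture
def small_textured_volume():
    """A 5x5x5 volume with a hand-drawn irregular mask and varied levels."""
    rng = np.random.default_rng(42)
    intensities = rng.integers(0, 120, size=(5, 5, 5)).astype(float)
    mask = rng.random((5, 5, 5)) < 0.7
    mask[2, 2, 2] = True  # guarantee nonempty
    return VolumeWithMask(intensities, mask, (1.0, 1.0, 1.0))


@pytest.fixture
def small_gray(small_textured_volume):
    return discretize(small_textured_volume, bin_width=30.0)


@pytest.fixture
def noise_sphere():
    spec = PhantomSpec(
        shape_kind="sphere",
        size_mm=14,
        texture_kind="gaussian_noise",
        texture_params=(("value", 100.0), ("sd", 20.0)),
        seed=7,
    )
    return gen_phantom(spec)


@pytest.fixture
def linked_cohort():
    """A small cohort with one feature linked to one gene set (s = 0.8)."""
    design = PlantedDesign(
        n_patients=200,
        n_genes=120,
        gene_sets=(("SETA", tuple(f"G{j:05d}" for j in range(15))),
                   ("SETB", tuple(f"G{j:05d}" for j in range(15, 35)))),
        links=(("feat_x", "SETA", 0.8),),
        n_noise_features=5,
        survival_link=("feat_x", 0.0),
        censor_rate=0.2,
        seed=11,
    )
    return gen_cohort(design, "test")
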