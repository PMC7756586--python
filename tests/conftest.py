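import numpy as np
import pytest

from cascadeseg.extent import ClassifierConfig, ExtentInterval, pad_extent, train_presence_classifier
from cascadeseg.optim import OptimizerConfig
from cascadeseg.phantom import PhantomSpec, generate_cohort, generate_phantom
from cascadeseg.segmentation import AugmentSpec, train_refine_segmenter, train_segmenter

SMALL_GRID = (32, 48, 48)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(grid_shape=SMALL_GRID, noise_sigma=0.0)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(PhantomSpec(grid_shape=SMALL_GRID), n=6, seed=7)


def true_extent(sset, structure, n_slices, pad=1):
    zs = np.flatnonzero(sset.masks[structure].any(axis=(1, 2)))
    return pad_extent(ExtentInterval(int(zs.min()), int(zs.max())), n_slices, pad)


@pytest.fixture(scope="session")
def bladder_extents(small_cohort):
    return {s.volume_id: true_extent(s, "bladder", v.n_slices)
            for v, s in small_cohort}


@pytest.fixture(scope="session")
def trained_bladder(small_cohort, bladder_extents):
    """Coarse + refine bladder models shared across segmentation tests."""
    opt = OptimizerConfig(learning_rate=0.1, epochs=20, seed=3)
    aug = AugmentSpec()
    coarse = train_segmenter(small_cohort, "bladder", "3d", opt, aug,
                             extents=bladder_extents, coarse_shape=(24, 24))
    refine, box = train_refine_segmenter(small_cohort, "bladder", opt, aug)
    return {"coarse": coarse, "refine": refine, "box": box}


@pytest.fixture(scope="session")
def trained_bladder_classifier(small_cohort):
    cfg = ClassifierConfig(optimizer=OptimizerConfig(learning_rate=0.3, epochs=150),
                           seed=11)
    return train_presence_classifier(small_cohort, "bladder", cfg)
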