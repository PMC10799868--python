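import numpy as np
import pytest

from neurosig.data_model import CLASS_LABELS, BetaMap, BetaMapSet, BrainMask
from neurosig.synthetic import (
    GeneratorConfig,
    SignalRegion,
    SiteEffect,
    generate,
)


@pytest.fixture
def cube_mask():
    """All-true 4x4x4 mask at 3-mm isotropic resolution."""
    return BrainMask(
        inside=np.ones((4, 4, 4), dtype=bool), affine=np.diag([3.0, 3.0, 3.0, 1.0])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(mask, n_subjects, rng, site_id="siteA", prefix="sub"):
    """Random BetaMapSet: one map per subject per class."""
    maps = [
        BetaMap(
            f"{prefix}{j:03d}", label, site_id, rng.standard_normal(mask.n_voxels)
        )
        for j in range(n_subjects)
        for label in CLASS_LABELS
    ]
    return BetaMapSet(mask=mask, maps=maps)


@pytest.fixture
def random_set(cube_mask, rng):
    return make_set(cube_mask, 6, rng)


@pytest.fixture(scope="session")
def signal_train():
    """Moderate-size training set with separable class signal (session-scoped:
    reused by classifier and signature tests)."""
    grid = (10, 12, 10)
    cx, cy, cz = 5, 6, 5
    regions = [
        SignalRegion((cx - 2, cy - 3, cz), 2.0, (0.0, 0.0, 2.0)),
        SignalRegion((cx + 2, cy + 3, cz), 2.0, (0.0, 2.0, 0.0)),
    ]
    config = GeneratorConfig(
        grid_shape=grid,
        n_subjects=24,
        sites=[SiteEffect("siteA")],
        regions=regions,
        subject_sd=0.2,
        noise_sd=0.4,
        seed=7,
    )
    data, truth = generate(config)
    return data, truth
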