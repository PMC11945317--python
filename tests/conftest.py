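import numpy as np
import pytest

from splatplant import GaussianScene, PlantSceneSpec, make_plant_scene


def random_scene(rng: np.random.Generator, n: int,
                 scale_range=(0.5e-3, 5e-3), extent=0.3) -> GaussianScene:
    """Random valid scene with anisotropic Gaussians near the origin."""
    q = rng.standard_normal((n, 4))
    return GaussianScene(
        means=rng.uniform(-extent, extent, (n, 3)),
        scales=rng.uniform(*scale_range, (n, 3)),
        rotations=q / np.linalg.norm(q, axis=1, keepdims=True),
        opacities=rng.uniform(0.05, 1.0, n),
        sh_coeffs=rng.uniform(-0.5, 0.5, (n, 3, 16)),
    )


@pytest.fixture(scope="session")
def plant_fixture():
    """Default toy plant scene with ground truth and labels (seeded)."""
    return make_plant_scene(PlantSceneSpec(seed=11))


@pytest.fixture(scope="session")
def small_plant_fixture():
    """Light fixture for render-heavy tests."""
    spec = PlantSceneSpec(n_stem_segments=150, leaf_count=2, leaf_length=0.12,
                          background_count=9, seed=5)
    return make_plant_scene(spec)
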