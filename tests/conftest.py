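"""Shared fixtures: small generated scenes and (session-cached) histograms."""

import numpy as np
import pytest

from phenoseg.features import FeatureParams, compute_histograms
from phenoseg.io import PointCloud
from phenoseg.scenes import PrimitiveSpec, SceneSpec, generate_scene, sample_primitive


@pytest.fixture(scope="session")
def plane_cloud():
    """Noise-free 10x10 mm plane patch at z=0, 0.5 mm pitch (441 points)."""
    return sample_primitive(
        PrimitiveSpec("plane_patch", 1, length=10, width=10), 0.5, 0.0, 0
    )


@pytest.fixture(scope="session")
def cylinder_cloud():
    """Noise-free cylinder, radius 5 mm about the z axis, 0.5 mm sampling."""
    return sample_primitive(
        PrimitiveSpec("cylinder", 1, radius=5.0, length=30.0), 0.5, 0.0, 0
    )


@pytest.fixture(scope="session")
def plane_histograms(plane_cloud):
    return compute_histograms(plane_cloud)


@pytest.fixture(scope="session")
def cylinder_histograms(cylinder_cloud):
    return compute_histograms(cylinder_cloud)


@pytest.fixture(scope="session")
def small_noisy_scene():
    """A stem segment plus one bent leaf, with scanner-level noise."""
    spec = SceneSpec(
        primitives=(
            PrimitiveSpec("cylinder", 1, radius=2.0, length=25.0),
            PrimitiveSpec(
                "plane_patch", 2, length=25.0, width=12.0, bend=0.01,
                origin=(5.0, 0.0, 5.0), euler_zyx=(0.3, -0.7, 0.0),
            ),
        ),
        noise_sigma=0.045,
        seed=3,
    )
    return spec, generate_scene(spec)


@pytest.fixture(scope="session")
def barley_scene():
    """The barley-like preset at scanner noise, with its histograms.

    Computed once per session; the histogram pass is the expensive stage.
    """
    from phenoseg.scenes import barley_like

    spec = barley_like(seed=1, noise_sigma=0.045)
    pc = generate_scene(spec)
    hs = compute_histograms(pc)
    return spec, pc, hs


def random_simplex(rng: np.random.Generator, m: int, n: int = 1, zeros: bool = False):
    """Random simplex vectors; optionally with a sprinkling of exact zeros."""
    x = rng.dirichlet(np.ones(m) * 0.5, size=n)
    if zeros:
        mask = rng.random(x.shape) < 0.3
        x = np.where(mask, 0.0, x)
        keep = x.sum(axis=1) > 0
        x = x[keep]
        x /= x.sum(axis=1, keepdims=True)
    return x[0] if n == 1 and len(x) else x
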