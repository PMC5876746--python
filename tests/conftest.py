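import numpy as np
import pytest

from bunch3d import DetectionParams


def sample_sphere(rng, center, radius, n, noise=0.0):
    """Area-uniform surface samples of a sphere, optional isotropic noise."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = np.asarray(center, dtype=float) + radius * u
    if noise > 0:
        pts = pts + rng.normal(0, noise, size=pts.shape)
    return pts


def assert_model_valid(model, points, params: DetectionParams):
    """Post-hoc check of every SphereModel type invariant."""
    assert params.min_radius <= model.radius <= params.max_radius
    assert model.n_inliers >= params.min_supporters
    d = np.abs(np.linalg.norm(points[model.inlier_indices] - model.center, axis=1)
               - model.radius)
    assert (d <= params.inlier_distance + 1e-9).all()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
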