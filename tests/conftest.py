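import numpy as np
import pytest

from dosewarp.synthetic import (
    DeformSpec,
    PhantomSpec,
    generate_displacement,
    generate_phantom,
    make_pair,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return generate_phantom(phantom_spec, seed=7)


@pytest.fixture(scope="session")
def pair(phantom_spec, phantom):
    field = generate_displacement(
        DeformSpec(amplitude=4.0, smoothness_sigma=12.0, seed=3),
        phantom_spec.grid_shape,
        phantom_spec.spacing,
    )
    return make_pair(phantom, field)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def finite_diff_check(loss_fn, x, analytic, rng, eps=1e-6, n_probe=10, tol=1e-5):
    """Assert analytic gradients match central differences at probed entries."""
    for _ in range(n_probe):
        i = tuple(rng.integers(0, s) for s in x.shape)
        x0 = x[i]
        x[i] = x0 + eps
        fp = loss_fn()
        x[i] = x0 - eps
        fm = loss_fn()
        x[i] = x0
        num = (fp - fm) / (2 * eps)
        denom = max(1e-8, abs(num), abs(analytic[i]))
        assert abs(num - analytic[i]) / denom < tol


def random_mask(rng, shape=(12, 12, 10), p=0.3, spacing=(1.0, 1.0, 1.0)):
    from dosewarp.grids import Mask3D

    data = rng.random(shape) < p
    if not data.any():
        data[tuple(s // 2 for s in shape)] = True
    return Mask3D(data, spacing)
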