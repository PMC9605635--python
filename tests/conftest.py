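import numpy as np
import pytest

from gliomics import LesionSpec, PhantomSpec, make_phantom


@pytest.fixture
def sphere_phantom():
    """Factory for a single-sphere phantom; returns (grid, truth)."""

    def make(radius=10.0, spacing=1.0, shape=None, noise_sd=0.0, seed=1,
             rim_suv=2.0, background_suv=0.2, **lesion_kwargs):
        if shape is None:
            bump = lesion_kwargs.get("bumpiness", 0.0)
            n = int(round(2 * radius * (1 + bump) / spacing)) + 16
            shape = (n, n, n)
        center = tuple((s // 2) * spacing for s in shape)
        lesion = LesionSpec(center=center, base_radius=radius, rim_suv=rim_suv,
                            **lesion_kwargs)
        spec = PhantomSpec(grid_shape=shape, spacing=(spacing,) * 3,
                           lesions=[lesion], background_suv=background_suv,
                           noise_sd=noise_sd, seed=seed)
        return make_phantom(spec)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
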