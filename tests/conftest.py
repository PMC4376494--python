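import numpy as np
import pytest

from vesselem import PhantomSpec, generate_phantom


def small_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Fast 192x192 phantom used by unit tests."""
    params = dict(width=192, height=192, n_trees=2, width_root=3.0,
                  aperture_radius=85.0, seed=seed)
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec(seed=3)
    truth, centerlines, render = generate_phantom(spec)
    return spec, truth, centerlines, render


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
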