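import numpy as np
import pytest

import densitex as dx


@pytest.fixture(scope="session")
def phantom_grid():
    """One phantom per (class, view) pair at the default resolution."""
    out = {}
    for cls in dx.synthetic.BIRADS_CLASSES:
        for view in ("MLO", "CC"):
            spec = dx.PhantomSpec(class_label=cls, view=view, seed=11)
            out[(cls, view)] = dx.generate_phantom(spec)
    return out


@pytest.fixture(scope="session")
def mlo_sample(phantom_grid):
    return phantom_grid[("III", "MLO")]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
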