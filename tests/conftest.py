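import numpy as np
import pytest

import mnkit as mk


@pytest.fixture(scope="session")
def icm20():
    """Default monolayer simulation, 20-min stimulation, seed 0."""
    return mk.simulate_preset("icm_default", period=20.0, seed=0)


@pytest.fixture(scope="session")
def sa20():
    return mk.simulate_preset("sa_default", period=20.0, seed=0)


@pytest.fixture(scope="session")
def sparse_rendered():
    """A short resolvable-density movie rendered noise-free, with its
    ground-truth dataset."""
    from mnkit.render import render_frames

    ds = mk.simulate_preset("icm_default", period=20.0, seed=3,
                            with_junctions=False, duration=160.0,
                            density=300.0, min_separation=30.0)
    stack = render_frames(ds, pixel_size=1.0, snr=None)
    return ds, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
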