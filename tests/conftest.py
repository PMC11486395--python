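import numpy as np
import pandas as pd
import pytest

from spatalign import FixtureSpec, PointSet, ScaleSpec, Session, make_section


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_spec():
    return ScaleSpec(data_scale=1.0, image_scale=1.0, display_scale=1.0)


@pytest.fixture
def random_points(rng):
    n = 500
    return PointSet(ids=np.arange(n),
                    x=rng.uniform(-100, 100, n),
                    y=rng.uniform(-100, 100, n))


@pytest.fixture
def counted_points(rng):
    """Small annotated point set with a Poisson count matrix."""
    n, g = 30, 8
    counts = pd.DataFrame(rng.poisson(3.0, size=(g, n)),
                          index=[f"g{i}" for i in range(g)],
                          columns=np.arange(n))
    return PointSet(ids=np.arange(n),
                    x=rng.uniform(0, 500, n), y=rng.uniform(0, 500, n),
                    annotation=rng.choice(["a", "b"], n), counts=counts)


@pytest.fixture
def session(random_points, unit_spec):
    return Session(random_points, unit_spec)


@pytest.fixture(scope="session")
def small_section():
    return make_section(FixtureSpec(seed=7))
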