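import numpy as np
import pytest

from saxseg.preprocess import CurveMatrix
from saxseg.synthdata import (
    PhantomSpec,
    PhaseSpectrum,
    blob_weight_map,
    generate_phantom,
    quadrant_sites,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 16x16 two-phase phantom with hard boundaries."""
    q = np.geomspace(1.0, 30.0, 400)
    phases = [
        PhaseSpectrum(
            peaks=((8.0, 0.5, 20.0), (20.0, 1.0, 10.0)),
            powerlaw_exponent=2.0,
            powerlaw_amplitude=10.0,
            flat_background=1.0,
        ),
        PhaseSpectrum(
            peaks=((12.0, 0.6, 15.0),),
            powerlaw_exponent=3.0,
            powerlaw_amplitude=50.0,
            flat_background=2.0,
        ),
    ]
    wmap = blob_weight_map(
        16, 16, 2, mix_width=0.0, sites=np.array([[4.0, 8.0], [12.0, 8.0]])
    )
    spec = PhantomSpec(
        q_grid=q, phases=phases, weight_map=wmap, counts_scale=1e5, seed=7
    )
    return generate_phantom(spec)


@pytest.fixture
def log_uniform_grid():
    """Dense log-uniform q grid for derivative tests."""
    return np.geomspace(1.0, 4.0, 300)


def make_matrix(values, q):
    return CurveMatrix(values=np.atleast_2d(values), q_centers=q)
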