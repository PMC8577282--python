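import numpy as np
import pytest

from dirgmm.model import DirectionalGmmParams, GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


def random_spd(rng, d, scale=1.0):
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T / d + np.eye(d))


def random_params(rng, grid: GridSpec, d: int) -> DirectionalGmmParams:
    """A valid random parameter set for a given grid (small d, test scale)."""
    S = grid.n_clusters
    delta = rng.standard_normal(d)
    dperp = None
    if grid.rows == 2:
        dperp = rng.standard_normal(d)
        dperp -= (dperp @ delta) / (delta @ delta) * delta
    mu = rng.standard_normal((S, d)) * 2.0
    pi = rng.dirichlet(np.ones(S))
    Sigma = np.stack([random_spd(rng, d) for _ in range(S)])
    return DirectionalGmmParams(
        mu=mu,
        Sigma=Sigma,
        pi=pi,
        Delta=delta,
        Q=random_spd(rng, d, 0.5),
        Q0=random_spd(rng, d, 2.0),
        mu0=rng.standard_normal(d),
        Delta_perp=dperp,
    )


@pytest.fixture
def small_1d_instance(rng):
    """Random 1-D chain instance: 3 clusters, d=2, 12 points."""
    grid = GridSpec(3, 1)
    params = random_params(rng, grid, 2)
    X = rng.standard_normal((12, 2))
    return grid, params, X
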