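"""Shared fixtures: small landscapes and a reusable discretized campaign."""

import numpy as np
import pytest

from memmpath.discretize import discretize_ensemble
from memmpath.landscape import Landscape, two_well_landscape
from memmpath.simulate import emit_features, simulate_umbrella_campaign
from memmpath.tram import estimate_tram


@pytest.fixture(scope="session")
def flat_landscape():
    return Landscape(terms=(), z_range=(-10.0, 10.0), wall_k=0.0)


@pytest.fixture(scope="session")
def twowell():
    """Charged-variant two-well landscape with conformational coupling."""
    return two_well_landscape(variant="charged", coupling=1.0)


@pytest.fixture(scope="session")
def small_campaign(twowell):
    """A small umbrella + unbiased campaign with features attached.

    Deliberately modest (21 windows, ~2 ns each) so estimator tests stay
    fast; accuracy-critical checks use their own larger runs.
    """
    trajs = simulate_umbrella_campaign(
        twowell, n_steps_window=20_000, n_steps_unbiased=20_000, dt=1e-4,
        master_seed=123, spacing=1.0, k_bias=10.0, stride=20,
        equil_steps=2_000, unbiased_every=2)
    return emit_features(trajs, D=12, snr=20.0, seed=5)


@pytest.fixture(scope="session")
def small_discrete(small_campaign):
    tic = [t.c[:, None] for t in small_campaign]
    return discretize_ensemble(small_campaign, tic, n_zbins=50,
                               n_clusters=2, seed=0)


@pytest.fixture(scope="session")
def small_memm(small_discrete):
    return estimate_tram(small_discrete, lag=50, tol=1e-9, max_iter=20_000,
                         dt_ns=0.002)


def make_dtraj(T, n, seed, start=0):
    """Sample a discrete trajectory from a transition matrix."""
    rng = np.random.default_rng(seed)
    d = np.empty(n, dtype=int)
    d[0] = start
    cum = np.cumsum(T, axis=1)
    u = rng.random(n - 1)
    for t in range(1, n):
        d[t] = np.searchsorted(cum[d[t - 1]], u[t - 1])
    return d


@pytest.fixture
def chain_sampler():
    return make_dtraj
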