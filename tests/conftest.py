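"""Shared fixtures: fitted phase reductions are expensive (sparse eigensolves
on 120x120 grids), so they are computed once per session and shared."""

import numpy as np
import pytest

import stochphase as sp

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

#: the packaged study configurations
CONFIGS = {
    "spiral_sink": ("spiral_sink", {}),
    "wilson_cowan": ("wilson_cowan", {}),
    "van_der_pol": ("van_der_pol", {}),
    "het_low": ("heteroclinic", {}),
    "het_high": ("heteroclinic", {"D": 0.1}),
}


@pytest.fixture(scope="session")
def fitted():
    """Lazy per-session cache of fitted 120x120 phase reductions."""
    cache = {}

    def get(key, **overrides):
        tag = (key, tuple(sorted(overrides.items())))
        if tag not in cache:
            name, kw = CONFIGS[key]
            cache[tag] = sp.StochasticOscillator.from_name(
                name, **{**kw, **overrides}).fit(seed=1)
        return cache[tag]

    return get


@pytest.fixture(scope="session")
def mrt_reports(fitted):
    """Lazy per-session cache of Monte-Carlo MRT uniformity reports
    (n = 10^4 paths, dt = 1e-3, horizon 3*T-bar, fixed seeds)."""
    cache = {}

    def get(key, which, **kw):
        tag = (key, which, tuple(sorted(kw.items())))
        if tag not in cache:
            res = fitted(key)
            cache[tag] = res.mrt_check(which=which, isochron_level=0.0,
                                       k_points=3, n=10_000, dt=1e-3,
                                       seed=11, **kw)
        return cache[tag]

    return get


@pytest.fixture(scope="session")
def oup_params():
    """The canonical spiral-sink parameter set used throughout."""
    return sp.make_model("spiral_sink").canonical_oup


def random_admissible_oup(rng):
    """Random stable canonical parameters with PSD diffusion."""
    mu = -float(rng.uniform(0.02, 1.0))
    omega = float(rng.uniform(0.2, 2.0))
    eps = float(rng.uniform(1e-4, 0.05))
    b = rng.uniform(0, 0.95)
    phi = rng.uniform(0, 2 * np.pi)
    return sp.CanonicalOUP(mu=mu, omega=omega, eps=eps,
                           beta_d=float(b * np.cos(phi)),
                           beta_c=float(b * np.sin(phi)))
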