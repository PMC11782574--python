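"""Shared fixtures: configurations and cached simulation runs.

Expensive coupled runs are session-scoped so the whole suite pays for each
configuration once.  The "reduced" scale (narrow domain, coarse elements,
few fibers) keeps single runs at a few seconds while preserving the physics:
full tissue depth (fold/arrival timing), folding onset near T ~ 0.55, and
energy ratios within the quasi-static bound.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from foldax.config import SimulationConfig


@pytest.fixture(scope="session")
def reduced_config() -> SimulationConfig:
    """Coupled-run configuration small enough for the test suite."""
    return SimulationConfig(
        w=24.0,
        h=30.0,
        t_c=1.5,
        elem_size=0.75,
        substeps=80,
        agent_steps=500,
        n_fibers=12,
        seed=0,
    )


@pytest.fixture(scope="session")
def micro_config() -> SimulationConfig:
    """Tiny configuration for exercising code paths, not physics."""
    return SimulationConfig(
        w=6.0,
        h=4.5,
        t_c=1.5,
        elem_size=0.75,
        seed_band=2.0,
        agent_steps=50,
        substeps=20,
        n_fibers=3,
        n_replicates=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def baseline_run(reduced_config):
    """One full reduced coupled run, shared across integration tests."""
    from foldax.driver import run_simulation

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_simulation(reduced_config, record_trajectories=True)


@pytest.fixture(scope="session")
def trend_config() -> SimulationConfig:
    """Ensemble scale for trend acceptance tests (paired, 20 fibers)."""
    return SimulationConfig(
        w=24.0,
        h=30.0,
        t_c=1.5,
        elem_size=0.75,
        substeps=80,
        agent_steps=500,
        n_fibers=20,
        seed=0,
    )


#: scenario name -> config overrides relative to trend_config
TREND_SCENARIOS = {
    "gaxn0.6": dict(G_axn=0.6),
    "base": {},
    "gaxn1.2": dict(G_axn=1.2),
    "muf1": dict(mu_f_over_mu_s=1.0),
    "muc1": dict(mu_c_over_mu_s=1.0),
    "noise0.05": dict(noise_std=0.05),
    "off0.6": dict(G_axn=0.6, reorientation_enabled=False),
    "off0.8": dict(reorientation_enabled=False),
}


@pytest.fixture(scope="session")
def trend_ensembles(trend_config):
    """10-replicate ensembles for every trend scenario (common random numbers)."""
    from foldax.driver import run_ensemble

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, overrides in TREND_SCENARIOS.items():
            out[name] = run_ensemble(trend_config.replace(**overrides))
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
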