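"""Shared fixtures: expensive simulation runs computed once per session."""

import numpy as np
import pytest

import gamdkit as gk


@pytest.fixture(scope="session")
def doublewell_benchmark():
    """Default symmetric double-well GaMD benchmark (1e6 production steps)."""
    potential = gk.make_double_well(barrier_height=6.0, well_separation=2.0)
    config = gk.SimulationConfig(
        n_steps_cmd=2000, n_steps_equil=20000, n_steps_production=1_000_000,
        save_stride=10, seed=0,
    )
    result = gk.run_gamd(potential, config)
    return potential, config, result


@pytest.fixture(scope="session")
def experiment_summary():
    """Default two-arm, five-seed toy allosteric experiment."""
    return gk.run_experiment(gk.default_experiment_config())


@pytest.fixture(scope="session")
def allosteric_dual_boost_run():
    """Default allosteric system under dual boost in the perturbative regime."""
    system = gk.make_allosteric_toy()
    config = gk.SimulationConfig(
        n_steps_cmd=2000, n_steps_equil=30000, n_steps_production=150000,
        save_stride=5, boost_mode="dual", component_terms=("sb",),
        sigma0=0.5, seed=0,
    )
    return system, config, gk.run_gamd(system, config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
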