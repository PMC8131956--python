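"""Shared fixtures: the synthetic mini-Fab and small condition trajectories.

Everything is generated programmatically and deterministically (fixed
seeds), so the suite needs no data files.
"""

import numpy as np
import pytest

from stressmap.synthetic import (ToyFabSpec, build_toy_fab, default_profiles,
                                 simulate_stress_trajectory, toy_apr_set,
                                 toy_domain_map, toy_strand_map)

SEED = 20240917
N_FRAMES = 21
N_REPLICATES = 2


@pytest.fixture(scope="session")
def toy_spec():
    return ToyFabSpec()


@pytest.fixture(scope="session")
def toy_fab(toy_spec):
    return build_toy_fab(toy_spec)


@pytest.fixture(scope="session")
def domain_map(toy_spec):
    return toy_domain_map(toy_spec)


@pytest.fixture(scope="session")
def strand_map(toy_spec):
    return toy_strand_map(toy_spec)


@pytest.fixture(scope="session")
def apr_set(toy_spec):
    return toy_apr_set(toy_spec)


def _condition(name, base, spec):
    profile = default_profiles(seed=SEED)[name]
    return simulate_stress_trajectory(base, profile, n_frames=N_FRAMES,
                                      n_replicates=N_REPLICATES, spec=spec)


@pytest.fixture(scope="session")
def reference_runs(toy_fab, toy_spec):
    return _condition("reference", toy_fab, toy_spec)


@pytest.fixture(scope="session")
def low_ph_runs(toy_fab, toy_spec):
    return _condition("low_ph_like", toy_fab, toy_spec)


@pytest.fixture(scope="session")
def high_temp_runs(toy_fab, toy_spec):
    return _condition("high_temp_like", toy_fab, toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
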