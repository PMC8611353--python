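"""Shared fixtures: small solved states and synthetic datasets.

Everything is generated programmatically at session scope so expensive
solves are shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spheroidfit.ebt import init_masses, evolve
from spheroidfit.inference import LogPosterior, SolverSettings
from spheroidfit.kernels import ModelParams
from spheroidfit.observation import InitialProfileSpec, initial_profile
from spheroidfit.synthetic import preset, simulate_dataset


@pytest.fixture(scope="session")
def v79():
    pre, priors = preset("V-79")
    return pre, priors


@pytest.fixture(scope="session")
def small_params():
    """A compact, fast configuration used across solver tests."""
    return ModelParams(alpha=1.0, sigma_k=0.06, sigma_o=0.05, sigma_i=0.3)


@pytest.fixture(scope="session")
def small_trajectory(small_params):
    """EBT solution of the compact configuration on [0, 6] days."""
    prof = initial_profile(InitialProfileSpec(sigma_i=small_params.sigma_i))
    state = init_masses(prof, N=300, R0=1.6)
    return evolve(state, small_params, np.linspace(0.0, 6.0, 13), method="rk45")


@pytest.fixture(scope="session")
def v79_dataset(v79):
    """Synthetic V-79 dataset on the fitting grid (matched geometry)."""
    pre, priors = v79
    truth = ModelParams(
        alpha=pre.prior_alpha, sigma_k=pre.prior_sigma_k, sigma_o=0.05, sigma_i=pre.prior_sigma_i
    )
    probe = simulate_dataset(truth, pre.schedule, seed=1)
    solver = SolverSettings(R0=LogPosterior(probe, priors, SolverSettings()).solver.R0)
    ds = simulate_dataset(truth, pre.schedule, solver=solver, seed=123)
    return ds, truth, solver
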