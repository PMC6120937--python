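"""Shared fixtures: synthetic sessions and derived pipeline objects.

Sessions are generated once per test run (session scope) at sizes chosen to
keep the full suite fast while leaving enough trials per direction for the
cluster-based analyses.
"""

from __future__ import annotations

import numpy as np
import pytest

import planstate as ps
from planstate.pipeline import SessionAnalysis


@pytest.fixture(scope="session")
def medium_session() -> ps.Session:
    """Balanced 200-trial session (10 1-Target trials per direction)."""
    return ps.generate_session(n_trials=200, seed=5)


@pytest.fixture(scope="session")
def medium_analysis(medium_session) -> SessionAnalysis:
    return SessionAnalysis(medium_session)


@pytest.fixture(scope="session")
def quiet_population() -> ps.PopulationModel:
    """Small population with excess variability switched off (pure Poisson)."""
    return ps.generate_population(
        ps.PopulationSpec(
            n_units=20,
            unit_gain_sd=0.0,
            unit_gain_trial_sd=0.0,
            population_gain_sd=0.0,
            shared_noise_sd=0.0,
            drift_step_sd=0.0,
            seed=3,
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
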