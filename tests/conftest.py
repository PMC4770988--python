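"""Shared fixtures: synthetic sessions at two scales.

``small_spec`` sessions (24 stimuli, ~3 min) keep unit tests fast; the
session-scoped full-size fixtures are generated once and shared by the tests
that need the study's real geometry (128 stimuli, 2–3 min lead-in).
"""

import numpy as np
import pytest

from gw6.core import GW6Config
from gw6.synthetic import CouplingSpec, SessionSpec, gen_background, gen_schedule, gen_session_pair, inject_sync


def make_small_spec(seed: int = 0, **overrides) -> SessionSpec:
    params = dict(
        n_stimuli=24,
        lead_in_low_s=8.0,
        lead_in_high_s=10.0,
        tail_s=4.0,
        rng_seed=seed,
    )
    params.update(overrides)
    return SessionSpec(**params)


@pytest.fixture
def small_spec() -> SessionSpec:
    return make_small_spec(seed=7)


@pytest.fixture(scope="session")
def full_pair():
    """One full-size sender/receiver pair with the default ERP and coupling."""
    return gen_session_pair(SessionSpec(rng_seed=2024))


@pytest.fixture(scope="session")
def full_null_session():
    """Full-size stimulus-free-background session (no injected effects)."""
    spec = SessionSpec(rng_seed=515)
    seeds = np.random.SeedSequence(515).spawn(2)
    return gen_background(spec, rng=seeds[0]), gen_schedule(spec, rng=seeds[1])


@pytest.fixture(scope="session")
def full_coupled_session(full_null_session):
    """The null session with the default-calibrated coupling injected."""
    rec, sched = full_null_session
    return inject_sync(rec, sched, CouplingSpec(), rng=99), sched


@pytest.fixture
def default_config() -> GW6Config:
    return GW6Config()
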