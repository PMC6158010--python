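"""Shared fixtures: small synthetic sessions and trajectories.

Everything is generated programmatically with fixed seeds so the suite is
deterministic and self-contained.
"""

import numpy as np
import pytest

from parahd.core import Trajectory
from parahd.synthetic import (CohortSpec, build_synthetic_session,
                              make_schedule, simulate_lfp, simulate_trajectory)


@pytest.fixture(scope="session")
def traj_20min() -> Trajectory:
    """20-minute foraging trajectory (shared read-only)."""
    return simulate_trajectory(1200.0, seed=101)


@pytest.fixture(scope="session")
def schedule_40():
    return make_schedule(40, 120.0)


@pytest.fixture(scope="session")
def traj_80min() -> Trajectory:
    return simulate_trajectory(4800.0, seed=102)


@pytest.fixture(scope="session")
def lfp_20min():
    """(LFPTrace, ThetaPhase) of a high-SNR 20-minute theta LFP."""
    return simulate_lfp(1200.0, seed=103, snr=3.0)


@pytest.fixture(scope="session")
def small_session():
    """Compact mixed-cohort session (12 trials) for structural tests."""
    spec = CohortSpec(n_rhythmic_hd=1, n_nonrhythmic_hd=1, n_grid=1,
                      n_untuned=1, n_trials=12, lfp_fs=500.0)
    return build_synthetic_session(spec, seed=104)
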