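"""Shared fixtures: a simulated tracking benchmark with ground-truth labels.

The benchmark dataset (20 individuals x 2 trips, well-separated kinematic
states) is session-scoped because several modules validate against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sulaniche as sn
from sulaniche.synthetic import StateKinematics


@pytest.fixture(scope="session")
def colony():
    return sn.synthetic.default_colony()


@pytest.fixture(scope="session")
def separated_states():
    """Well-separated kinematics: speed and turn axes both cleanly split."""
    return [
        StateKinematics("LL", 1.5, 0.4, 0.97, 600.0),
        StateKinematics("LH", 4.0, 1.0, 0.90, 600.0),
        StateKinematics("HL", 45.0, 2.5, 0.99, 600.0),
        StateKinematics("HH", 25.0, 2.5, 0.90, 600.0),
    ]


@pytest.fixture(scope="session")
def benchmark_fixes(colony, separated_states):
    return sn.synthetic.gen_tracks(
        colony, separated_states, n_individuals=20, trips_per_individual=2, fix_interval_s=10.0, seed=7
    )


@pytest.fixture(scope="session")
def benchmark_trips(benchmark_fixes, colony):
    return sn.tracks.segment_trips(benchmark_fixes, colony)


@pytest.fixture(scope="session")
def benchmark_steps(benchmark_trips, colony):
    """Pooled step kinematics with the generator's true state per step."""
    frames = []
    for t in benchmark_trips:
        if t.n_fixes >= 3:
            steps = sn.tracks.step_kinematics(t.fixes, center=(colony.latitude, colony.longitude))
            # row i describes interior fix i; its speed is the move i -> i+1,
            # whose generating state is stored on the arrival fix
            steps["true_state"] = t.fixes["true_state"].to_numpy()[2:]
            frames.append(steps)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def benchmark_model(benchmark_steps):
    return sn.behavior.fit_embc(benchmark_steps, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
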