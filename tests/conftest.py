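"""Shared fixtures: tiny hand-built trajectories and random step ensembles."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from trajstat import Ensemble, Trajectory


@pytest.fixture(autouse=True)
def _quiet_hold_warnings():
    # hold-last-value warnings are expected in tests that query past run ends
    logging.getLogger("trajstat.core").setLevel(logging.ERROR)
    yield


@pytest.fixture
def toy_traj() -> Trajectory:
    """Three events, two variables; the canonical zero-order-hold example."""
    return Trajectory(
        times=[0.0, 2.0, 5.0],
        values=[[10.0, 4.0], [7.0, 4.0], [3.0, 4.0]],
        var_names=["A", "B"],
    )


def random_step_trajectory(
    rng: np.random.Generator,
    n_vars: int = 2,
    n_points: int = 12,
    t_span: float = 10.0,
) -> Trajectory:
    """A random piecewise-constant trajectory starting at t = 0."""
    gaps = rng.exponential(t_span / n_points, size=n_points - 1)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    values = rng.integers(0, 30, size=(n_points, n_vars)).astype(float)
    return Trajectory(times, values, [f"S{i}" for i in range(n_vars)])


def random_ensemble(
    rng: np.random.Generator,
    n_runs: int = 5,
    n_vars: int = 2,
    n_points: int = 12,
) -> Ensemble:
    return Ensemble(
        [random_step_trajectory(rng, n_vars, n_points) for _ in range(n_runs)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
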