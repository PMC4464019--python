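"""Core domain types for stochastic-simulation time-series.

A :class:`Trajectory` is one realisation of a stochastic model: a strictly
increasing time vector plus a matrix of per-variable values. Jump processes
(Gillespie output) are piecewise-constant between events, so the sampling
convention throughout the package is a zero-order hold: the value at time
``t`` is the value recorded at the latest event time ``<= t``. Queries past
the final recorded time return the last value with a logged warning, because
independent runs stopped by event-count limits end at different times and a
hard failure would make such ensembles unusable.

An :class:`Ensemble` is an ordered collection of trajectories sharing the
same variables — the "dataset" of repeated independent simulations that all
statistics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatasetError,
    ParameterError,
    TimeRangeError,
    VariableNameError,
)

logger = logging.getLogger(__name__)

#: Reserved name of the time column in files and headers.
TIME_COLUMN = "time"


class Trajectory:
    """One independent time-evolution of a model.

    Parameters
    ----------
    times
        Strictly increasing vector of time points (arbitrary simulation
        units, non-negative values are typical but not enforced beyond
        monotonicity).
    values
        Matrix of shape ``(len(times), n_vars)``; real-valued (integer
        molecule counts are the common special case).
    var_names
        Unique, non-empty names for the columns of ``values``. The reserved
        time-column name ``"time"`` is not allowed.
    """

    __slots__ = ("times", "values", "var_names")

    def __init__(
        self,
        times: Sequence[float],
        values: Sequence[Sequence[float]],
        var_names: Sequence[str],
    ) -> None:
        times_arr = np.asarray(times, dtype=float)
        values_arr = np.asarray(values, dtype=float)
        if values_arr.ndim == 1:
            values_arr = values_arr.reshape(-1, 1)
        names = list(var_names)
        if times_arr.ndim != 1 or times_arr.size < 1:
            raise ParameterError("times must be a 1-D vector with at least one point")
        if np.any(np.diff(times_arr) <= 0):
            bad = int(np.flatnonzero(np.diff(times_arr) <= 0)[0]) + 1
            raise ParameterError(
                f"times must be strictly increasing (violated at index {bad})"
            )
        if values_arr.shape[0] != times_arr.size:
            raise ParameterError(
                f"values has {values_arr.shape[0]} rows but times has "
                f"{times_arr.size} points"
            )
        if values_arr.shape[1] != len(names):
            raise ParameterError(
                f"values has {values_arr.shape[1]} columns but "
                f"{len(names)} variable names were given"
            )
        if len(set(names)) != len(names):
            raise VariableNameError("variable names contain duplicates")
        if any(not n for n in names):
            raise VariableNameError("variable names must be non-empty")
        if TIME_COLUMN in names:
            raise VariableNameError(
                f"variable names may not include the reserved name {TIME_COLUMN!r}"
            )
        self.times = times_arr
        self.values = values_arr
        self.var_names = names

    # -- introspection -----------------------------------------------------

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def t_first(self) -> float:
        return float(self.times[0])

    @property
    def t_last(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return self.times.size

    def __repr__(self) -> str:
        return (
            f"Trajectory(n_points={len(self)}, vars={self.var_names}, "
            f"t=[{self.t_first:g}, {self.t_last:g}])"
        )

    def var_index(self, name: str) -> int:
        try:
            return self.var_names.index(name)
        except ValueError:
            raise VariableNameError(
                f"unknown variable {name!r}; available: {self.var_names}"
            ) from None

    def column(self, name: str) -> np.ndarray:
        """Values of one variable over all recorded times."""
        return self.values[:, self.var_index(name)]

    def to_frame(self) -> pd.DataFrame:
        """The trajectory as a DataFrame with the time column first."""
        frame = pd.DataFrame(self.values, columns=self.var_names)
        frame.insert(0, TIME_COLUMN, self.times)
        return frame

    def equals(self, other: "Trajectory") -> bool:
        return (
            self.var_names == other.var_names
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )

    # -- sampling ----------------------------------------------------------

    def sample_at(self, t: float, var: str) -> float:
        """Zero-order-hold sample of one variable at time ``t``.

        Returns the value at the largest event time ``<= t`` (the exact
        semantics of a jump-process sample path). Beyond the last event the
        last value is held, with a logged warning.
        """
        j = self.var_index(var)
        if t < self.times[0]:
            raise TimeRangeError(
                f"t={t!r} precedes the first recorded time {self.t_first!r}"
            )
        if t > self.times[-1]:
            logger.warning(
                "sample_at(t=%g) beyond final recorded time %g; holding last value",
                t,
                self.t_last,
            )
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.values[idx, j])

    def resample(self, grid: "TimeGrid") -> np.ndarray:
        """Zero-order-hold values of every variable on a uniform grid.

        Returns a ``(grid.n_points, n_vars)`` matrix whose row ``i`` equals
        ``sample_at(grid.points[i], v)`` for every variable ``v``.
        """
        pts = grid.points
        if pts[0] < self.times[0]:
            raise TimeRangeError(
                f"grid starts at {pts[0]!r}, before the trajectory's first "
                f"time {self.t_first!r}"
            )
        if pts[-1] > self.times[-1]:
            logger.warning(
                "grid extends to %g beyond final recorded time %g; "
                "holding last value",
                pts[-1],
                self.t_last,
            )
        idx = np.searchsorted(self.times, pts, side="right") - 1
        return self.values[idx, :]

    def resampled(self, grid: "TimeGrid") -> "Trajectory":
        """Like :meth:`resample` but wrapped back into a Trajectory."""
        return Trajectory(grid.points, self.resample(grid), self.var_names)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform discretisation of a closed time interval.

    ``points`` is the inclusive sequence ``start ... stop`` with ``n_points``
    equally spaced entries; a single-point grid requires ``start == stop``.
    """

    start: float
    stop: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ParameterError("n_points must be >= 1")
        if self.start > self.stop:
            raise ParameterError("grid start must not exceed stop")
        if self.n_points == 1 and self.start != self.stop:
            raise ParameterError("a single-point grid requires start == stop")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


class Ensemble:
    """An ordered collection of trajectories sharing variable names.

    When loaded from disk the order is by sorted source filename, so
    ensembles are deterministic across runs and worker counts.
    """

    __slots__ = ("trajectories", "provenance")

    def __init__(
        self,
        trajectories: Sequence[Trajectory],
        provenance: Optional[str] = None,
    ) -> None:
        trajs = list(trajectories)
        if not trajs:
            raise EmptyDatasetError("an ensemble must contain at least one trajectory")
        names = trajs[0].var_names
        offenders = [
            i for i, tr in enumerate(trajs) if tr.var_names != names
        ]
        if offenders:
            raise VariableNameError(
                f"trajectories {offenders} disagree with the ensemble variable "
                f"names {names}"
            )
        self.trajectories = trajs
        self.provenance = provenance

    @property
    def var_names(self) -> list[str]:
        return self.trajectories[0].var_names

    @property
    def n_runs(self) -> int:
        return len(self.trajectories)

    @property
    def t_first(self) -> float:
        return min(tr.t_first for tr in self.trajectories)

    @property
    def t_last(self) -> float:
        return max(tr.t_last for tr in self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def __repr__(self) -> str:
        return (
            f"Ensemble(n_runs={self.n_runs}, vars={self.var_names}, "
            f"provenance={self.provenance!r})"
        )

    def equals(self, other: "Ensemble") -> bool:
        return self.n_runs == other.n_runs and all(
            a.equals(b) for a, b in zip(self.trajectories, other.trajectories)
        )

    def samples_at(self, t: float, var: str) -> np.ndarray:
        """The cross-run sample ``{sample_at(run, t, var)}`` as a vector."""
        return np.array([tr.sample_at(t, var) for tr in self.trajectories])


@dataclass
class GaussianFit:
    """Maximum-likelihood Gaussian parameters: mean and (biased) variance."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ParameterError("sigma2 must be non-negative")


@dataclass
class DensityEstimate:
    """Histogram estimate of one variable's law at one time point.

    ``kind`` records the normalisation: ``"mass"`` (per-bin probability mass
    summing to 1), ``"density"`` (mass / bin width integrating to 1) or
    ``"counts"`` (raw occupation counts).
    """

    var_name: str
    time: float
    bin_edges: np.ndarray
    mass: np.ndarray
    kind: str
    n_samples: int
    sample_min: float
    sample_max: float
    fit: Optional[GaussianFit] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.kind not in ("mass", "density", "counts"):
            raise ParameterError(f"unknown normalisation kind {self.kind!r}")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin_edges must be strictly increasing")
        if self.mass.size != self.bin_edges.size - 1:
            raise ParameterError("mass must have one entry per bin")
        if np.any(self.mass < 0):
            raise ParameterError("bin masses must be non-negative")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass
class MasterEqEstimate:
    """Empirical estimate of P(x, t) for one variable over a time interval.

    ``prob`` is an ``(n_points, n_bins)`` matrix of probability masses; every
    time-row sums to 1, so each row is the estimated law of the variable at
    the corresponding grid time — the ensemble estimate of the master-equation
    solution.
    """

    var_name: str
    grid: TimeGrid
    bin_edges: np.ndarray
    prob: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (self.grid.n_points, self.bin_edges.size - 1):
            raise ParameterError(
                "prob must have shape (grid.n_points, n_bins) = "
                f"({self.grid.n_points}, {self.bin_edges.size - 1})"
            )
        if np.any(self.prob < 0) or np.any(self.prob > 1):
            raise ParameterError("probability masses must lie in [0, 1]")
        sums = self.prob.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ParameterError("every time-row of prob must sum to 1")

    def row(self, i: int) -> DensityEstimate:
        """Time slice ``i`` as a standalone density estimate."""
        mass = self.prob[i]
        nz = np.flatnonzero(mass)
        centres = self.bin_centres
        return DensityEstimate(
            var_name=self.var_name,
            time=float(self.grid.points[i]),
            bin_edges=self.bin_edges,
            mass=mass,
            kind="mass",
            n_samples=-1,
            sample_min=float(centres[nz[0]]) if nz.size else float("nan"),
            sample_max=float(centres[nz[-1]]) if nz.size else float("nan"),
        )

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PhasePath:
    """A trajectory projected into 2- or 3-variable phase space."""

    var_names: list[str]
    points: np.ndarray
    times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.var_names) not in (2, 3):
            raise ParameterError("phase space requires 2 or 3 variables")
        if self.points.shape != (self.times.size, len(self.var_names)):
            raise ParameterError("points must be (len(times), n_vars)")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def ndim(self) -> int:
        return len(self.var_names)
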