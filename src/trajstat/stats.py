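"""Ensemble statistics: mean/SD traces, densities, master-equation estimates.

The key quantity a modeller extracts from a simulation ensemble is the
time-dependent law of a variable. At a fixed time ``t`` the cross-run sample
``{X_i(t)}`` estimates ``P(X_t = x)``; computing that histogram on a shared
set of state bins over a whole time grid yields an empirical estimate of the
master-equation solution ``P(x, t)``. Everything here works on the
zero-order-hold samples provided by :class:`~trajstat.core.Trajectory`, so
trajectories need not share event times.

Conventions (fixed, documented in docs/methods.md):

* standard deviation and the Gaussian fit use the population / MLE
  convention (divide by ``n``); an unbiased switch is provided;
* "auto" binning uses width-1 bins centred on integers when all samples are
  (near-)integer — natural for molecule counts — and 30 equal-width bins
  otherwise;
* when all samples coincide, the histogram degenerates to a single bin of
  width 1 centred on the common value, with mass 1;
* a value exactly on an interior edge belongs to the right bin, and the last
  bin is closed on both sides (numpy's histogram convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DensityEstimate,
    Ensemble,
    GaussianFit,
    MasterEqEstimate,
    PhasePath,
    TimeGrid,
    Trajectory,
)
from .errors import ParameterError, VariableNameError

__all__ = [
    "BinningSpec",
    "EnsembleSummary",
    "ensemble_mean",
    "ensemble_sd",
    "gaussian_fit",
    "master_equation",
    "pdf_at",
    "pdf_multi",
    "phase_space",
    "phase_space_avg",
    "summary",
    "total_variation",
    "total_variation_from_pmf",
]

#: Tolerance under which samples count as integers for "auto" binning.
_INTEGER_TOL = 1e-9


@dataclass(frozen=True)
class BinningSpec:
    """How to quantise samples into state bins.

    ``n_bins="auto"`` selects integer-aligned width-1 bins when all samples
    are near-integers and their span does not exceed ``MAX_INTEGER_BINS``
    (beyond that, unit bins stop being readable or tractable), else 30
    equal-width bins. ``integer_aligned=True`` forces width-1 bins centred
    on integers regardless of span; ``False`` forbids them. ``range`` fixes
    the (lo, hi) span instead of the sample extrema.
    """

    #: Widest integer span that "auto" still resolves to unit bins.
    MAX_INTEGER_BINS = 400

    n_bins: int | str = "auto"
    integer_aligned: Optional[bool] = None
    range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if isinstance(self.n_bins, str):
            if self.n_bins != "auto":
                raise ParameterError(f"n_bins must be an integer or 'auto', got {self.n_bins!r}")
        elif self.n_bins < 1:
            raise ParameterError("n_bins must be >= 1")
        if self.range is not None and self.range[0] > self.range[1]:
            raise ParameterError("binning range must satisfy lo <= hi")

    def resolve_edges(self, samples: np.ndarray) -> np.ndarray:
        """Bin edges for a concrete sample vector."""
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ParameterError("cannot resolve bins for an empty sample")
        lo, hi = (
            self.range
            if self.range is not None
            else (float(samples.min()), float(samples.max()))
        )
        if lo == hi:
            # Degenerate span: one bin of width 1 centred on the value.
            return np.array([lo - 0.5, lo + 0.5])
        integerish = bool(np.all(np.abs(samples - np.round(samples)) < _INTEGER_TOL))
        aligned = (
            self.integer_aligned
            if self.integer_aligned is not None
            else (
                self.n_bins == "auto"
                and integerish
                and hi - lo <= self.MAX_INTEGER_BINS
            )
        )
        if aligned:
            first = np.floor(lo)
            last = np.ceil(hi)
            return np.arange(first - 0.5, last + 1.0, 1.0)
        n = 30 if self.n_bins == "auto" else int(self.n_bins)
        return np.linspace(lo, hi, n + 1)


def gaussian_fit(samples: Sequence[float], unbiased: bool = False) -> GaussianFit:
    """Closed-form maximum-likelihood Gaussian fit.

    ``mu`` is the sample mean and ``sigma2`` the MLE (biased, divide-by-n)
    variance; ``unbiased=True`` divides by ``n - 1`` instead. No iterative
    optimisation is involved — these are the explicit MLE formulas.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ParameterError("gaussian_fit requires at least one sample")
    if unbiased and x.size < 2:
        raise ParameterError("unbiased variance requires at least two samples")
    mu = float(x.mean())
    ddof = 1 if unbiased else 0
    sigma2 = float(np.sum((x - mu) ** 2) / (x.size - ddof))
    return GaussianFit(mu=mu, sigma2=sigma2)


def _require_nonempty(ens: Ensemble) -> None:
    if ens.n_runs < 1:  # Ensemble construction already forbids this
        raise ParameterError("ensemble is empty")


def _stack_resampled(ens: Ensemble, grid: TimeGrid) -> np.ndarray:
    """All runs resampled on a grid: shape (n_runs, n_points, n_vars)."""
    return np.stack([tr.resample(grid) for tr in ens])


def ensemble_mean(ens: Ensemble, grid: TimeGrid) -> Trajectory:
    """The average trace ``X̄_t`` of all runs, per variable, on a grid."""
    _require_nonempty(ens)
    cube = _stack_resampled(ens, grid)
    return Trajectory(grid.points, cube.mean(axis=0), ens.var_names)


def ensemble_sd(ens: Ensemble, grid: TimeGrid, unbiased: bool = False) -> Trajectory:
    """The standard deviation ``σ_X`` of the runs, per variable, on a grid.

    Population convention by default (divide by ``n``), consistent with the
    MLE variance; ``unbiased=True`` divides by ``n - 1``.
    """
    _require_nonempty(ens)
    if unbiased and ens.n_runs < 2:
        raise ParameterError("unbiased SD requires at least two runs")
    cube = _stack_resampled(ens, grid)
    sd = cube.std(axis=0, ddof=1 if unbiased else 0)
    return Trajectory(grid.points, sd, ens.var_names)


def _histogram(
    samples: np.ndarray,
    edges: np.ndarray,
    normed: bool,
    density: bool,
) -> tuple[np.ndarray, str]:
    counts, _ = np.histogram(samples, bins=edges)
    if not normed:
        return counts.astype(float), "counts"
    mass = counts / samples.size
    if density:
        return mass / np.diff(edges), "density"
    return mass, "mass"


def pdf_at(
    ens: Ensemble,
    t: float,
    var: str,
    bins: BinningSpec = BinningSpec(),
    normed: bool = True,
    fit: bool = False,
    density: bool = False,
) -> DensityEstimate:
    """Histogram estimate of ``P(X_t = x)`` from the cross-run sample at ``t``.

    With ``normed`` the per-bin masses sum to 1 (or, with ``density``, the
    histogram integrates to 1); without it raw counts are returned. With
    ``fit`` a closed-form Gaussian MLE of the raw samples is attached. The
    sample minimum and maximum are always reported.
    """
    _require_nonempty(ens)
    samples = ens.samples_at(t, var)
    edges = bins.resolve_edges(samples)
    mass, kind = _histogram(samples, edges, normed, density)
    return DensityEstimate(
        var_name=var,
        time=float(t),
        bin_edges=edges,
        mass=mass,
        kind=kind,
        n_samples=samples.size,
        sample_min=float(samples.min()),
        sample_max=float(samples.max()),
        fit=gaussian_fit(samples) if fit else None,
    )


def pdf_multi(
    ens: Ensemble,
    times: Sequence[float],
    var: str,
    bins: BinningSpec = BinningSpec(),
    normed: bool = True,
    fit: bool = False,
    density: bool = False,
) -> list[DensityEstimate]:
    """Per-time density estimates on one shared set of bin edges.

    The edges are resolved once over the union of the samples at every
    requested time, so the bars are directly comparable across times (the
    3-D multi-time density view relies on this).
    """
    if len(times) == 0:
        raise ParameterError("at least one time point is required")
    _require_nonempty(ens)
    per_time = [ens.samples_at(t, var) for t in times]
    edges = bins.resolve_edges(np.concatenate(per_time))
    out = []
    for t, samples in zip(times, per_time):
        mass, kind = _histogram(samples, edges, normed, density)
        out.append(
            DensityEstimate(
                var_name=var,
                time=float(t),
                bin_edges=edges,
                mass=mass,
                kind=kind,
                n_samples=samples.size,
                sample_min=float(samples.min()),
                sample_max=float(samples.max()),
                fit=gaussian_fit(samples) if fit else None,
            )
        )
    return out


def master_equation(
    ens: Ensemble,
    var: str,
    start: float,
    stop: float,
    n_time_points: int = 50,
    bins: BinningSpec = BinningSpec(),
) -> MasterEqEstimate:
    """Empirical master-equation estimate of ``P(x, t)`` on ``[start, stop]``.

    State bins are resolved once from the global extrema of ``var`` over all
    runs and all grid points; each time-row is the mass-normalised histogram
    of the cross-run sample at that grid time, so every row sums to 1.
    """
    if start >= stop:
        raise ParameterError("master_equation requires start < stop")
    if n_time_points < 2:
        raise ParameterError("n_time_points must be >= 2")
    _require_nonempty(ens)
    grid = TimeGrid(start, stop, n_time_points)
    j = ens.trajectories[0].var_index(var)
    samples = np.stack([tr.resample(grid)[:, j] for tr in ens])  # (runs, points)
    edges = bins.resolve_edges(samples.ravel())
    prob = np.empty((grid.n_points, edges.size - 1))
    for i in range(grid.n_points):
        prob[i], _ = _histogram(samples[:, i], edges, normed=True, density=False)
    return MasterEqEstimate(var_name=var, grid=grid, bin_edges=edges, prob=prob)


def phase_space(traj: Trajectory, vars: Sequence[str]) -> PhasePath:
    """Project a trajectory onto 2 or 3 of its variables, in time order."""
    names = list(vars)
    if len(names) not in (2, 3):
        raise ParameterError("phase space requires exactly 2 or 3 variables")
    if len(set(names)) != len(names):
        raise VariableNameError("phase-space variables must be distinct")
    cols = [traj.var_index(n) for n in names]
    return PhasePath(
        var_names=names, points=traj.values[:, cols], times=traj.times.copy()
    )


def phase_space_avg(
    ens: Ensemble, grid: TimeGrid, vars: Sequence[str]
) -> PhasePath:
    """Phase-space path of the ensemble-average trace on a grid."""
    return phase_space(ensemble_mean(ens, grid), vars)


@dataclass
class EnsembleSummary:
    """Global per-variable extrema and temporal span of an ensemble."""

    n_runs: int
    t_first: float
    t_last: float
    minima: dict[str, float]
    maxima: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.minima, "max": self.maxima},
        ).rename_axis("variable")


def summary(ens: Ensemble) -> EnsembleSummary:
    """Exact min/max per variable over all runs and all recorded times."""
    _require_nonempty(ens)
    mins = np.min([tr.values.min(axis=0) for tr in ens], axis=0)
    maxs = np.max([tr.values.max(axis=0) for tr in ens], axis=0)
    return EnsembleSummary(
        n_runs=ens.n_runs,
        t_first=ens.t_first,
        t_last=ens.t_last,
        minima={n: float(v) for n, v in zip(ens.var_names, mins)},
        maxima={n: float(v) for n, v in zip(ens.var_names, maxs)},
    )


# -- distribution distances (for validation against analytic laws) ---------


def total_variation(p: Sequence[float], q: Sequence[float]) -> float:
    """Total-variation distance ``0.5 * Σ|p_i − q_i|`` between two pmfs."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ParameterError("pmfs must have equal length")
    return 0.5 * float(np.abs(p - q).sum())


def total_variation_from_pmf(
    estimate: DensityEstimate, pmf: Callable[[np.ndarray], np.ndarray]
) -> float:
    """Total variation between a mass-normalised histogram and an integer pmf.

    The analytic pmf is aggregated onto the estimate's bins (summing over the
    integers each bin covers); analytic mass falling outside every bin counts
    fully towards the distance, so the result is the TV distance on the whole
    integer support.
    """
    if estimate.kind != "mass":
        raise ParameterError("estimate must be mass-normalised")
    edges = estimate.bin_edges
    support = np.arange(np.floor(edges[0]), np.ceil(edges[-1]) + 1)
    pm = np.asarray(pmf(support), dtype=float)
    # right-closed last bin, right-open elsewhere — match the histogram rule
    which = np.clip(np.searchsorted(edges, support, side="right") - 1, 0, None)
    inside = (support >= edges[0]) & (support <= edges[-1])
    which = np.where(support == edges[-1], edges.size - 2, which)
    q = np.zeros(edges.size - 1)
    np.add.at(q, which[inside], pm[inside])
    outside_mass = 1.0 - pm.sum() + pm[~inside].sum()
    return 0.5 * (float(np.abs(estimate.mass - q).sum()) + max(outside_mass, 0.0))
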