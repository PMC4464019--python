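"""Render ensemble statistics to image files.

Every visualisation takes its data as an already-computed statistics object
(or a raw Trajectory/Ensemble for the unprocessed views) and writes a PNG,
SVG or PDF file; the input objects are never modified. Trajectories are
drawn as post-step functions, matching the zero-order-hold semantics of
jump processes; only mean traces are drawn as smooth lines. Heatmaps use a
fixed colour map (viridis) with the probability scale anchored at
[0, max mass] per plot, time on the horizontal axis and state bins on the
vertical.

SVG output is byte-stable for identical data and requests (fixed hash salt,
no embedded date), which gives plots a regression surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: F401  (registers Agg)
from matplotlib.figure import Figure

from .core import (
    DensityEstimate,
    Ensemble,
    MasterEqEstimate,
    PhasePath,
    TimeGrid,
    Trajectory,
)
from .errors import ParameterError, VariableNameError
from .stats import ensemble_mean, ensemble_sd

__all__ = ["PlotRequest", "render", "PLOT_KINDS"]

PLOT_KINDS = (
    "traces",
    "mean",
    "sd",
    "mean_sd",
    "pdf_bar",
    "pdf_3d",
    "meq_heatmap",
    "meq_surface",
    "phase2d",
    "phase3d",
)

#: Fixed, documented colour map for probability heatmaps/surfaces.
HEATMAP_CMAP = "viridis"

_SVG_SALT = "trajstat"

PlotData = Union[
    Trajectory,
    Ensemble,
    DensityEstimate,
    Sequence[DensityEstimate],
    MasterEqEstimate,
    PhasePath,
]


@dataclass
class PlotRequest:
    """What to draw and where to write it.

    ``columns`` restricts trace-like plots to a variable subset; ``start``
    and ``stop`` window the time axis before drawing; ``grid_points``
    controls the resampling resolution of mean/SD overlays.
    """

    kind: str
    out_path: str | Path
    columns: Optional[Sequence[str]] = None
    start: Optional[float] = None
    stop: Optional[float] = None
    grid_points: int = 200
    title: Optional[str] = None
    format: Optional[str] = None  # inferred from out_path when None

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ParameterError(
                f"unknown plot kind {self.kind!r}; choose from {PLOT_KINDS}"
            )
        fmt = self.format or Path(self.out_path).suffix.lstrip(".").lower()
        if fmt not in ("png", "svg", "pdf"):
            raise ParameterError(f"unsupported image format {fmt!r}")
        self.format = fmt


def _as_ensemble(data: PlotData) -> Ensemble:
    if isinstance(data, Ensemble):
        return data
    if isinstance(data, Trajectory):
        return Ensemble([data])
    raise ParameterError(
        f"this plot kind needs a Trajectory or Ensemble, got {type(data).__name__}"
    )


def _window(ens: Ensemble, req: PlotRequest) -> tuple[float, float]:
    start = ens.t_first if req.start is None else max(req.start, ens.t_first)
    stop = ens.t_last if req.stop is None else min(req.stop, ens.t_last)
    if start > stop:
        raise ParameterError("empty time window after start/stop filtering")
    return start, stop


def _columns(names: Sequence[str], req: PlotRequest) -> list[str]:
    if req.columns is None:
        return list(names)
    missing = [c for c in req.columns if c not in names]
    if missing:
        raise VariableNameError(f"unknown variables {missing}; available: {list(names)}")
    return list(req.columns)


def _save(fig: Figure, req: PlotRequest) -> Path:
    out = Path(req.out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": _SVG_SALT}):
        if req.format == "svg":
            fig.savefig(out, format="svg", metadata={"Date": None})
        else:
            fig.savefig(out, format=req.format)
    return out


def _plot_traces(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    ens = _as_ensemble(data)
    names = _columns(ens.var_names, req)
    start, stop = _window(ens, req)
    ax = fig.add_subplot(111)
    colors = matplotlib.colormaps["tab10"]
    for ci, name in enumerate(names):
        for ri, tr in enumerate(ens):
            mask = (tr.times >= start) & (tr.times <= stop)
            ax.step(
                tr.times[mask],
                tr.column(name)[mask],
                where="post",
                color=colors(ci % 10),
                alpha=min(1.0, max(0.15, 3.0 / ens.n_runs)),
                label=name if ri == 0 else None,
                linewidth=0.8,
            )
    ax.set_xlabel("time")
    ax.set_ylabel("value")
    # fixed legend location: "best" scans every vertex of every run
    ax.legend(loc="upper right")


def _plot_mean_sd(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    ens = _as_ensemble(data)
    names = _columns(ens.var_names, req)
    start, stop = _window(ens, req)
    grid = TimeGrid(start, stop, req.grid_points)
    mean = ensemble_mean(ens, grid)
    sd = ensemble_sd(ens, grid) if req.kind in ("sd", "mean_sd") else None
    ax = fig.add_subplot(111)
    colors = matplotlib.colormaps["tab10"]
    for ci, name in enumerate(names):
        c = colors(ci % 10)
        if req.kind in ("mean", "mean_sd"):
            ax.plot(grid.points, mean.column(name), color=c, label=f"{name} mean")
        if req.kind == "sd":
            ax.plot(grid.points, sd.column(name), color=c, label=f"{name} SD")
        if req.kind == "mean_sd":
            m, s = mean.column(name), sd.column(name)
            ax.fill_between(
                grid.points, m - s, m + s, color=c, alpha=0.25,
                label=f"{name} ±1 SD",
            )
    ax.set_xlabel("time")
    ax.set_ylabel("value")
    ax.legend(loc="best")


def _as_density_list(data: PlotData) -> list[DensityEstimate]:
    if isinstance(data, DensityEstimate):
        return [data]
    if isinstance(data, (list, tuple)) and all(
        isinstance(d, DensityEstimate) for d in data
    ):
        return list(data)
    raise ParameterError(
        f"this plot kind needs DensityEstimate(s), got {type(data).__name__}"
    )


def _gaussian_curve(ax, est: DensityEstimate) -> None:
    if est.fit is None or est.fit.sigma2 <= 0:
        return
    mu, s2 = est.fit.mu, est.fit.sigma2
    x = np.linspace(est.bin_edges[0], est.bin_edges[-1], 256)
    pdf = np.exp(-((x - mu) ** 2) / (2 * s2)) / np.sqrt(2 * np.pi * s2)
    if est.kind == "mass":
        pdf = pdf * float(np.mean(est.bin_widths))  # density -> per-bin mass scale
    elif est.kind == "counts":
        pdf = pdf * est.n_samples * float(np.mean(est.bin_widths))
    ax.plot(x, pdf, color="crimson", linewidth=1.5, label="Gaussian fit")


def _plot_pdf_bar(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    # one panel per estimate (per variable/time), mirroring multi-panel reports
    ests = _as_density_list(data)
    n = len(ests)
    for i, est in enumerate(ests):
        ax = fig.add_subplot(1, n, i + 1)
        ax.bar(
            est.bin_centres,
            est.mass,
            width=est.bin_widths,
            align="center",
            color="steelblue",
            edgecolor="white",
        )
        _gaussian_curve(ax, est)
        ax.set_xlabel(est.var_name)
        ylabel = {"mass": "probability", "density": "density", "counts": "count"}
        ax.set_ylabel(ylabel[est.kind])
        ax.set_title(f"t = {est.time:g}")
        if est.fit is not None:
            ax.legend(loc="best")


def _plot_pdf_3d(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    ests = _as_density_list(data)
    ax = fig.add_subplot(111, projection="3d")
    for est in ests:
        ax.bar(
            est.bin_centres,
            est.mass,
            zs=est.time,
            zdir="y",
            width=est.bin_widths,
            alpha=0.8,
        )
    ax.set_xlabel(ests[0].var_name)
    ax.set_ylabel("time")
    ax.set_zlabel("probability")


def _as_meq(data: PlotData) -> MasterEqEstimate:
    if isinstance(data, MasterEqEstimate):
        return data
    raise ParameterError(
        f"this plot kind needs a MasterEqEstimate, got {type(data).__name__}"
    )


def _plot_meq_heatmap(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    meq = _as_meq(data)
    ax = fig.add_subplot(111)
    mesh = ax.pcolormesh(
        meq.grid.points,
        meq.bin_centres,
        meq.prob.T,
        cmap=HEATMAP_CMAP,
        vmin=0.0,
        vmax=float(meq.prob.max()),
        shading="nearest",
    )
    fig.colorbar(mesh, ax=ax, label="probability mass")
    ax.set_xlabel("time")
    ax.set_ylabel(meq.var_name)


def _plot_meq_surface(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    meq = _as_meq(data)
    ax = fig.add_subplot(111, projection="3d")
    tt, xx = np.meshgrid(meq.grid.points, meq.bin_centres)
    ax.plot_surface(
        tt, xx, meq.prob.T, cmap=HEATMAP_CMAP, vmin=0.0,
        vmax=float(meq.prob.max()),
    )
    ax.set_xlabel("time")
    ax.set_ylabel(meq.var_name)
    ax.set_zlabel("probability mass")


def _as_phase(data: PlotData, ndim: int) -> PhasePath:
    if isinstance(data, PhasePath):
        if data.ndim != ndim:
            raise ParameterError(
                f"{data.ndim}-D phase path given to a {ndim}-D plot kind"
            )
        return data
    raise ParameterError(
        f"this plot kind needs a PhasePath, got {type(data).__name__}"
    )


def _plot_phase(fig: Figure, data: PlotData, req: PlotRequest) -> None:
    ndim = 2 if req.kind == "phase2d" else 3
    path = _as_phase(data, ndim)
    mask = np.ones(path.times.size, dtype=bool)
    if req.start is not None:
        mask &= path.times >= req.start
    if req.stop is not None:
        mask &= path.times <= req.stop
    pts = path.points[mask]
    if ndim == 2:
        ax = fig.add_subplot(111)
        ax.plot(pts[:, 0], pts[:, 1], linewidth=0.9)
        ax.set_xlabel(path.var_names[0])
        ax.set_ylabel(path.var_names[1])
    else:
        ax = fig.add_subplot(111, projection="3d")
        ax.plot(pts[:, 0], pts[:, 1], pts[:, 2], linewidth=0.9)
        ax.set_xlabel(path.var_names[0])
        ax.set_ylabel(path.var_names[1])
        ax.set_zlabel(path.var_names[2])


_DISPATCH = {
    "traces": _plot_traces,
    "mean": _plot_mean_sd,
    "sd": _plot_mean_sd,
    "mean_sd": _plot_mean_sd,
    "pdf_bar": _plot_pdf_bar,
    "pdf_3d": _plot_pdf_3d,
    "meq_heatmap": _plot_meq_heatmap,
    "meq_surface": _plot_meq_surface,
    "phase2d": _plot_phase,
    "phase3d": _plot_phase,
}


def render(req: PlotRequest, data: PlotData) -> Path:
    """Draw ``data`` according to ``req`` and write the image file.

    Returns the output path. Raises a usage error when the data type does
    not match the requested kind, and a name error for unknown variables.
    """
    fig = Figure(figsize=(7.0, 4.5), dpi=100)
    _DISPATCH[req.kind](fig, data, req)
    if req.title:
        fig.suptitle(req.title)
    fig.set_layout_engine("tight")
    return _save(fig, req)
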