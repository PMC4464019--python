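"""Config-driven batch reports: load (or simulate) a dataset, run analysis
steps in order, write images, exported tables, a run log and a MANIFEST.

A report config is declarative (plain YAML, no executable code): a dataset
source, a list of analysis steps and an output directory. Every step is
validated before any execution (fail fast); a step failure aborts the run
with a message naming the step, and the partial outputs are retained with a
MANIFEST marking the report incomplete. The run log records every parameter
actually used — including resolved defaults, dataset size, per-variable
min/max and Gaussian-fit mu/sigma2 where fits were requested — so a run is
reproducible from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .core import Ensemble, TimeGrid
from .errors import ParameterError, TrajstatError
from .io import (
    LoadSpec,
    load_dataset,
    write_density,
    write_meq,
    write_sbrml,
)
from .plotting import PlotRequest, render
from .ssa import (
    generate_ensemble,
    immigration_death,
    lotka_volterra,
    model_from_config,
    pure_death,
)
from .stats import (
    BinningSpec,
    master_equation,
    pdf_multi,
    phase_space,
    phase_space_avg,
    summary,
)

logger = logging.getLogger(__name__)

STEP_KINDS = (
    "traces",
    "mean",
    "sd",
    "mean_sd",
    "pdf",
    "pdf3d",
    "meq2d",
    "meq3d",
    "phase2d",
    "phase3d",
    "summary",
    "sbrml_export",
)

_BUILTIN_MODELS = {
    "lotka_volterra": lotka_volterra,
    "immigration_death": immigration_death,
    "pure_death": pure_death,
}


@dataclass
class ReportConfig:
    """Parsed and validated report configuration."""

    output_dir: Path
    dataset: Optional[dict[str, Any]] = None
    simulate: Optional[dict[str, Any]] = None
    steps: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"
    image_format: str = "png"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReportConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: report config must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ReportConfig":
        known = {
            "output_dir",
            "dataset",
            "simulate",
            "steps",
            "seed",
            "log_level",
            "image_format",
        }
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ParameterError("config must set output_dir")
        cfg = cls(
            output_dir=Path(raw["output_dir"]),
            dataset=raw.get("dataset"),
            simulate=raw.get("simulate"),
            steps=list(raw.get("steps") or []),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            image_format=str(raw.get("image_format", "png")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Fail fast: every step is checked before any execution."""
        if (self.dataset is None) == (self.simulate is None):
            raise ParameterError(
                "config must set exactly one of 'dataset' or 'simulate'"
            )
        if not self.steps:
            raise ParameterError("config must list at least one analysis step")
        if self.image_format not in ("png", "svg", "pdf"):
            raise ParameterError(f"unsupported image_format {self.image_format!r}")
        if self.simulate is not None:
            model = self.simulate.get("model")
            if model not in _BUILTIN_MODELS and "config" not in self.simulate:
                raise ParameterError(
                    f"simulate.model must be one of {sorted(_BUILTIN_MODELS)} "
                    "or simulate.config must point to a model file"
                )
        for i, step in enumerate(self.steps):
            kind = step.get("kind")
            if kind not in STEP_KINDS:
                raise ParameterError(
                    f"step {i}: unknown kind {kind!r}; choose from {STEP_KINDS}"
                )
            if kind in ("pdf", "pdf3d"):
                if "t" not in step and "times" not in step:
                    raise ParameterError(f"step {i} ({kind}): needs 't' or 'times'")
            if kind in ("meq2d", "meq3d"):
                if "stop" not in step:
                    raise ParameterError(f"step {i} ({kind}): needs 'stop'")
                if "start" in step and float(step["start"]) >= float(step["stop"]):
                    raise ParameterError(f"step {i} ({kind}): needs start < stop")
            if kind in ("phase2d", "phase3d"):
                want = 2 if kind == "phase2d" else 3
                vars_ = step.get("vars")
                if not vars_ or len(vars_) != want:
                    raise ParameterError(
                        f"step {i} ({kind}): needs exactly {want} 'vars'"
                    )


def _obtain_ensemble(cfg: ReportConfig) -> Ensemble:
    if cfg.dataset is not None:
        spec = LoadSpec(
            path=cfg.dataset["path"],
            pattern=cfg.dataset.get("pattern", "*"),
            col_names=cfg.dataset.get("col_names"),
            delimiter=cfg.dataset.get("delimiter", "auto"),
            has_header=cfg.dataset.get("has_header", "auto"),
            n_workers=cfg.dataset.get("n_workers"),
        )
        logger.info("loading dataset: %s", spec)
        return load_dataset(spec)
    sim = dict(cfg.simulate or {})
    name = sim.get("model")
    params = dict(sim.get("params") or {})
    if name in _BUILTIN_MODELS:
        model = _BUILTIN_MODELS[name](**params)
    else:
        model = model_from_config(sim["config"])
    n_runs = int(sim.get("n_runs", 100))
    t_max = float(sim.get("t_max", 150.0))
    seed = int(sim.get("seed", cfg.seed))
    out_dir = sim.get("out_dir")
    logger.info(
        "simulating fixture: model=%s params=%s n_runs=%d t_max=%g seed=%d",
        model.label, params, n_runs, t_max, seed,
    )
    return generate_ensemble(model, n_runs, t_max, seed, out_dir=out_dir)


def _binning_from_step(step: dict[str, Any]) -> BinningSpec:
    n_bins = step.get("bins", "auto")
    return BinningSpec(n_bins=n_bins, range=tuple(step["range"]) if "range" in step else None)


def _grid_for(ens: Ensemble, step: dict[str, Any], n_default: int = 200) -> TimeGrid:
    start = float(step.get("start", ens.t_first))
    stop = float(step.get("stop", ens.t_last))
    stop = min(stop, ens.t_last)
    n = int(step.get("grid_points", n_default))
    return TimeGrid(start, stop, n)


def run_report(config: ReportConfig | str | Path) -> Path:
    """Execute a validated report config; return the report directory."""
    if not isinstance(config, ReportConfig):
        config = ReportConfig.from_yaml(config)
    out = config.output_dir
    images = out / "images"
    tables = out / "tables"
    for d in (out, images, tables):
        d.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []

    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    pkg_logger = logging.getLogger("trajstat")
    old_level = pkg_logger.level
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(config.log_level.upper())
    status = "INCOMPLETE"
    current = "setup"
    try:
        logger.info("trajstat %s report run; seed=%d", __version__, config.seed)
        ens = _obtain_ensemble(config)
        logger.info(
            "dataset: n_runs=%d vars=%s t_first=%g t_last=%g provenance=%s",
            ens.n_runs, ens.var_names, ens.t_first, ens.t_last, ens.provenance,
        )
        summ = summary(ens)
        for name in ens.var_names:
            logger.info(
                "variable %s: min=%g max=%g", name, summ.minima[name], summ.maxima[name]
            )
        summary_path = tables / "summary.tsv"
        summ.to_frame().to_csv(summary_path, sep="\t")
        produced.append(str(summary_path.relative_to(out)))

        for i, step in enumerate(config.steps):
            kind = step["kind"]
            current = f"step {i} ({kind})"
            logger.info("%s: parameters %s", current, step)
            _execute_step(i, step, ens, config, images, tables, produced)
        status = "COMPLETE"
    except Exception as exc:
        logger.error("report aborted at %s: %s", current, exc)
        raise TrajstatError(f"report aborted at {current}: {exc}") from exc
    finally:
        manifest = out / "MANIFEST"
        with open(manifest, "w", encoding="utf-8") as fh:
            fh.write(f"status: {status}\n")
            for item in produced:
                fh.write(f"{item}\n")
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(old_level)
        handler.close()
    return out


def _execute_step(
    i: int,
    step: dict[str, Any],
    ens: Ensemble,
    config: ReportConfig,
    images: Path,
    tables: Path,
    produced: list[str],
) -> None:
    out_root = config.output_dir
    kind = step["kind"]
    fmt = step.get("format", config.image_format)
    img = images / f"{i:02d}_{kind}.{fmt}"

    def note(path: Path) -> None:
        produced.append(str(path.relative_to(out_root)))

    if kind in ("traces", "mean", "sd", "mean_sd"):
        plot_kind = "traces" if kind == "traces" else kind
        req = PlotRequest(
            kind=plot_kind,
            out_path=img,
            columns=step.get("columns"),
            start=step.get("start"),
            stop=step.get("stop"),
            grid_points=int(step.get("grid_points", 200)),
        )
        note(render(req, ens))
    elif kind in ("pdf", "pdf3d"):
        times = [float(t) for t in step.get("times", [step.get("t")])]
        columns = step.get("columns") or ens.var_names
        normed = bool(step.get("normed", True))
        fit = bool(step.get("fit", False))
        bins = _binning_from_step(step)
        for var in columns:
            ests = pdf_multi(ens, times, var, bins=bins, normed=normed, fit=fit)
            for est in ests:
                if est.fit is not None:
                    logger.info(
                        "pdf %s t=%g: n=%d min=%g max=%g gaussian mu=%.10g "
                        "sigma2=%.10g",
                        var, est.time, est.n_samples, est.sample_min,
                        est.sample_max, est.fit.mu, est.fit.sigma2,
                    )
                else:
                    logger.info(
                        "pdf %s t=%g: n=%d min=%g max=%g",
                        var, est.time, est.n_samples, est.sample_min, est.sample_max,
                    )
                tab = tables / f"{i:02d}_pdf_{var}_t{est.time:g}.tsv"
                write_density(est, tab)
                note(tab)
            var_img = images / f"{i:02d}_{kind}_{var}.{fmt}"
            plot_kind = "pdf_bar" if kind == "pdf" else "pdf_3d"
            note(render(PlotRequest(kind=plot_kind, out_path=var_img), ests))
    elif kind in ("meq2d", "meq3d"):
        columns = step.get("columns") or ens.var_names
        start = float(step.get("start", ens.t_first))
        stop = float(step["stop"])
        n_points = int(step.get("n_time_points", 50))
        bins = _binning_from_step(step)
        for var in columns:
            meq = master_equation(ens, var, start, stop, n_points, bins)
            tab = tables / f"{i:02d}_meq_{var}.tsv"
            write_meq(meq, tab)
            note(tab)
            var_img = images / f"{i:02d}_{kind}_{var}.{fmt}"
            plot_kind = "meq_heatmap" if kind == "meq2d" else "meq_surface"
            note(render(PlotRequest(kind=plot_kind, out_path=var_img), meq))
    elif kind in ("phase2d", "phase3d"):
        vars_ = list(step["vars"])
        if step.get("average", True):
            grid = _grid_for(ens, step)
            path = phase_space_avg(ens, grid, vars_)
        else:
            path = phase_space(ens[int(step.get("run", 0))], vars_)
        note(render(PlotRequest(kind=kind, out_path=img,
                                start=step.get("start"), stop=step.get("stop")), path))
    elif kind == "summary":
        pass  # always produced at report start
    elif kind == "sbrml_export":
        target = tables / step.get("filename", "dataset.sbrml.xml")
        write_sbrml(ens, target)
        note(target)
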