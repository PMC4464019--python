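"""Reading and writing trajectories and ensembles.

Native format: delimited text, one file per independent run, first column
time, remaining columns model variables. Lines starting with ``#`` are
comments. Delimiter and header are auto-detected (tab, comma, semicolon,
whitespace, in that order; a first line with any non-numeric token is a
header) unless the :class:`LoadSpec` says otherwise.

Dataset loading is process-parallel with a deterministic merge by sorted
filename: the resulting ensemble is bit-identical for every worker count.

SBRML support covers a minimal time-course subset (one time dimension plus
per-species value columns per result component); any other layout is
rejected loudly rather than half-parsed.

A content-addressed result cache (:class:`ResultCache`) memoises expensive
statistics: keys are cryptographic hashes of the input data content plus all
parameters, so edits to data or parameters always trigger recomputation, and
a corrupt cache entry degrades to a recompute with a warning, never a wrong
answer.
"""

from __future__ import annotations

import hashlib
import logging
import os
import pickle
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, TypeVar

import numpy as np
import pandas as pd
from lxml import etree

from .core import (
    DensityEstimate,
    Ensemble,
    MasterEqEstimate,
    TIME_COLUMN,
    Trajectory,
)
from .errors import (
    ConsistencyError,
    EmptyDatasetError,
    FormatError,
    ParameterError,
    UnsupportedDialectError,
)

logger = logging.getLogger(__name__)

T = TypeVar("T")

#: Namespace used for SBRML output (level 1 version 1 time-course subset).
SBRML_NS = "http://www.sbrml.org/sbrml/level1/version1"

_DELIMITERS: tuple[tuple[str, str], ...] = (
    ("\t", "\t"),
    (",", ","),
    (";", ";"),
)


@dataclass(frozen=True)
class LoadSpec:
    """Where and how to read one trajectory file or a dataset folder.

    ``col_names`` names every column including the time column (first by
    default); it overrides any header found in the file. ``delimiter`` and
    ``has_header`` default to auto-detection. ``n_workers=None`` uses all
    available cores for dataset loading.
    """

    path: str | Path
    pattern: str = "*"
    col_names: Optional[Sequence[str]] = None
    delimiter: str = "auto"
    has_header: bool | str = "auto"
    time_column: int = 0
    n_workers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_workers is not None and self.n_workers < 1:
            raise ParameterError("n_workers must be >= 1")


# -- delimited text --------------------------------------------------------


def _first_data_line(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                return stripped
    raise FormatError(f"{path}: file contains no data lines")


def _detect_delimiter(line: str) -> str:
    for char, sep in _DELIMITERS:
        if char in line:
            return sep
    return r"\s+"


def _tokenize(line: str, sep: str) -> list[str]:
    if sep == r"\s+":
        return line.split()
    return [tok.strip() for tok in line.split(sep)]


def _is_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_timeseries(spec: LoadSpec | str | Path) -> Trajectory:
    """Load a single trajectory from a delimited text file.

    Column names come from ``spec.col_names`` (first entry names the time
    column), else from a detected header, else are generated as ``V1..Vk``.
    Times must be strictly increasing; ragged rows and non-numeric cells are
    format errors.
    """
    if not isinstance(spec, LoadSpec):
        spec = LoadSpec(path=spec)
    path = Path(spec.path)
    if not path.is_file():
        raise FormatError(f"{path}: not a readable file")
    first = _first_data_line(path)
    sep = _detect_delimiter(first) if spec.delimiter == "auto" else spec.delimiter
    tokens = _tokenize(first, sep)
    if spec.has_header == "auto":
        has_header = any(not _is_numeric(tok) for tok in tokens)
    else:
        has_header = bool(spec.has_header)
    try:
        frame = pd.read_csv(
            path,
            sep=sep,
            comment="#",
            header=0 if has_header else None,
            skip_blank_lines=True,
            engine="c",
            float_precision="round_trip",  # exact text -> double parsing
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    n_cols = frame.shape[1]
    if spec.col_names is not None:
        if len(spec.col_names) != n_cols:
            raise FormatError(
                f"{path}: {len(spec.col_names)} column names given but the "
                f"file has {n_cols} columns"
            )
        frame.columns = list(spec.col_names)
    elif not has_header:
        frame.columns = [TIME_COLUMN] + [f"V{i}" for i in range(1, n_cols)]

    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: missing/ragged value in data row {row}")
    try:
        data = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc

    tcol = spec.time_column
    if not 0 <= tcol < n_cols:
        raise ParameterError(f"time_column {tcol} out of range for {n_cols} columns")
    times = data[:, tcol]
    values = np.delete(data, tcol, axis=1)
    var_names = [str(c) for i, c in enumerate(frame.columns) if i != tcol]
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise FormatError(
            f"{path}: time column not strictly increasing at data row {row} "
            f"(t={times[row]!r} after t={times[row - 1]!r})"
        )
    return Trajectory(times, values, var_names)


def write_timeseries(
    traj: Trajectory,
    path: str | Path,
    delimiter: str = "\t",
    precision: int = 17,
) -> None:
    """Write a trajectory as delimited text with a header line.

    The default 17 significant digits make the text round-trip exact for
    double precision.
    """
    path = Path(path)
    fmt = f"%.{precision}g"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join([TIME_COLUMN] + traj.var_names) + "\n")
        for t, row in zip(traj.times, traj.values):
            fh.write(delimiter.join(fmt % v for v in [t, *row]) + "\n")


def _load_one(args: tuple) -> Trajectory:
    path, spec = args
    return read_timeseries(replace(spec, path=path))


def load_dataset(spec: LoadSpec | str | Path) -> Ensemble:
    """Load a dataset folder: one trajectory per file, ordered by filename.

    The result is bit-identical for every ``n_workers`` value; files whose
    variable names or column counts disagree raise a consistency error
    listing the offenders.
    """
    if not isinstance(spec, LoadSpec):
        spec = LoadSpec(path=spec)
    root = Path(spec.path)
    if not root.is_dir():
        raise EmptyDatasetError(f"{root}: not a directory")
    files = sorted(p for p in root.glob(spec.pattern) if p.is_file())
    if not files:
        raise EmptyDatasetError(f"{root}: no files match pattern {spec.pattern!r}")
    n_workers = spec.n_workers or os.cpu_count() or 1
    tasks = [(p, spec) for p in files]
    if n_workers == 1 or len(files) == 1:
        trajs = [_load_one(t) for t in tasks]
    else:
        with ProcessPoolExecutor(max_workers=min(n_workers, len(files))) as pool:
            trajs = list(pool.map(_load_one, tasks))
    names = trajs[0].var_names
    offenders = [
        str(p.name) for p, tr in zip(files, trajs) if tr.var_names != names
    ]
    if offenders:
        raise ConsistencyError(
            f"files disagree with the variable names {names} of "
            f"{files[0].name}: {offenders}"
        )
    return Ensemble(trajs, provenance=str(root))


# -- SBRML time-course subset ----------------------------------------------


def _q(tag: str) -> str:
    return f"{{{SBRML_NS}}}{tag}"


def write_sbrml(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as an SBRML time-course document.

    One ``resultComponent`` per run; the dimension description declares the
    time index and one value column per species. Floats are written with 17
    significant digits so the document round-trips exactly.
    """
    if any(not n for n in ens.var_names):
        raise ParameterError("SBRML export requires non-empty variable names")
    root = etree.Element(_q("sbrml"), nsmap={None: SBRML_NS}, version="1")
    ops = etree.SubElement(root, _q("operations"))
    op = etree.SubElement(ops, _q("operation"), id="simulation")
    result = etree.SubElement(op, _q("result"))
    for i, traj in enumerate(ens):
        comp = etree.SubElement(result, _q("resultComponent"), id=f"run-{i:04d}")
        desc = etree.SubElement(comp, _q("dimensionDescription"))
        cdesc = etree.SubElement(
            desc, _q("compositeDescription"), name=TIME_COLUMN, indexType="double"
        )
        tdesc = etree.SubElement(cdesc, _q("tupleDescription"))
        for name in traj.var_names:
            etree.SubElement(
                tdesc, _q("atomicDescription"), name=name, valueType="double"
            )
        dim = etree.SubElement(comp, _q("dimension"))
        for t, row in zip(traj.times, traj.values):
            cval = etree.SubElement(
                dim, _q("compositeValue"), indexValue="%.17g" % t
            )
            tup = etree.SubElement(cval, _q("tuple"))
            for v in row:
                atom = etree.SubElement(tup, _q("atomicValue"))
                atom.text = "%.17g" % v
    tree = etree.ElementTree(root)
    tree.write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def read_sbrml(path: str | Path) -> Ensemble:
    """Read an SBRML time-course document into an ensemble.

    Only the time-course layout written by :func:`write_sbrml` is accepted:
    each ``resultComponent`` must carry a ``compositeDescription`` naming the
    time index and a tuple of per-species value columns. Anything else
    raises :class:`UnsupportedDialectError` naming the offending element.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if _local(root) != "sbrml":
        raise UnsupportedDialectError(
            f"{path}: root element is <{_local(root)}>, expected <sbrml>"
        )
    comps = root.findall(f".//{{*}}resultComponent")
    if not comps:
        raise UnsupportedDialectError(f"{path}: no <resultComponent> found")
    trajs = []
    for comp in comps:
        cid = comp.get("id", "?")
        cdesc = comp.find("{*}dimensionDescription/{*}compositeDescription")
        if cdesc is None:
            raise UnsupportedDialectError(
                f"{path}: resultComponent {cid!r} lacks a "
                "<compositeDescription> (no time dimension)"
            )
        if cdesc.get("indexType") not in ("double", "float", "integer"):
            raise UnsupportedDialectError(
                f"{path}: resultComponent {cid!r} has a non-numeric index "
                f"type {cdesc.get('indexType')!r}"
            )
        atoms = cdesc.findall("{*}tupleDescription/{*}atomicDescription")
        if not atoms:
            raise UnsupportedDialectError(
                f"{path}: resultComponent {cid!r} declares no value columns"
            )
        names = [a.get("name", "") for a in atoms]
        times, rows = [], []
        for cval in comp.findall("{*}dimension/{*}compositeValue"):
            idx = cval.get("indexValue")
            if idx is None:
                raise UnsupportedDialectError(
                    f"{path}: <compositeValue> without indexValue in {cid!r}"
                )
            vals = cval.findall("{*}tuple/{*}atomicValue")
            if len(vals) != len(names):
                raise FormatError(
                    f"{path}: row at t={idx} in {cid!r} has {len(vals)} "
                    f"values for {len(names)} columns"
                )
            times.append(float(idx))
            rows.append([float(v.text) for v in vals])
        if not times:
            raise UnsupportedDialectError(
                f"{path}: resultComponent {cid!r} contains no data rows"
            )
        trajs.append(Trajectory(times, rows, names))
    return Ensemble(trajs, provenance=str(path))


# -- statistic exports -----------------------------------------------------


def write_density(estimate: DensityEstimate, path: str | Path, delimiter: str = "\t") -> None:
    """Export a density estimate as delimited text (edges and masses)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variable: {estimate.var_name}\n")
        fh.write(f"# time: {estimate.time!r}\n")
        fh.write(f"# kind: {estimate.kind}  n_samples: {estimate.n_samples}\n")
        fh.write(
            f"# sample_min: {estimate.sample_min!r}  "
            f"sample_max: {estimate.sample_max!r}\n"
        )
        if estimate.fit is not None:
            fh.write(
                f"# gaussian_fit_mu: {estimate.fit.mu!r}  "
                f"gaussian_fit_sigma2: {estimate.fit.sigma2!r}\n"
            )
        fh.write(delimiter.join(["left_edge", "right_edge", "value"]) + "\n")
        for lo, hi, m in zip(
            estimate.bin_edges[:-1], estimate.bin_edges[1:], estimate.mass
        ):
            fh.write(delimiter.join("%.17g" % v for v in (lo, hi, m)) + "\n")


def write_meq(meq: MasterEqEstimate, path: str | Path, delimiter: str = "\t") -> None:
    """Export a master-equation estimate as a time x state-bin matrix."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variable: {meq.var_name}\n")
        fh.write("# rows: time points; columns: state-bin centres\n")
        fh.write(
            delimiter.join(
                [TIME_COLUMN] + ["%.17g" % c for c in meq.bin_centres]
            )
            + "\n"
        )
        for t, row in zip(meq.grid.points, meq.prob):
            fh.write(delimiter.join("%.17g" % v for v in [t, *row]) + "\n")


# -- content-addressed result cache ----------------------------------------


def content_key(*parts) -> str:
    """Cryptographic key for a computation: data content plus parameters.

    Arrays are hashed over dtype, shape and raw bytes; trajectories and
    ensembles over all their arrays and names; everything else over its
    ``repr``. Two keys are equal only if every input byte and parameter is.
    """
    h = hashlib.sha256()

    def feed(obj) -> None:
        if isinstance(obj, np.ndarray):
            h.update(b"ndarray")
            h.update(str(obj.dtype).encode())
            h.update(str(obj.shape).encode())
            h.update(np.ascontiguousarray(obj).tobytes())
        elif isinstance(obj, Trajectory):
            h.update(b"trajectory")
            feed(obj.times)
            feed(obj.values)
            h.update(repr(obj.var_names).encode())
        elif isinstance(obj, Ensemble):
            h.update(b"ensemble")
            for tr in obj:
                feed(tr)
        elif isinstance(obj, (tuple, list)):
            h.update(b"seq")
            for item in obj:
                feed(item)
        elif isinstance(obj, dict):
            h.update(b"map")
            for k in sorted(obj):
                h.update(repr(k).encode())
                feed(obj[k])
        else:
            h.update(repr(obj).encode())
        h.update(b"\x00")

    for part in parts:
        feed(part)
    return h.hexdigest()


class ResultCache:
    """Size-capped, LRU-evicted pickle store keyed by content hash.

    Lives in a dot-directory (conventionally beside the dataset). A second
    request with an identical key is served from disk without recomputation;
    any change in data or parameters yields a fresh key and hence a fresh
    computation. Corrupt entries are discarded with a warning and
    transparently recomputed.
    """

    def __init__(
        self,
        directory: str | Path,
        max_bytes: int = 256 * 1024 * 1024,
        enabled: bool = True,
    ) -> None:
        self.directory = Path(directory)
        self.max_bytes = max_bytes
        self.enabled = enabled
        if enabled:
            self.directory.mkdir(parents=True, exist_ok=True)

    def _entry(self, key: str) -> Path:
        return self.directory / f"{key}.pkl"

    def get_or_compute(self, key: str, thunk: Callable[[], T]) -> T:
        """Return the cached result for ``key``, computing it on a miss."""
        if not self.enabled:
            return thunk()
        entry = self._entry(key)
        if entry.exists():
            try:
                with open(entry, "rb") as fh:
                    value = pickle.load(fh)
                entry.touch()  # refresh LRU clock
                return value
            except Exception:
                logger.warning(
                    "cache entry %s is corrupt; recomputing", entry.name
                )
                entry.unlink(missing_ok=True)
        value = thunk()
        try:
            with open(entry, "wb") as fh:
                pickle.dump(value, fh, protocol=pickle.HIGHEST_PROTOCOL)
            self._evict()
        except OSError as exc:
            logger.warning("could not write cache entry %s: %s", entry.name, exc)
        return value

    def _evict(self) -> None:
        entries = sorted(
            self.directory.glob("*.pkl"), key=lambda p: p.stat().st_mtime
        )
        total = sum(p.stat().st_size for p in entries)
        while entries and total > self.max_bytes:
            victim = entries.pop(0)
            total -= victim.stat().st_size
            victim.unlink(missing_ok=True)

    def clear(self) -> None:
        for entry in self.directory.glob("*.pkl"):
            entry.unlink(missing_ok=True)


def cache_get_or_compute(
    cache: Optional[ResultCache], key: str, thunk: Callable[[], T]
) -> T:
    """Memoise ``thunk`` under ``key``; with ``cache=None`` just compute."""
    if cache is None:
        return thunk()
    return cache.get_or_compute(key, thunk)
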