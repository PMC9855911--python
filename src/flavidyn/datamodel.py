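"""Core containers and delimited-matrix I/O for time-resolved spectra.

A time-resolved dataset is a matrix of signal changes (stimulated-Raman
intensity or absorbance) on a grid of pump-probe delays (rows, seconds)
by spectral channels (columns, wavenumbers in cm^-1 for Raman or
wavelengths in nm for transient absorption).

File dialect
------------
One fixed plain-text dialect is used for every matrix artifact:

* tab-separated by default; comma-separated accepted for ``.csv`` paths;
* cell (0, 0) is the literal header token ``delay_s``;
* row 0 holds the spectral axis values, column 0 the delays in seconds;
* UTF-8, ``.`` decimal separator, scientific notation accepted;
* floats are written with 10 significant digits, so a write/read
  round-trip is lossless to 1e-9 relative.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("flavidyn")

HEADER_TOKEN = "delay_s"

#: Delays below this value (seconds) fall inside the instrument-response /
#: coherent-artifact window and are excluded before any kinetic analysis.
EARLY_DELAY_CUTOFF = 750e-15


class AxisKind(str, Enum):
    wavenumber_cm1 = "wavenumber_cm1"
    wavelength_nm = "wavelength_nm"


class Modality(str, Enum):
    FSRS = "FSRS"
    TA = "TA"


class Solvent(str, Enum):
    H2O = "H2O"
    D2O = "D2O"


class MatrixFormatError(ValueError):
    """Structural problem in a delimited matrix file (ragged rows, bad header)."""


class MatrixParseError(ValueError):
    """A cell could not be parsed as a number; names the row and column."""


class ValidationError(ValueError):
    """A domain invariant was violated (axis ordering, delay sign, shapes)."""


# ---------------------------------------------------------------------------
# Axes and dataset containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralAxis:
    """Ordered spectral axis, wavenumbers (cm^-1) or wavelengths (nm)."""

    kind: AxisKind
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", AxisKind(self.kind))
        if vals.ndim != 1 or vals.size < 2:
            raise ValidationError("spectral axis needs at least 2 values")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("spectral axis values must be finite and > 0")
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("spectral axis must be strictly monotonic")

    @property
    def n_channels(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TimeGrid:
    """Pump-probe delays in seconds, strictly increasing and positive."""

    delays: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.delays, dtype=float)
        object.__setattr__(self, "delays", t)
        if t.ndim != 1 or t.size < 1:
            raise ValidationError("time grid must be a non-empty 1-d array")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValidationError("delays must be finite and > 0 seconds")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("delays must be strictly increasing")

    @property
    def n_delays(self) -> int:
        return self.delays.size


@dataclass(frozen=True)
class DatasetMeta:
    modality: Modality
    solvent: Solvent
    sample: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        object.__setattr__(self, "solvent", Solvent(self.solvent))


@dataclass(frozen=True)
class TRDataset:
    """Time-resolved signal matrix with its two axes and metadata.

    ``signal[i, j]`` is the signal change at delay ``time.delays[i]`` and
    spectral channel ``axis.values[j]`` (arbitrary units).
    """

    time: TimeGrid
    axis: SpectralAxis
    signal: np.ndarray
    meta: DatasetMeta

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if sig.shape != (self.time.n_delays, self.axis.n_channels):
            raise ValidationError(
                f"signal shape {sig.shape} does not match "
                f"({self.time.n_delays}, {self.axis.n_channels})"
            )
        if not np.all(np.isfinite(sig)):
            raise ValidationError("signal contains non-finite values")

    @property
    def n_delays(self) -> int:
        return self.time.n_delays

    @property
    def n_channels(self) -> int:
        return self.axis.n_channels


# ---------------------------------------------------------------------------
# Spectral regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Closed spectral interval [lo, hi] in the units of its axis kind."""

    name: str
    lo: float
    hi: float
    kind: AxisKind

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"region {self.name}: lo must be < hi")


#: Named analysis regions. ``raman_low_full`` has no fixed lower bound: it
#: extends down to the dataset minimum wavenumber (instrument dependent),
#: encoded here as None and resolved against an axis by :func:`get_region`.
REGION_BOUNDS: dict[str, tuple[float | None, float, AxisKind]] = {
    "raman_high": (1000.0, 1750.0, AxisKind.wavenumber_cm1),
    "raman_low_truncated": (303.0, 1000.0, AxisKind.wavenumber_cm1),
    "raman_low_full": (None, 1000.0, AxisKind.wavenumber_cm1),
    "visTA": (380.0, 1000.0, AxisKind.wavelength_nm),
}


def get_region(name: str, axis: SpectralAxis | None = None) -> Region:
    """Resolve a named region, filling the open lower bound from ``axis``."""
    try:
        lo, hi, kind = REGION_BOUNDS[name]
    except KeyError:
        raise ValidationError(
            f"unknown region {name!r}; valid: {sorted(REGION_BOUNDS)}"
        ) from None
    if lo is None:
        if axis is None:
            raise ValidationError(
                f"region {name!r} needs an axis to resolve its lower bound"
            )
        lo = float(np.min(axis.values))
    return Region(name=name, lo=lo, hi=hi, kind=kind)


def slice_region(ds: TRDataset, region: Region | str) -> TRDataset:
    """Keep the channels inside a closed spectral interval.

    The region kind must match the dataset axis kind (a wavelength region
    cannot slice a wavenumber axis). The time grid is unchanged.
    """
    if isinstance(region, str):
        region = get_region(region, ds.axis)
    if region.kind != ds.axis.kind:
        raise ValidationError(
            f"region {region.name!r} is a {region.kind.value} region but the "
            f"dataset axis is {ds.axis.kind.value}"
        )
    mask = (ds.axis.values >= region.lo) & (ds.axis.values <= region.hi)
    if not mask.any():
        raise ValidationError(
            f"region {region.name!r} [{region.lo}, {region.hi}] selects no "
            f"channels on axis spanning "
            f"[{ds.axis.values.min()}, {ds.axis.values.max()}]"
        )
    axis = SpectralAxis(ds.axis.kind, ds.axis.values[mask])
    return TRDataset(ds.time, axis, ds.signal[:, mask], ds.meta)


def exclude_early_delays(ds: TRDataset, cutoff: float = EARLY_DELAY_CUTOFF) -> TRDataset:
    """Drop delays strictly below ``cutoff`` seconds (boundary kept)."""
    keep = ds.time.delays >= cutoff
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValidationError(
            f"all {ds.n_delays} delays are below the {cutoff:g} s cutoff"
        )
    if n_removed:
        logger.info("excluded %d delays below %g s", n_removed, cutoff)
    return TRDataset(
        TimeGrid(ds.time.delays[keep]), ds.axis, ds.signal[keep, :], ds.meta
    )


# ---------------------------------------------------------------------------
# Delimited-matrix reader / writer
# ---------------------------------------------------------------------------

def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_cell(token: str, row: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise MatrixParseError(
            f"non-numeric cell at row {row}, column {col}: {token!r}"
        ) from None


def read_dataset(
    path: str | Path,
    meta: DatasetMeta | dict,
    axis_kind: AxisKind | None = None,
) -> TRDataset:
    """Read a delimited time x spectral-channel matrix.

    ``axis_kind`` defaults from the modality: TA data carry a wavelength
    axis (nm), FSRS data a wavenumber axis (cm^-1). Rows are sorted by
    delay if the file is unsorted.
    """
    path = Path(path)
    if isinstance(meta, dict):
        meta = DatasetMeta(**meta)
    if axis_kind is None:
        axis_kind = (
            AxisKind.wavelength_nm
            if meta.modality is Modality.TA
            else AxisKind.wavenumber_cm1
        )

    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=_delimiter_for(path)) if r]
    if len(rows) < 2:
        raise MatrixFormatError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    if header[0].strip() != HEADER_TOKEN:
        raise MatrixFormatError(
            f"{path}: cell (0,0) must be {HEADER_TOKEN!r}, got {header[0]!r}"
        )
    n_cols = len(header)
    if n_cols < 2:
        raise MatrixFormatError(f"{path}: no spectral channels in header row")
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != n_cols:
            raise MatrixFormatError(
                f"{path}: ragged row {i} has {len(row)} cells, expected {n_cols}"
            )

    axis_vals = np.array(
        [_parse_cell(tok, 0, j) for j, tok in enumerate(header[1:], start=1)]
    )
    delays = np.array(
        [_parse_cell(row[0], i, 0) for i, row in enumerate(rows[1:], start=1)]
    )
    if np.any(delays <= 0):
        bad = int(np.argmax(delays <= 0))
        raise ValidationError(
            f"{path}: non-positive delay {delays[bad]:g} s at data row {bad + 1}"
        )
    signal = np.array(
        [
            [_parse_cell(tok, i, j) for j, tok in enumerate(row[1:], start=1)]
            for i, row in enumerate(rows[1:], start=1)
        ]
    )
    order = np.argsort(delays, kind="stable")
    return TRDataset(
        TimeGrid(delays[order]),
        SpectralAxis(axis_kind, axis_vals),
        signal[order, :],
        meta,
    )


def _fmt(x: float) -> str:
    # 10 significant digits: worst-case relative rounding error 5e-10,
    # which keeps the advertised 1e-9 round-trip guarantee (9 digits
    # would allow up to 5e-9 for values with leading digit 1)
    return f"{float(x):.10g}"


def write_matrix(obj, path: str | Path) -> Path:
    """Write a two-axis object as a delimited matrix (deterministic bytes).

    Dispatches structurally: a :class:`TRDataset` becomes a delay x channel
    matrix headed by ``delay_s``; an amplitude map becomes a channel x
    lifetime matrix (lifetime header row, trailing ``offset`` column); a
    dynamical-content curve becomes a two-column ``tau_s``/``D`` table.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    lines: list[str] = []
    if hasattr(obj, "signal"):  # TRDataset
        lines.append(sep.join([HEADER_TOKEN] + [_fmt(v) for v in obj.axis.values]))
        for t, row in zip(obj.time.delays, obj.signal):
            lines.append(sep.join([_fmt(t)] + [_fmt(v) for v in row]))
    elif hasattr(obj, "amplitudes"):  # AmplitudeMap
        lines.append(
            sep.join(["axis_value"] + [_fmt(t) for t in obj.grid.taus] + ["offset"])
        )
        for x, row, off in zip(obj.axis.values, obj.amplitudes, obj.offsets):
            lines.append(sep.join([_fmt(x)] + [_fmt(v) for v in row] + [_fmt(off)]))
    elif hasattr(obj, "D"):  # DynamicalContent
        lines.append(sep.join(["tau_s", "D"]))
        for t, d in zip(obj.grid.taus, obj.D):
            lines.append(sep.join([_fmt(t), _fmt(d)]))
    else:
        raise TypeError(f"don't know how to serialize {type(obj).__name__}")
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc
    return path
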