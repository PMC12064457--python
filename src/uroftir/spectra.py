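"""Spectrum containers and .dpt data-point-table I/O.

ATR-FTIR instruments export "data point tables": plain-text files with one
``wavenumber, absorbance`` pair per line (comma, tab or space separated,
ascending or descending).  This module reads and writes that dialect,
averages technical replicates, subtracts the water background, and stacks
the per-patient spectra into the labelled matrix used by every downstream
step.

Conventions
-----------
* Wavenumber grids are stored strictly descending (4000 -> 400 cm^-1),
  uniformly spaced, in cm^-1.
* Absorbance is dimensionless (AU).
* Labels: 0 = control (benign), 1 = cancer.
* ``replicate == 0`` marks a replicate-averaged spectrum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    GridError,
    IdentityError,
    LabelError,
    MissingDataError,
    ParseError,
)

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectraSet",
    "read_dpt",
    "write_dpt",
    "average_replicates",
    "subtract_background",
    "assemble_set",
    "load_metadata",
]

#: absolute tolerance (cm^-1) on grid uniformity after canonicalisation
GRID_UNIFORM_TOL = 1e-9
#: tolerance used when deciding whether a parsed grid is uniform
PARSE_UNIFORM_TOL = 1e-6


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly descending, uniformly spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise GridError("grid needs at least two wavenumbers")
        diffs = np.diff(values)
        if not np.all(diffs < 0):
            raise GridError("wavenumber grid must be strictly descending")
        if np.ptp(diffs) > GRID_UNIFORM_TOL:
            raise GridError(
                f"non-uniform grid spacing (spread {np.ptp(diffs):.3g} cm^-1)"
            )
        if values.min() < 400.0 - GRID_UNIFORM_TOL or values.max() > 4000.0 + GRID_UNIFORM_TOL:
            raise GridError("grid outside the 4000-400 cm^-1 instrument range")

    @property
    def spacing(self) -> float:
        """Grid step in cm^-1 (positive)."""
        return float(self.values[0] - self.values[1])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, atol=GRID_UNIFORM_TOL, rtol=0.0
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((len(self), float(self.values[0]), float(self.values[-1])))

    def index_of(self, wavenumber: float, max_distance: float | None = None) -> int:
        """Index of the grid point nearest ``wavenumber``.

        ``max_distance`` defaults to one grid spacing.
        """
        if max_distance is None:
            max_distance = self.spacing
        idx = int(np.argmin(np.abs(self.values - wavenumber)))
        if abs(self.values[idx] - wavenumber) > max_distance + GRID_UNIFORM_TOL:
            from .errors import LookupError_

            raise LookupError_(
                f"wavenumber {wavenumber} cm^-1 not on grid "
                f"(nearest {self.values[idx]} cm^-1)"
            )
        return idx


@dataclass
class Spectrum:
    """One absorbance trace on a wavenumber grid plus measurement metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    patient_id: str = ""
    replicate: int = 1
    label: int | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.grid),) :
            raise GridError(
                f"absorbance length {self.absorbance.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError(f"non-finite absorbance in spectrum {self.patient_id!r}")
        if self.label is not None and self.label not in (0, 1):
            raise LabelError(f"label {self.label!r} outside {{0, 1}}")


@dataclass
class SpectraSet:
    """Labelled patient x wavenumber absorbance matrix (replicates averaged)."""

    grid: WavenumberGrid
    matrix: np.ndarray
    labels: np.ndarray
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.matrix.shape
        if p != len(self.grid):
            raise GridError("matrix column count != grid length")
        if self.labels.shape != (n,):
            raise LabelError("labels length != row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise LabelError("labels must be in {0, 1}")
        if len(self.patient_ids) != n:
            raise IdentityError("patient_ids length != row count")
        if len(set(self.patient_ids)) != n:
            raise IdentityError("duplicate patient_id in SpectraSet")

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    def with_matrix(self, matrix: np.ndarray) -> "SpectraSet":
        return SpectraSet(self.grid, matrix, self.labels.copy(), list(self.patient_ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=np.round(self.grid.values, 6))
        df.insert(0, "patient_id", self.patient_ids)
        df.insert(1, "label", self.labels)
        return df


_SEPARATORS = (",", "\t", None)  # None -> any whitespace


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return line.split()


def read_dpt(path: str | Path, patient_id: str = "", replicate: int = 1,
             label: int | None = None) -> Spectrum:
    """Read a two-column data-point-table spectrum.

    The separator (comma, tab or whitespace) is auto-detected per line and
    ascending files are flipped to the descending convention.  Uniform
    spacing is enforced to text precision and the grid re-canonicalised via
    ``linspace`` so downstream exact-uniformity invariants hold.
    """
    path = Path(path)
    wavenumbers: list[float] = []
    absorbances: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = _split_line(line)
            if len(fields) != 2:
                raise ParseError(f"{path.name}:{lineno}: expected two fields, got {len(fields)}")
            try:
                wavenumbers.append(float(fields[0]))
                absorbances.append(float(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    if len(wavenumbers) < 2:
        raise FormatError(f"{path.name}: fewer than 2 data points")
    wn = np.asarray(wavenumbers)
    ab = np.asarray(absorbances)
    if wn[0] < wn[-1]:  # ascending export -> normalise
        wn, ab = wn[::-1], ab[::-1]
    diffs = np.diff(wn)
    if not np.all(diffs < 0):
        raise GridError(f"{path.name}: wavenumbers not monotone")
    if np.ptp(diffs) > PARSE_UNIFORM_TOL:
        raise GridError(f"{path.name}: non-uniform grid spacing beyond tolerance")
    grid = WavenumberGrid(np.linspace(wn[0], wn[-1], wn.size))
    return Spectrum(grid, ab, patient_id=patient_id, replicate=replicate, label=label)


def write_dpt(path: str | Path, spectrum: Spectrum, fmt: str = "%.6f") -> None:
    """Write a spectrum as a comma-separated data point table."""
    data = np.column_stack([spectrum.grid.values, spectrum.absorbance])
    np.savetxt(path, data, fmt=fmt, delimiter=",")


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of technical replicates of one patient.

    The result carries ``replicate = 0`` to mark it as the aggregate.
    """
    if len(spectra) == 0:
        raise MissingDataError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.grid != first.grid:
            raise GridError("replicate grids differ")
        if s.patient_id != first.patient_id:
            raise IdentityError(
                f"mixed patient ids {first.patient_id!r} and {s.patient_id!r}"
            )
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return Spectrum(first.grid, mean, patient_id=first.patient_id,
                    replicate=0, label=first.label)


def subtract_background(sample: Spectrum, background: Spectrum,
                        scale: float = 1.0) -> Spectrum:
    """``sample - scale * background`` pointwise, on identical grids.

    The study subtracts a double-distilled-water reference from each
    replicate-averaged urine spectrum; plain unit-scale subtraction, no
    automated scaling optimisation.
    """
    if not np.isfinite(scale):
        raise ValueError("scale must be finite")
    if sample.grid != background.grid:
        raise GridError("sample and background grids differ")
    return replace(sample, absorbance=sample.absorbance - scale * background.absorbance)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata CSV (patient_id, replicate, label[, file])."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "replicate", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    return df


def assemble_set(
    spectra: Iterable[Spectrum],
    metadata: pd.DataFrame,
    background: Spectrum | None = None,
    background_scale: float = 1.0,
) -> SpectraSet:
    """Average replicates per patient, subtract the background, stack rows.

    Rows follow the order of first appearance of each patient in
    ``metadata``; each patient must have exactly one label in {0, 1} and at
    least one spectrum.
    """
    by_patient: dict[str, list[Spectrum]] = {}
    for s in spectra:
        by_patient.setdefault(s.patient_id, []).append(s)

    meta_labels: dict[str, int] = {}
    order: list[str] = []
    for _, row in metadata.iterrows():
        pid = str(row["patient_id"])
        label = row["label"]
        if label not in (0, 1):
            raise LabelError(f"patient {pid}: label {label!r} outside {{0, 1}}")
        if pid in meta_labels:
            if meta_labels[pid] != int(label):
                raise LabelError(f"patient {pid}: conflicting labels")
        else:
            meta_labels[pid] = int(label)
            order.append(pid)

    if not order:
        raise MissingDataError("empty metadata")

    rows, labels = [], []
    grid: WavenumberGrid | None = None
    for pid in order:
        if pid not in by_patient:
            raise MissingDataError(f"patient {pid} has no spectra")
        avg = average_replicates(by_patient[pid])
        if background is not None:
            avg = subtract_background(avg, background, background_scale)
        if grid is None:
            grid = avg.grid
        elif avg.grid != grid:
            raise GridError(f"patient {pid}: grid differs from cohort grid")
        rows.append(avg.absorbance)
        labels.append(meta_labels[pid])
    assert grid is not None
    return SpectraSet(grid, np.vstack(rows), np.asarray(labels), order)
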