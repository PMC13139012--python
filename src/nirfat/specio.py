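"""Spectral table I/O.

The canonical interchange format is a wide CSV: one row per sample, a
header of ``sample_id,state,fat_percent,<wavelength>,...`` with one
wavelength (nm) per remaining column.  Absorbance is stored in absorbance
units (AU).  A minimal read-only JCAMP-DX parser covers the single-spectrum
``##XYDATA=(X++(Y..Y))`` layout that portable NIR instruments commonly
export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STATES = ("in_shell", "de_shelled", "granules")

#: decimal places used by :func:`write_csv_dataset`; re-reads are stable
#: to this precision.
ABSORBANCE_DECIMALS = 8
FAT_DECIMALS = 4

RESERVED_COLUMNS = ("sample_id", "state", "fat_percent")


class SpectraFormatError(ValueError):
    """Raised when a spectral file violates the documented layout."""


@dataclass
class SpectralDataset:
    """A wavelength grid with an n x p absorbance matrix and metadata.

    Parameters
    ----------
    wavelengths : array of float, shape (p,)
        Strictly increasing wavelength grid in nm.
    absorbance : array of float, shape (n, p)
        Absorbance in AU; must be finite.
    sample_ids : array of int, shape (n,)
        Unique sample identifiers (1-based by convention).
    reference : array of float, shape (n,), optional
        Reference fat content in % (w/w); absent for prediction-only data.
    state : str
        One of ``in_shell``, ``de_shelled``, ``granules`` or ``unknown``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    reference: np.ndarray | None = None
    state: str = "unknown"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=int)
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.wavelengths.ndim != 1:
            raise SpectraFormatError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraFormatError("wavelength grid must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise SpectraFormatError(
                f"absorbance has {p} columns but grid has {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("absorbance contains non-finite values")
        if self.sample_ids.size != n:
            raise SpectraFormatError("sample_ids length does not match row count")
        if np.unique(self.sample_ids).size != n:
            raise SpectraFormatError("sample_ids must be unique")
        if self.reference is not None and self.reference.size != n:
            raise SpectraFormatError("reference length does not match row count")
        if self.state not in STATES and self.state != "unknown":
            raise SpectraFormatError(f"unknown state label {self.state!r}")

    # -- conveniences ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, sample_ids: Sequence[int]) -> "SpectralDataset":
        """Rows restricted to ``sample_ids``, in the stored row order."""
        wanted = set(int(s) for s in sample_ids)
        missing = wanted - set(self.sample_ids.tolist())
        if missing:
            raise KeyError(f"sample ids not in dataset: {sorted(missing)}")
        mask = np.array([int(s) in wanted for s in self.sample_ids])
        return replace(
            self,
            absorbance=self.absorbance[mask],
            sample_ids=self.sample_ids[mask],
            reference=None if self.reference is None else self.reference[mask],
        )

    def drop(self, sample_ids: Sequence[int]) -> "SpectralDataset":
        """Rows with ``sample_ids`` removed; unknown ids are an error."""
        doomed = set(int(s) for s in sample_ids)
        missing = doomed - set(self.sample_ids.tolist())
        if missing:
            raise KeyError(f"sample ids not in dataset: {sorted(missing)}")
        keep = [int(s) for s in self.sample_ids if int(s) not in doomed]
        return self.subset(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        same_ref = (
            (self.reference is None) == (other.reference is None)
            and (self.reference is None or np.array_equal(self.reference, other.reference))
        )
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and same_ref
            and self.state == other.state
        )


# ---------------------------------------------------------------------------
# wide CSV
# ---------------------------------------------------------------------------

def write_csv_dataset(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as a wide CSV with deterministic formatting.

    Columns are ``sample_id,state,fat_percent,<grid...>``; the
    ``fat_percent`` column is omitted when the dataset has no reference
    values.  Absorbance is written with 8 decimals and fat with 4, so a
    write -> read round-trip is the identity at that precision.
    """
    dataset.validate()
    cols: dict[str, object] = {"sample_id": dataset.sample_ids, "state": dataset.state}
    if dataset.reference is not None:
        cols["fat_percent"] = np.round(dataset.reference, FAT_DECIMALS)
    frame = pd.DataFrame(cols)
    spec = pd.DataFrame(
        np.round(dataset.absorbance, ABSORBANCE_DECIMALS),
        columns=[_format_wavelength(w) for w in dataset.wavelengths],
        index=frame.index,
    )
    pd.concat([frame, spec], axis=1).to_csv(path, index=False)


def read_csv_dataset(path: str | Path) -> SpectralDataset:
    """Parse a wide CSV written by :func:`write_csv_dataset`.

    Raises :class:`SpectraFormatError` with row/column context on a
    non-monotone wavelength header, duplicate sample ids, ragged rows or
    non-numeric cells.  Row count in equals row count out.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise SpectraFormatError(f"{path}: malformed CSV ({exc})") from exc
    if "sample_id" not in frame.columns:
        raise SpectraFormatError(f"{path}: missing reserved column 'sample_id'")
    wl_cols = [c for c in frame.columns if c not in RESERVED_COLUMNS]
    if not wl_cols:
        raise SpectraFormatError(f"{path}: no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavelength header ({exc})") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectraFormatError(f"{path}: wavelength header is not strictly increasing")

    def _numeric(col: str) -> np.ndarray:
        series = pd.to_numeric(frame[col], errors="coerce")
        bad = series.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 zero-base
            raise SpectraFormatError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} in column {col!r}, line {row}"
            )
        if series.isna().any():
            row = int(series.isna().idxmax()) + 2
            raise SpectraFormatError(f"{path}: missing value in column {col!r}, line {row}")
        return series.to_numpy(dtype=float)

    absorbance = np.column_stack([_numeric(c) for c in wl_cols])
    ids_float = _numeric("sample_id")
    sample_ids = ids_float.astype(int)
    if np.any(sample_ids != ids_float):
        raise SpectraFormatError(f"{path}: sample_id column must hold integers")
    if np.unique(sample_ids).size != sample_ids.size:
        dupes = pd.Series(sample_ids)
        dupes = sorted(dupes[dupes.duplicated()].unique().tolist())
        raise SpectraFormatError(f"{path}: duplicate sample ids {dupes}")
    reference = _numeric("fat_percent") if "fat_percent" in frame.columns else None
    if "state" in frame.columns:
        labels = frame["state"].unique().tolist()
        if len(labels) != 1:
            raise SpectraFormatError(f"{path}: mixed state labels {labels}")
        state = str(labels[0])
    else:
        state = "unknown"
    return SpectralDataset(wavelengths, absorbance, sample_ids, reference, state)


def _format_wavelength(w: float) -> str:
    return f"{w:g}"


# ---------------------------------------------------------------------------
# JCAMP-DX (single spectrum, (X++(Y..Y)) AFFN)
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")


def read_jcampdx_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one spectrum from a JCAMP-DX file.

    Supports the ``##XYDATA=(X++(Y..Y))`` tabular form with plain AFFN
    numbers.  The abscissa is reconstructed from ``##FIRSTX``/``##LASTX``/
    ``##NPOINTS`` and both axes are scaled by ``##XFACTOR``/``##YFACTOR``.

    Returns ``(wavelengths, absorbance)`` arrays of length NPOINTS.
    """
    path = Path(path)
    records: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].strip()  # strip JCAMP comments
        if not line:
            continue
        match = _LDR.match(line)
        if match:
            label = match.group(1).upper().replace(" ", "")
            value = match.group(2).strip()
            if label == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise SpectraFormatError(f"{path}: unsupported XYDATA form {value!r}")
                in_data = True
                continue
            if label == "END":
                in_data = False
                continue
            records[label] = value
        elif in_data:
            data_lines.append(line)
    required = ("FIRSTX", "LASTX", "NPOINTS", "XFACTOR", "YFACTOR")
    missing = [k for k in required if k not in records]
    if missing:
        raise SpectraFormatError(f"{path}: missing required records {missing}")
    if not data_lines:
        raise SpectraFormatError(f"{path}: no XYDATA table found")
    npoints = int(float(records["NPOINTS"]))
    float(records["XFACTOR"])  # validated present; FIRSTX/LASTX are actual values
    yfactor = float(records["YFACTOR"])
    firstx = float(records["FIRSTX"])
    lastx = float(records["LASTX"])

    ys: list[float] = []
    for line in data_lines:
        numbers = [float(tok) for tok in re.split(r"[,\s]+", line) if tok]
        if not numbers:
            continue
        ys.extend(numbers[1:])  # leading value is the line's X check value
    if len(ys) != npoints:
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but decoded {len(ys)} ordinate values"
        )
    wavelengths = np.linspace(firstx, lastx, npoints)
    absorbance = np.asarray(ys, dtype=float) * yfactor
    return wavelengths, absorbance
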