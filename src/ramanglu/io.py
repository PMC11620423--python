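"""Reading and writing label-prefixed Raman CSV files.

One sample per file, two numeric columns (Raman shift in cm^-1, intensity
counts), with the integer class label encoded as the filename prefix before
the first ``-`` character (e.g. ``7-solution-rep3.csv`` has label code 7).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    AxisMismatch,
    EmptyDataset,
    MalformedSpectrum,
    MissingLabel,
)

#: Glucose concentration (mmol/L) -> integer label code used throughout the
#: study design: ten levels, coded 1..10 in ascending concentration order.
TABLE1_LABEL_MAP: dict[float, int] = {
    5.0: 1,
    5.5: 2,
    6.0: 3,
    6.5: 4,
    7.0: 5,
    7.5: 6,
    10.0: 7,
    12.5: 8,
    15.0: 9,
    20.0: 10,
}

#: Fixed decimal formatting used by the writers so round trips are exact on
#: the textual representation.
_CSV_FLOAT_FMT = "%.6f"


@dataclass
class Spectrum:
    """A single Raman spectrum: ascending shift axis, intensities, label.

    Parameters
    ----------
    shifts : ndarray
        Raman-shift axis in cm^-1, strictly ascending.
    intensities : ndarray
        Non-negative intensity counts, same length as ``shifts``.
    label_code : int or None
        Integer class code (1..10 for the standard design), or None when
        the sample is unlabeled.
    concentration : float or None
        Glucose concentration in mmol/L, when known.
    sample_id : str
        Free-text identifier (usually the file stem).
    """

    shifts: np.ndarray
    intensities: np.ndarray
    label_code: int | None = None
    concentration: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise MalformedSpectrum("shifts and intensities must be 1-D")
        if self.shifts.shape != self.intensities.shape:
            raise MalformedSpectrum(
                f"length mismatch: {self.shifts.size} shifts vs "
                f"{self.intensities.size} intensities"
            )
        if self.shifts.size and np.any(np.diff(self.shifts) <= 0):
            raise MalformedSpectrum("shift axis must be strictly ascending")

    @property
    def n_points(self) -> int:
        return int(self.shifts.size)

    def copy(self, **replacements) -> "Spectrum":
        kwargs = dict(
            shifts=self.shifts.copy(),
            intensities=self.intensities.copy(),
            label_code=self.label_code,
            concentration=self.concentration,
            sample_id=self.sample_id,
        )
        kwargs.update(replacements)
        return Spectrum(**kwargs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.shifts, other.shifts)
            and np.array_equal(self.intensities, other.intensities)
            and self.label_code == other.label_code
            and self.sample_id == other.sample_id
        )


def _check_nonnegative(intensities: np.ndarray, context: str) -> None:
    # Zero counts are physically meaningful and accepted; strictly
    # negative raw intensities are rejected.
    if intensities.size and np.min(intensities) < 0:
        raise MalformedSpectrum(f"negative intensity in {context}")


@dataclass
class SpectraDataset:
    """An ordered collection of spectra sharing one shift axis."""

    spectra: list[Spectrum] = field(default_factory=list)
    label_map: Mapping[float, int] = field(
        default_factory=lambda: dict(TABLE1_LABEL_MAP)
    )

    def __post_init__(self) -> None:
        if self.spectra:
            axis = self.spectra[0].shifts
            for s in self.spectra[1:]:
                if not np.array_equal(s.shifts, axis):
                    raise AxisMismatch(
                        f"sample {s.sample_id!r} has a different shift axis"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def shifts(self) -> np.ndarray:
        if not self.spectra:
            raise EmptyDataset("dataset has no spectra")
        return self.spectra[0].shifts

    @property
    def n_points(self) -> int:
        return self.spectra[0].n_points if self.spectra else 0

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into a (n_samples, n_points) float matrix."""
        if not self.spectra:
            raise EmptyDataset("dataset has no spectra")
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        return np.array([s.label_code for s in self.spectra])

    def sorted_by_id(self) -> "SpectraDataset":
        return SpectraDataset(
            sorted(self.spectra, key=lambda s: s.sample_id),
            label_map=dict(self.label_map),
        )

    def manifest(self) -> list[dict]:
        return [
            {
                "sample_id": s.sample_id,
                "label_code": s.label_code,
                "concentration": s.concentration,
                "n_points": s.n_points,
            }
            for s in self.spectra
        ]


def parse_label_from_filename(path: str | Path) -> int:
    """Extract the integer label from the prefix before the first ``-``."""
    name = Path(path).name
    if "-" not in name:
        raise MissingLabel(f"no '-' separator in filename {name!r}")
    prefix = name.split("-", 1)[0]
    if not re.fullmatch(r"\d+", prefix):
        raise MissingLabel(f"non-integer label prefix {prefix!r} in {name!r}")
    return int(prefix)


def read_spectrum_csv(
    path: str | Path, *, require_label: bool = True, allow_negative: bool = False
) -> Spectrum:
    """Read one spectrum from a two-column CSV file.

    The file holds one ``raman_shift,intensity`` pair per row, optionally
    preceded by a single non-numeric header row (auto-detected and
    skipped). Rows are kept in ascending-shift order; a non-ascending axis,
    a non-numeric data row, or a negative intensity raises
    :class:`MalformedSpectrum`. The label is the filename prefix before the
    first ``-``; with ``require_label=False`` a missing label leaves
    ``label_code`` as None instead of raising :class:`MissingLabel`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment=None, skiprows=0)
    except Exception as exc:  # pragma: no cover - pandas-specific failures
        raise MalformedSpectrum(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise MalformedSpectrum(f"{path} does not have two columns")
    df = df.iloc[:, :2]
    # Auto-detect a single header row: skip it if non-numeric.
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:]
    if df.empty:
        raise MalformedSpectrum(f"{path} contains no data rows")
    try:
        values = df.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise MalformedSpectrum(f"non-numeric row in {path}") from exc
    if np.any(~np.isfinite(values)):
        raise MalformedSpectrum(f"non-finite value in {path}")
    shifts, intensities = values[:, 0], values[:, 1]
    # Baseline-corrected spectra may legitimately undershoot zero; raw
    # spectra may not.
    if not allow_negative:
        _check_nonnegative(intensities, str(path))
    try:
        label: int | None = parse_label_from_filename(path)
    except MissingLabel:
        if require_label:
            raise
        label = None
    return Spectrum(
        shifts=shifts,
        intensities=intensities,
        label_code=label,
        sample_id=path.stem,
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_spectrum_csv(
    spectrum: Spectrum, path: str | Path, *, header: bool = False
) -> Path:
    """Write a spectrum as a two-column CSV with fixed decimal formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "raman_shift_cm-1": spectrum.shifts,
            "intensity": spectrum.intensities,
        }
    )
    df.to_csv(path, index=False, header=header, float_format=_CSV_FLOAT_FMT)
    return path


def load_dataset(
    directory: str | Path,
    label_map: Mapping[float, int] | None = None,
    *,
    pattern: str = "*.csv",
) -> SpectraDataset:
    """Load every spectrum CSV in a directory into one dataset.

    Files are read in sorted filename order so the result is independent
    of directory enumeration order. Every file must share the first file's
    shift axis (:class:`AxisMismatch` otherwise); an empty directory raises
    :class:`EmptyDataset`. Label codes are checked against ``label_map``
    (concentration -> code; the standard ten-level design by default) and
    each spectrum is annotated with its concentration.
    """
    directory = Path(directory)
    label_map = dict(TABLE1_LABEL_MAP if label_map is None else label_map)
    files = sorted(directory.glob(pattern))
    if not files:
        raise EmptyDataset(f"no {pattern} files in {directory}")
    code_to_conc = {code: conc for conc, code in label_map.items()}
    spectra = []
    axis = None
    for f in files:
        s = read_spectrum_csv(f)
        if axis is None:
            axis = s.shifts
        elif not np.array_equal(s.shifts, axis):
            raise AxisMismatch(
                f"{f.name}: shift axis differs from {files[0].name}"
            )
        s.concentration = code_to_conc.get(s.label_code)
        spectra.append(s)
    return SpectraDataset(spectra, label_map=label_map)


def save_dataset(
    dataset: SpectraDataset,
    directory: str | Path,
    *,
    manifest: bool = True,
) -> list[Path]:
    """Write each spectrum as ``<label>-<sample_id>.csv`` plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in dataset:
        stem = s.sample_id or "sample"
        if s.label_code is not None and not stem.startswith(f"{s.label_code}-"):
            stem = f"{s.label_code}-{stem}"
        paths.append(write_spectrum_csv(s, directory / f"{stem}.csv"))
    if manifest:
        with open(directory / "manifest.json", "w") as fh:
            json.dump(dataset.manifest(), fh, indent=2)
    return paths


def dataset_from_arrays(
    shifts: np.ndarray,
    intensities: Iterable[np.ndarray],
    labels: Iterable[int | None],
    *,
    sample_ids: Iterable[str] | None = None,
    label_map: Mapping[float, int] | None = None,
) -> SpectraDataset:
    """Assemble a dataset from in-memory arrays sharing one axis."""
    intensities = list(intensities)
    labels = list(labels)
    ids = list(sample_ids) if sample_ids is not None else [
        f"sample{i}" for i in range(len(intensities))
    ]
    label_map = dict(TABLE1_LABEL_MAP if label_map is None else label_map)
    code_to_conc = {code: conc for conc, code in label_map.items()}
    spectra = [
        Spectrum(
            shifts=np.asarray(shifts, dtype=float),
            intensities=np.asarray(y, dtype=float),
            label_code=lab,
            concentration=code_to_conc.get(lab),
            sample_id=sid,
        )
        for y, lab, sid in zip(intensities, labels, ids)
    ]
    return SpectraDataset(spectra, label_map=label_map)
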