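"""Core spectral containers and wide-table I/O.

Absorbance spectra live on a shared wavenumber grid stored in *descending*
order (the spectroscopy plotting convention, 1800 -> 700 cm^-1).  All
downstream modules assume that convention; readers re-order ascending input
files on load.

The on-disk format is a wide CSV: first column ``wavenumber`` (cm^-1), one
column per measured spectrum named ``<sample_id>_<replicate_id>`` with the
*last* underscore as the separator.  Values are plain decimal-point floats
written at full precision so that a write/read round trip is value-exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectraMatrix",
    "SampleRecord",
    "read_spectra_table",
    "write_spectra_table",
    "read_metadata",
    "write_metadata",
    "align_to_grid",
    "restrict_range",
]

#: full range of the instrument in cm^-1; grids must stay inside it
INSTRUMENT_RANGE = (4000.0, 400.0)

_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly descending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("grid needs at least one wavenumber")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite wavenumbers")
        if not np.all(np.diff(values) < 0):
            raise ValueError("wavenumber grid must be strictly descending")
        hi, lo = INSTRUMENT_RANGE
        if values[0] > hi or values[-1] < lo:
            raise ValueError(
                f"grid {values[0]:.1f}-{values[-1]:.1f} cm^-1 outside the "
                f"instrument range {hi:.0f}-{lo:.0f} cm^-1"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    @property
    def spacing(self) -> float:
        """Nominal (median) step in cm^-1, returned as a positive number."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(-np.diff(self.values)))

    @property
    def is_uniform(self) -> bool:
        if len(self) < 2:
            return True
        steps = -np.diff(self.values)
        return bool(np.all(np.abs(steps - steps[0]) <= _UNIFORM_RTOL * abs(steps[0])))

    @property
    def span(self) -> tuple[float, float]:
        """(high, low) endpoints in cm^-1."""
        return float(self.values[0]), float(self.values[-1])

    def scaled(self) -> np.ndarray:
        """Wavenumbers affinely mapped onto [-1, 1] (conditioning helper)."""
        lo, hi = float(self.values.min()), float(self.values.max())
        return 2.0 * (self.values - lo) / (hi - lo) - 1.0

    def index_of(self, wavenumber: float, tol: float = 2.0) -> int:
        """Index of the grid point nearest ``wavenumber`` within ``tol`` cm^-1."""
        hi, lo = self.span
        if not (lo <= wavenumber <= hi):
            raise ValueError(
                f"{wavenumber} cm^-1 outside grid span {hi:.1f}-{lo:.1f} cm^-1"
            )
        idx = int(np.argmin(np.abs(self.values - wavenumber)))
        if abs(self.values[idx] - wavenumber) > tol:
            raise ValueError(
                f"no grid point within {tol} cm^-1 of {wavenumber} cm^-1"
            )
        return idx

    @classmethod
    def regular(cls, high: float, low: float, spacing: float) -> "WavenumberGrid":
        n = int(round((high - low) / spacing)) + 1
        return cls(np.linspace(high, low, n))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum with its sample/replicate identity."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_id: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", ab)
        if ab.shape != (len(self.grid),):
            raise ValueError("absorbance length must equal grid length")
        if not np.all(np.isfinite(ab)):
            raise ValueError(f"non-finite absorbance in spectrum {self.sample_id!r}")


@dataclass
class SpectraMatrix:
    """n_spectra x P matrix of absorbances sharing one wavenumber grid."""

    X: np.ndarray
    grid: WavenumberGrid
    sample_ids: list[str]
    replicate_ids: list[int]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("column count must equal grid length")
        if not (len(self.sample_ids) == len(self.replicate_ids) == self.X.shape[0]):
            raise ValueError("row metadata length must equal row count")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{s}_{r}" for s, r in zip(self.sample_ids, self.replicate_ids)]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.X[i], self.sample_ids[i], self.replicate_ids[i])

    def rows(self) -> Iterable[Spectrum]:
        for i in range(self.n_spectra):
            yield self.row(i)

    def select_rows(self, indices: Sequence[int]) -> "SpectraMatrix":
        idx = list(indices)
        return SpectraMatrix(
            self.X[idx],
            self.grid,
            [self.sample_ids[i] for i in idx],
            [self.replicate_ids[i] for i in idx],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "SpectraMatrix":
        """All replicate rows of the given samples, in the requested sample order."""
        wanted = list(sample_ids)
        missing = set(wanted) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        idx = [i for s in wanted for i, sid in enumerate(self.sample_ids) if sid == s]
        return self.select_rows(idx)

    def unique_samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(s)
        return list(seen)

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.X.copy(), self.grid, list(self.sample_ids), list(self.replicate_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X.T, columns=self.column_names)
        df.insert(0, "wavenumber", self.grid.values)
        return df


@dataclass
class SampleRecord:
    """Per-case metadata row."""

    sample_id: str
    case_id: str = ""
    cohort: str = "known"  # known | unknown
    pmi_hours: float | None = None
    pmi_provenance: str = "documented"  # documented | scene_estimate
    age: float | None = None
    sex: str = ""
    cause_of_death: str = ""
    storage_flag: str = "normal"  # normal | refrigerated_prolonged
    confounder_flag: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in ("known", "unknown"):
            raise ValueError(f"cohort must be known|unknown, got {self.cohort!r}")
        if self.cohort == "known":
            if self.pmi_hours is None:
                raise ValueError(f"known-cohort sample {self.sample_id} lacks pmi_hours")
            if self.pmi_provenance != "documented":
                raise ValueError(
                    f"known-cohort sample {self.sample_id} must have documented PMI"
                )
        if self.pmi_hours is not None and not self.pmi_hours > 0:
            raise ValueError(f"pmi_hours must be > 0, got {self.pmi_hours}")


_META_COLUMNS = [
    "sample_id",
    "case_id",
    "cohort",
    "pmi_hours",
    "pmi_provenance",
    "age",
    "sex",
    "cause_of_death",
    "storage_flag",
    "confounder_flag",
]


def _split_column_name(name: str) -> tuple[str, int]:
    if "_" not in name:
        raise ValueError(
            f"spectrum column {name!r} is not of the form <sample_id>_<replicate_id>"
        )
    sid, rep = name.rsplit("_", 1)
    try:
        return sid, int(rep)
    except ValueError as exc:
        raise ValueError(
            f"replicate suffix of column {name!r} is not an integer"
        ) from exc


def read_spectra_table(path: str | Path) -> SpectraMatrix:
    """Read a wide spectral CSV (wavenumber + one column per spectrum)."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    names = [h.strip() for h in header[1:]]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate spectrum columns in {path.name}: {sorted(dupes)}")

    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} in column {col!r}, line {row} of {path.name}"
            )

    wn = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(wn)[::-1]
    wn = wn[order]
    if np.any(np.diff(wn) >= 0):
        raise ValueError(f"duplicate wavenumbers in {path.name}")
    grid = WavenumberGrid(wn)

    sample_ids, replicate_ids = [], []
    for name in names:
        sid, rep = _split_column_name(name)
        sample_ids.append(sid)
        replicate_ids.append(rep)
    X = df.iloc[:, 1:].to_numpy(dtype=float)[order].T
    return SpectraMatrix(X, grid, sample_ids, replicate_ids)


def write_spectra_table(m: SpectraMatrix, path: str | Path) -> None:
    """Write the wide CSV described above; floats use repr precision (round-trip exact)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavenumber"] + m.column_names)
        for j in range(m.n_points):
            writer.writerow([repr(float(m.grid.values[j]))] + [repr(float(v)) for v in m.X[:, j]])


def read_metadata(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                case_id=row.get("case_id", ""),
                cohort=row.get("cohort", "known"),
                pmi_hours=float(row["pmi_hours"]) if row.get("pmi_hours", "") != "" else None,
                pmi_provenance=row.get("pmi_provenance", "documented") or "documented",
                age=float(row["age"]) if row.get("age", "") != "" else None,
                sex=row.get("sex", ""),
                cause_of_death=row.get("cause_of_death", ""),
                storage_flag=row.get("storage_flag", "normal") or "normal",
                confounder_flag=row.get("confounder_flag", ""),
            )
        )
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "case_id": r.case_id,
                "cohort": r.cohort,
                "pmi_hours": "" if r.pmi_hours is None else repr(float(r.pmi_hours)),
                "pmi_provenance": r.pmi_provenance,
                "age": "" if r.age is None else repr(float(r.age)),
                "sex": r.sex,
                "cause_of_death": r.cause_of_death,
                "storage_flag": r.storage_flag,
                "confounder_flag": r.confounder_flag,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def align_to_grid(m: SpectraMatrix, target: WavenumberGrid) -> SpectraMatrix:
    """Linearly interpolate every spectrum onto ``target`` (no extrapolation)."""
    src_hi, src_lo = m.grid.span
    tgt_hi, tgt_lo = target.span
    if tgt_hi > src_hi or tgt_lo < src_lo:
        raise ValueError(
            f"target grid {tgt_hi:.1f}-{tgt_lo:.1f} extends beyond source "
            f"{src_hi:.1f}-{src_lo:.1f} cm^-1 (extrapolation not supported)"
        )
    # np.interp wants ascending abscissae
    xp = m.grid.values[::-1]
    xq = target.values[::-1]
    X_new = np.empty((m.n_spectra, len(target)))
    for i in range(m.n_spectra):
        X_new[i] = np.interp(xq, xp, m.X[i, ::-1])[::-1]
    return SpectraMatrix(X_new, target, list(m.sample_ids), list(m.replicate_ids))


def restrict_range(m: SpectraMatrix, high: float, low: float) -> SpectraMatrix:
    """Keep grid points with low <= wavenumber <= high (order preserved)."""
    if high < low:
        raise ValueError(f"need high >= low, got {high} < {low}")
    mask = (m.grid.values >= low) & (m.grid.values <= high)
    if not mask.any():
        raise ValueError(f"no grid points in {high}-{low} cm^-1")
    return SpectraMatrix(
        m.X[:, mask].copy(), WavenumberGrid(m.grid.values[mask]), list(m.sample_ids), list(m.replicate_ids)
    )
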