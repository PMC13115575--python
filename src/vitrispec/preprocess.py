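"""EMSC -> Savitzky-Golay second derivative -> mean-centering pipeline.

The pipeline enforces a strict fit/apply separation: every parameter (EMSC
reference spectrum, centering mean) is estimated from a designated fitting
set and then applied unchanged to any other spectra, so held-out data can
never leak into the preprocessing.

EMSC decomposes each spectrum ``s`` by ordinary least squares into

    s ~ a * 1 + c * vt + b * reference

where ``vt`` is the wavenumber axis affinely scaled to [-1, 1] (raw cm^-1
values around 10^3 would make the normal equations needlessly
ill-conditioned).  The corrected spectrum is ``(s - a - c*vt) / b``; the
least-squares residual -- the chemical information -- is preserved inside it.
A first-order polynomial baseline is the default, matching wavelength-
dependent scattering in ATR work.

Second derivatives use a 15-point, third-order Savitzky-Golay filter and are
taken with respect to wavenumber (divided by the grid spacing squared), so
results are independent of the digitized point spacing.  Polynomial-fit edge
handling keeps the dimensionality constant across stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraMatrix, WavenumberGrid

__all__ = [
    "EMSCModel",
    "EMSCParams",
    "PreprocessPipelineModel",
    "fit_emsc",
    "apply_emsc",
    "second_derivative",
    "fit_center",
    "fit_preprocess",
    "apply_preprocess",
    "offset_correct",
    "average_replicates",
]

B_MIN = 1e-6  # below this |b| the multiplicative correction is meaningless


@dataclass(frozen=True)
class EMSCParams:
    """Per-spectrum correction coefficients."""

    a: float  # additive offset, a.u.
    c: float  # baseline tilt per unit scaled wavenumber, a.u.
    b: float  # multiplicative scale, dimensionless


@dataclass
class EMSCModel:
    """Fitted EMSC basis: polynomial baseline columns plus a reference spectrum."""

    reference: np.ndarray
    grid: WavenumberGrid
    poly_order: int = 1

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (len(self.grid),):
            raise ValueError("reference length must equal grid length")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")

    @property
    def basis(self) -> np.ndarray:
        """Design matrix columns: [1, vt, vt^2, ..., reference]."""
        vt = self.grid.scaled()
        cols = [vt**k for k in range(self.poly_order + 1)]
        cols.append(self.reference)
        return np.column_stack(cols)


def fit_emsc(fitting_set: SpectraMatrix, poly_order: int = 1) -> EMSCModel:
    """Reference = arithmetic mean spectrum of the fitting set."""
    if fitting_set.n_spectra < 2:
        warnings.warn(
            "EMSC reference fitted on a single spectrum (degenerate reference)",
            stacklevel=2,
        )
    reference = fitting_set.X.mean(axis=0)
    return EMSCModel(reference=reference, grid=fitting_set.grid, poly_order=poly_order)


def apply_emsc(
    model: EMSCModel, m: SpectraMatrix
) -> tuple[SpectraMatrix, list[EMSCParams]]:
    """Least-squares fit each spectrum to the EMSC basis and correct it."""
    if m.grid != model.grid:
        raise ValueError("spectra grid does not match the EMSC model grid")
    basis = model.basis
    # one solve for all spectra: coef shape (n_basis, n_spectra)
    coef, *_ = np.linalg.lstsq(basis, m.X.T, rcond=None)
    baseline_part = basis[:, :-1] @ coef[:-1]  # (P, n)
    b = coef[-1]
    params = []
    corrected = np.empty_like(m.X)
    for i in range(m.n_spectra):
        if abs(b[i]) <= B_MIN:
            raise ValueError(
                f"EMSC scale coefficient ~0 for spectrum "
                f"{m.sample_ids[i]}_{m.replicate_ids[i]} (|b| <= {B_MIN})"
            )
        corrected[i] = (m.X[i] - baseline_part[:, i]) / b[i]
        c = float(coef[1, i]) if model.poly_order >= 1 else 0.0
        params.append(EMSCParams(a=float(coef[0, i]), c=c, b=float(b[i])))
    return (
        SpectraMatrix(corrected, m.grid, list(m.sample_ids), list(m.replicate_ids)),
        params,
    )


def second_derivative(
    m: SpectraMatrix, window: int = 15, polyorder: int = 3
) -> SpectraMatrix:
    """Savitzky-Golay second derivative w.r.t. wavenumber (units a.u. per cm^-2)."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if m.n_points < window:
        raise ValueError(f"need at least {window} grid points, have {m.n_points}")
    if not m.grid.is_uniform:
        raise ValueError(
            "grid spacing is not uniform; run align_to_grid onto a regular grid first"
        )
    d2 = savgol_filter(
        m.X, window_length=window, polyorder=polyorder, deriv=2,
        delta=m.grid.spacing, axis=1, mode="interp",
    )
    return SpectraMatrix(d2, m.grid, list(m.sample_ids), list(m.replicate_ids))


def fit_center(fitting_set: SpectraMatrix) -> np.ndarray:
    """Columnwise mean of the fitting set (the centering vector)."""
    if fitting_set.n_spectra < 1:
        raise ValueError("fitting set is empty")
    return fitting_set.X.mean(axis=0)


@dataclass
class PreprocessPipelineModel:
    """Frozen parameters of the three-step pipeline."""

    emsc: EMSCModel
    sg_window: int = 15
    sg_polyorder: int = 3
    sg_deriv: int = 2
    center_mean: np.ndarray = field(default_factory=lambda: np.array([]))
    fitted_on: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        self.center_mean = np.asarray(self.center_mean, dtype=float)
        if self.center_mean.size and self.center_mean.shape != (len(self.emsc.grid),):
            raise ValueError("center_mean length must equal grid length")

    def to_dict(self) -> dict:
        return {
            "grid": self.emsc.grid.values.tolist(),
            "reference": self.emsc.reference.tolist(),
            "poly_order": self.emsc.poly_order,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
            "center_mean": self.center_mean.tolist(),
            "fitted_on": list(self.fitted_on),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessPipelineModel":
        grid = WavenumberGrid(np.array(d["grid"]))
        emsc = EMSCModel(np.array(d["reference"]), grid, d["poly_order"])
        return cls(
            emsc=emsc,
            sg_window=d["sg_window"],
            sg_polyorder=d["sg_polyorder"],
            sg_deriv=d["sg_deriv"],
            center_mean=np.array(d["center_mean"]),
            fitted_on=list(d["fitted_on"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessPipelineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_preprocess(
    fitting_set: SpectraMatrix,
    poly_order: int = 1,
    sg_window: int = 15,
    sg_polyorder: int = 3,
) -> PreprocessPipelineModel:
    """Fit EMSC reference and centering mean on the fitting set only."""
    emsc = fit_emsc(fitting_set, poly_order=poly_order)
    corrected, _ = apply_emsc(emsc, fitting_set)
    deriv = second_derivative(corrected, sg_window, sg_polyorder)
    center_mean = fit_center(deriv)
    return PreprocessPipelineModel(
        emsc=emsc,
        sg_window=sg_window,
        sg_polyorder=sg_polyorder,
        center_mean=center_mean,
        fitted_on=sorted(set(fitting_set.sample_ids)),
    )


def apply_preprocess(model: PreprocessPipelineModel, m: SpectraMatrix) -> SpectraMatrix:
    """center(second_derivative(emsc(m))) using only the fitted parameters."""
    corrected, _ = apply_emsc(model.emsc, m)
    deriv = second_derivative(corrected, model.sg_window, model.sg_polyorder)
    centered = deriv.X - model.center_mean
    return SpectraMatrix(centered, m.grid, list(m.sample_ids), list(m.replicate_ids))


def offset_correct(m: SpectraMatrix, anchor: float = 1800.0) -> SpectraMatrix:
    """Subtract each spectrum's absorbance at the anchor wavenumber."""
    idx = m.grid.index_of(anchor, tol=2.0)
    shifted = m.X - m.X[:, idx][:, None]
    return SpectraMatrix(shifted, m.grid, list(m.sample_ids), list(m.replicate_ids))


def average_replicates(m: SpectraMatrix) -> SpectraMatrix:
    """One arithmetic-mean spectrum per sample, ordered by first appearance."""
    order = m.unique_samples()
    rows = []
    for sid in order:
        idx = [i for i, s in enumerate(m.sample_ids) if s == sid]
        rows.append(m.X[idx].mean(axis=0))
    return SpectraMatrix(np.array(rows), m.grid, order, [0] * len(order))
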