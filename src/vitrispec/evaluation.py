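"""Validation protocols, uncertainty quantification and method comparison.

All cross-validation here refits the *entire* pipeline inside every fold:
the EMSC reference, the centering mean and the regression model are
re-estimated from the training samples alone, so a held-out spectrum can
never influence its own preprocessing (the leakage contract).

Prediction uncertainty follows a two-tier scheme: percentile intervals built
from the 50th/75th/90th percentiles of absolute leave-one-out errors of the
final model, and a 95% half-width from a non-parametric bootstrap (1000
resamples) of the cross-validated residuals.  An external PMI estimate is
"consistent" when it falls inside the tightest percentile interval that
contains it and "discrepant" outside the 90% interval; a gap exceeding the
95% half-width is flagged as a large discrepancy (biochemical age decoupled
from chronological time, e.g. prolonged refrigeration).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import (
    HuberRegressor,
    LinearRegression,
    RANSACRegressor,
    TheilSenRegressor,
)

from .chemometrics import PLSModel, fit_pls, predict_pls
from .preprocess import apply_preprocess, average_replicates, fit_preprocess
from .spectra import SampleRecord, SpectraMatrix

__all__ = [
    "SplitProtocol",
    "CVReport",
    "DiagnosticsReport",
    "ErrorPercentiles",
    "FittedLinearMethod",
    "comparison_variants",
    "PredictionRecord",
    "ReliabilityTier",
    "MethodComparison",
    "SpectralPMIRegressor",
    "metrics",
    "loocv",
    "loocv_pipeline",
    "select_components",
    "repeated_splits",
    "residual_diagnostics",
    "error_percentiles",
    "bootstrap_prediction_interval",
    "build_prediction_record",
    "assign_reliability",
    "fit_linear_method",
    "compare_methods",
]

REGRESSION_METHODS = ("PLS", "OLS", "Huber", "TheilSen", "RANSAC")
COMPARISON_VARIANTS = ("full", "excl_confounders", "excl_pls_problematic", "forensic_lt72")


@dataclass(frozen=True)
class SplitProtocol:
    n_splits: int = 5
    train_fraction: float = 0.75
    seed: int = 0
    component_grid: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if min(self.component_grid) < 1:
            raise ValueError("component grid must start at >= 1")


@dataclass
class CVReport:
    sample_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    rmse: float
    mae: float
    r2: float
    chosen_A: int | None = None
    failures: list[str] = field(default_factory=list)

    @property
    def residuals(self) -> np.ndarray:
        return self.y_true - self.y_pred

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.residuals)


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(rmse, mae, r2); r2 uses SST about mean(y_true)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length vectors (n >= 2)")
    err = y_true - y_pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    r2 = 1.0 - float(np.sum(err**2)) / sst
    return rmse, mae, r2


# ---------------------------------------------------------------------------
# composite estimator: preprocessing + regression, fitted as one unit
# ---------------------------------------------------------------------------


class SpectralPMIRegressor:
    """Full-pipeline PMI regressor on replicate-level spectra.

    ``fit`` derives the EMSC reference and centering mean from the training
    replicates, averages preprocessed replicates into one row per sample and
    fits the requested regression method (``PLS`` with ``n_components``
    latent variables, or one of OLS / Huber / TheilSen / RANSAC on the same
    sample-level matrix).
    """

    def __init__(self, method: str = "PLS", n_components: int = 2, seed: int = 0):
        if method not in REGRESSION_METHODS:
            raise ValueError(f"method must be one of {REGRESSION_METHODS}")
        self.method = method
        self.n_components = n_components
        self.seed = seed
        self.flags: dict[str, object] = {}

    def _sample_matrix(self, m: SpectraMatrix) -> tuple[np.ndarray, list[str]]:
        z = apply_preprocess(self.preprocess_, m)
        s = average_replicates(z)
        return s.X, s.sample_ids

    def fit(self, m: SpectraMatrix, y_by_sample: Mapping[str, float]) -> "SpectralPMIRegressor":
        self.preprocess_ = fit_preprocess(m)
        X, sample_order = self._sample_matrix(m)
        missing = [s for s in sample_order if s not in y_by_sample]
        if missing:
            raise KeyError(f"no PMI for samples {missing}")
        y = np.array([y_by_sample[s] for s in sample_order], dtype=float)
        if self.method == "PLS":
            self.model_ = fit_pls(X, y, self.n_components, training_ids=sample_order)
        else:
            fitted = fit_linear_method(self.method, X, y, seed=self.seed)
            self.model_ = fitted
            self.flags = fitted.flags
        self.training_X_ = X
        self.training_y_ = y
        self.training_samples_ = sample_order
        return self

    def predict(self, m: SpectraMatrix) -> pd.Series:
        X, sample_order = self._sample_matrix(m)
        if isinstance(self.model_, PLSModel):
            pred = predict_pls(self.model_, X)
        else:
            pred = self.model_.predict(X)
        return pd.Series(pred, index=sample_order, name="pmi_pred")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _unit_count(X) -> int:
    if isinstance(X, SpectraMatrix):
        return len(X.unique_samples())
    return np.asarray(X).shape[0]


def _take(X, idx: Sequence[int]):
    if isinstance(X, SpectraMatrix):
        units = X.unique_samples()
        return X.select_samples([units[i] for i in idx])
    return np.asarray(X)[list(idx)]


def loocv(
    X,
    y: np.ndarray,
    fit_and_predict: Callable,
) -> CVReport:
    """Leave-one-out CV over sample units.

    ``X`` is either a plain (n, P) array or a replicate-level SpectraMatrix
    whose units are its unique samples.  ``fit_and_predict(X_train, y_train,
    X_test) -> array`` must refit everything it needs from the training
    portion; a failing fold is recorded and excluded from the metrics.
    """
    y = np.asarray(y, dtype=float)
    n = _unit_count(X)
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    if y.shape != (n,):
        raise ValueError("y length must equal the number of sample units")
    ids = X.unique_samples() if isinstance(X, SpectraMatrix) else [str(i) for i in range(n)]

    preds = np.full(n, np.nan)
    failures = []
    for i in range(n):
        train = [j for j in range(n) if j != i]
        try:
            out = fit_and_predict(_take(X, train), y[train], _take(X, [i]))
            preds[i] = float(np.asarray(out).ravel()[0])
        except Exception as exc:  # noqa: BLE001 - per-fold failures are reported
            failures.append(f"fold {ids[i]}: {exc}")
    ok = ~np.isnan(preds)
    if failures:
        warnings.warn(f"{len(failures)} LOOCV folds failed; metrics over the rest", stacklevel=2)
    if ok.sum() < 2:
        raise RuntimeError("LOOCV failed on nearly all folds: " + "; ".join(failures))
    rmse, mae, r2 = metrics(y[ok], preds[ok])
    return CVReport(
        sample_ids=[ids[i] for i in range(n) if ok[i]],
        y_true=y[ok], y_pred=preds[ok], rmse=rmse, mae=mae, r2=r2, failures=failures,
    )


def loocv_pipeline(
    m: SpectraMatrix,
    y_by_sample: Mapping[str, float],
    make_model: Callable[[], SpectralPMIRegressor],
) -> CVReport:
    """LOOCV with full per-fold pipeline refit on replicate-level spectra."""
    samples = [s for s in m.unique_samples() if s in y_by_sample]
    sub = m.select_samples(samples)
    y = np.array([y_by_sample[s] for s in samples], dtype=float)

    def fold(train_m, y_train, test_m):
        ids = train_m.unique_samples()
        model = make_model().fit(train_m, dict(zip(ids, y_train)))
        return model.predict(test_m).to_numpy()

    return loocv(sub, y, fold)


def select_components(
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: Sequence[int] = tuple(range(1, 11)),
) -> tuple[int, pd.Series]:
    """Pick the component count minimizing LOOCV RMSECV (ties -> smallest A).

    Returns (A_star, RMSECV per candidate).  The grid is capped at
    n_train - 1 components.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = len(y_train)
    grid = sorted({a for a in grid if 1 <= a <= n - 2})
    if not grid:
        raise ValueError("component grid empty after capping at n_train - 1")
    rmsecv = {}
    for a in grid:
        def fold(Xtr, ytr, Xte, a=a):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return predict_pls(fit_pls(Xtr, ytr, a), Xte)
        rmsecv[a] = loocv(X_train, y_train, fold).rmse
    series = pd.Series(rmsecv, name="rmsecv")
    best = min(rmsecv, key=lambda a: (rmsecv[a], a))
    return best, series


def repeated_splits(
    m: SpectraMatrix,
    y_by_sample: Mapping[str, float],
    protocol: SplitProtocol = SplitProtocol(),
) -> pd.DataFrame:
    """Random train/test splits with per-split component selection.

    Per split: preprocessing and the component choice come from the training
    samples only; the test set is scored exactly once.  Returns one row per
    split (chosen_A, rmse, mae, r2) plus a trailing mean/sd summary accessor
    via ``df.attrs['summary']`` and the modal A in ``df.attrs['modal_A']``.
    """
    samples = [s for s in m.unique_samples() if s in y_by_sample]
    n = len(samples)
    n_train = int(round(protocol.train_fraction * n))
    if n_train < max(protocol.component_grid) + 2:
        warnings.warn("training sets are small; component grid will be capped", stacklevel=2)
    rng = np.random.default_rng(protocol.seed)

    rows = []
    for split in range(protocol.n_splits):
        perm = rng.permutation(n)
        train_ids = [samples[i] for i in perm[:n_train]]
        test_ids = [samples[i] for i in perm[n_train:]]

        train_m = m.select_samples(train_ids)
        pre = fit_preprocess(train_m)
        s_train = average_replicates(apply_preprocess(pre, train_m))
        y_train = np.array([y_by_sample[s] for s in s_train.sample_ids])
        a_star, _ = select_components(s_train.X, y_train, protocol.component_grid)

        model = SpectralPMIRegressor("PLS", n_components=a_star).fit(
            train_m, {s: y_by_sample[s] for s in train_ids}
        )
        pred = model.predict(m.select_samples(test_ids))
        y_test = np.array([y_by_sample[s] for s in pred.index])
        rmse, mae, r2 = metrics(y_test, pred.to_numpy())
        rows.append(
            {"split": split, "chosen_A": a_star, "n_train": n_train,
             "n_test": n - n_train, "rmse": rmse, "mae": mae, "r2": r2}
        )

    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "rmse_mean": df.rmse.mean(), "rmse_sd": df.rmse.std(ddof=1),
        "mae_mean": df.mae.mean(), "mae_sd": df.mae.std(ddof=1),
        "r2_mean": df.r2.mean(), "r2_sd": df.r2.std(ddof=1),
    }
    df.attrs["modal_A"] = Counter(df.chosen_A).most_common(1)[0][0]
    return df


# ---------------------------------------------------------------------------
# residual diagnostics and intervals
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    shapiro_p: float | None
    levene_p: float | None
    notes: list[str] = field(default_factory=list)


def residual_diagnostics(
    residuals: np.ndarray,
    predicted: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> DiagnosticsReport:
    """Shapiro-Wilk normality and Brown-Forsythe (median-centered Levene)
    homoscedasticity of residuals.

    Default grouping splits folds at the median predicted value.
    """
    residuals = np.asarray(residuals, dtype=float)
    notes = []
    if residuals.size >= 8:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
    else:
        shapiro_p = None
        notes.append("Shapiro-Wilk unavailable (n < 8)")
    if groups is None:
        if predicted is None:
            levene_p = None
            notes.append("Levene unavailable (no grouping)")
            return DiagnosticsReport(shapiro_p, levene_p, notes)
        predicted = np.asarray(predicted, dtype=float)
        groups = predicted > np.median(predicted)
    parts = [residuals[groups == g] for g in np.unique(groups)]
    if len(parts) < 2 or min(len(p) for p in parts) < 2:
        levene_p = None
        notes.append("Levene unavailable (fewer than 2 usable groups)")
    else:
        levene_p = float(stats.levene(*parts, center="median").pvalue)
    return DiagnosticsReport(shapiro_p, levene_p, notes)


@dataclass(frozen=True)
class ErrorPercentiles:
    q50: float
    q75: float
    q90: float

    def __post_init__(self) -> None:
        if not 0 <= self.q50 <= self.q75 <= self.q90:
            raise ValueError("percentiles must be ordered 0 <= q50 <= q75 <= q90")


def error_percentiles(abs_errors: np.ndarray) -> ErrorPercentiles:
    """Linear-interpolation percentiles of absolute cross-validated errors."""
    abs_errors = np.asarray(abs_errors, dtype=float)
    if abs_errors.size < 1:
        raise ValueError("need at least one error")
    q50, q75, q90 = np.percentile(abs_errors, [50, 75, 90])
    return ErrorPercentiles(float(q50), float(q75), float(q90))


def bootstrap_prediction_interval(
    cv_residuals: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    aggregation: str = "mean",
) -> float:
    """Symmetric prediction half-width from bootstrapped CV residuals.

    Each bootstrap replicate resamples the residual vector with replacement
    and takes the ``level`` percentile of absolute residuals; the half-width
    is the mean over replicates (``aggregation='median'`` or
    ``'percentile'``, the 95th percentile of replicates, are available as
    more conservative summaries).
    """
    res = np.asarray(cv_residuals, dtype=float)
    if res.size < 5:
        raise ValueError("need at least 5 residuals")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, res.size, size=(n_boot, res.size))
    per_rep = np.percentile(np.abs(res[idx]), 100 * level, axis=1)
    if aggregation == "mean":
        return float(per_rep.mean())
    if aggregation == "median":
        return float(np.median(per_rep))
    if aggregation == "percentile":
        return float(np.percentile(per_rep, 95))
    raise ValueError(f"unknown aggregation {aggregation!r}")


# ---------------------------------------------------------------------------
# reporting rules
# ---------------------------------------------------------------------------


@dataclass
class PredictionRecord:
    sample_id: str
    y_hat: float
    interval_50: tuple[float, float]
    interval_75: tuple[float, float]
    interval_90: tuple[float, float]
    interval_95_halfwidth: float
    external_estimate: float | None = None
    agreement: str = "not_evaluable"


def build_prediction_record(
    sample_id: str,
    y_hat: float,
    percentiles: ErrorPercentiles,
    halfwidth95: float,
    estimate: float | None = None,
) -> PredictionRecord:
    """Percentile intervals around the prediction plus the consistency call.

    Agreement is the tightest percentile interval containing the external
    estimate; outside the 90% interval the call is ``discrepant``, escalated
    to ``large_discrepancy`` when the gap also exceeds the 95% bootstrap
    half-width.
    """
    intervals = {
        50: (y_hat - percentiles.q50, y_hat + percentiles.q50),
        75: (y_hat - percentiles.q75, y_hat + percentiles.q75),
        90: (y_hat - percentiles.q90, y_hat + percentiles.q90),
    }
    if estimate is None:
        agreement = "not_evaluable"
    else:
        gap = abs(y_hat - estimate)
        if gap <= percentiles.q50:
            agreement = "consistent_50"
        elif gap <= percentiles.q75:
            agreement = "consistent_75"
        elif gap <= percentiles.q90:
            agreement = "consistent_90"
        elif gap > halfwidth95:
            agreement = "large_discrepancy"
        else:
            agreement = "discrepant"
    return PredictionRecord(
        sample_id=sample_id,
        y_hat=y_hat,
        interval_50=intervals[50],
        interval_75=intervals[75],
        interval_90=intervals[90],
        interval_95_halfwidth=halfwidth95,
        external_estimate=estimate,
        agreement=agreement,
    )


@dataclass(frozen=True)
class ReliabilityTier:
    sample_id: str
    abs_error: float
    tier: str  # reliable | borderline | problematic


def assign_reliability(
    abs_errors: Mapping[str, float] | pd.Series, rmse: float
) -> list[ReliabilityTier]:
    """Tier thresholds at [rmse, 2*rmse]; boundary values are borderline."""
    if not rmse > 0:
        raise ValueError("rmse must be > 0")
    items = abs_errors.items() if hasattr(abs_errors, "items") else abs_errors
    tiers = []
    for sid, err in items:
        if err < rmse:
            tier = "reliable"
        elif err <= 2 * rmse:
            tier = "borderline"
        else:
            tier = "problematic"
        tiers.append(ReliabilityTier(sample_id=str(sid), abs_error=float(err), tier=tier))
    return tiers


# ---------------------------------------------------------------------------
# linear regression methods for the robustness comparison
# ---------------------------------------------------------------------------


class FittedLinearMethod:
    """Thin wrapper around a fitted sklearn regressor with provenance flags."""

    def __init__(self, name: str, estimator, flags: dict | None = None):
        self.name = name
        self.estimator = estimator
        self.flags = flags or {}

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.atleast_2d(X)), dtype=float)


def fit_linear_method(
    name: str, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> FittedLinearMethod:
    """Fit OLS / Huber / TheilSen / RANSAC on a (possibly P >= n) matrix.

    TheilSen's median-of-slopes construction is undefined when the predictor
    dimension reaches the sample count; in that regime the fit falls back to
    the minimum-norm OLS solution and sets ``flags['theilsen_ols_fallback']``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    flags: dict[str, object] = {}

    if name == "OLS":
        est = LinearRegression().fit(X, y)
    elif name == "Huber":
        est = HuberRegressor(max_iter=2000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            est.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            flags["huber_converged"] = False
    elif name == "TheilSen":
        if p >= n:
            est = LinearRegression().fit(X, y)
            flags["theilsen_ols_fallback"] = True
        else:
            est = TheilSenRegressor(random_state=seed).fit(X, y)
    elif name == "RANSAC":
        mad = float(np.median(np.abs(y - np.median(y))))
        est = RANSACRegressor(
            estimator=LinearRegression(),
            min_samples=3,
            residual_threshold=max(mad, 1e-8),
            random_state=seed,
        ).fit(X, y)
        flags["ransac_inlier_mask"] = est.inlier_mask_.tolist()
    else:
        raise ValueError(f"unknown method {name!r}")
    return FittedLinearMethod(name, est, flags)


@dataclass
class MethodComparison:
    results: pd.DataFrame  # method x variant -> rmse, r2, mae, n
    variant_samples: dict[str, list[str]]


def comparison_variants(
    meta: Sequence[SampleRecord],
    pls_problematic: Sequence[str] = (),
    pmi_cutoff: float = 72.0,
) -> dict[str, list[str]]:
    """Variant membership from metadata: confounder flags and the PMI filter."""
    known = [r for r in meta if r.cohort == "known" and r.pmi_hours is not None]
    full = [r.sample_id for r in known]
    excl_conf = [r.sample_id for r in known if not r.confounder_flag]
    excl_pls = [s for s in full if s not in set(pls_problematic)]
    lt = [r.sample_id for r in known if r.pmi_hours < pmi_cutoff]
    return {
        "full": full,
        "excl_confounders": excl_conf,
        "excl_pls_problematic": excl_pls,
        "forensic_lt72": lt,
    }


def compare_methods(
    m: SpectraMatrix,
    meta: Sequence[SampleRecord],
    methods: Sequence[str] = REGRESSION_METHODS,
    variants: Mapping[str, Sequence[str]] | None = None,
    n_components: int = 2,
    seed: int = 0,
) -> MethodComparison:
    """LOOCV metrics for every method on every dataset variant.

    When ``variants`` is not given they are derived from the metadata: the
    full known cohort, the cohort without flagged clinical confounders, the
    cohort without samples the PLS model itself marks problematic (LOOCV
    error beyond twice the RMSE), and the forensic PMI < 72 h subset.
    """
    y_by_sample = {
        r.sample_id: float(r.pmi_hours)
        for r in meta
        if r.cohort == "known" and r.pmi_hours is not None
    }
    if variants is None:
        base = loocv_pipeline(
            m, y_by_sample, lambda: SpectralPMIRegressor("PLS", n_components, seed)
        )
        tiers = assign_reliability(
            dict(zip(base.sample_ids, base.abs_errors)), base.rmse
        )
        problematic = [t.sample_id for t in tiers if t.tier == "problematic"]
        variants = comparison_variants(meta, pls_problematic=problematic)

    rows = []
    variant_samples = {}
    for vname, sample_list in variants.items():
        sample_list = list(sample_list)
        if len(sample_list) < 5:
            raise ValueError(f"variant {vname!r} has n={len(sample_list)} < 5; refused")
        variant_samples[vname] = sample_list
        sub = m.select_samples(sample_list)
        y_sub = {s: y_by_sample[s] for s in sample_list}
        for method in methods:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = loocv_pipeline(
                    sub, y_sub,
                    lambda: SpectralPMIRegressor(method, n_components, seed),
                )
            rows.append(
                {"method": method, "variant": vname, "n": len(sample_list),
                 "rmse": rep.rmse, "r2": rep.r2, "mae": rep.mae}
            )
    return MethodComparison(results=pd.DataFrame(rows), variant_samples=variant_samples)
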