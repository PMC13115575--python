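"""End-to-end orchestration: one config in, a bundle of report tables out.

The run covers the whole analysis: (optional) cohort simulation, preprocessing
fitted on the known cohort, diagnostic-peak statistics, PCA, PLS calibration
with LOOCV and repeated-split validation, percentile/bootstrap prediction
intervals for the query cohort, binary triage, and the multi-method
robustness comparison.  Every random stage takes its seed from one master
seed via named substreams, so a run is fully reproducible; rounding is
applied only when tables are rendered.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, peaks, preprocess, synth, triage
from .chemometrics import (
    bootstrap_coefficient_ci,
    fit_pca,
    fit_pls,
    predict_pls,
    vip_scores,
)
from .spectra import (
    SampleRecord,
    SpectraMatrix,
    read_metadata,
    read_spectra_table,
    restrict_range,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_tables"]

log = logging.getLogger("vitrispec")


def _substream(master_seed: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    h = np.random.SeedSequence([master_seed, zlib.crc32(name.encode())])
    return int(h.generate_state(1)[0] % (2**31))


_STAGE_SEEDS = ("simulate", "bootstrap_coefs", "bootstrap_pi", "splits", "triage", "compare")


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    out_dir: str = "vitrispec_run"
    spectra_path: str | None = None  # wide CSV; None -> simulate
    metadata_path: str | None = None
    working_range: tuple[float, float] = (1800.0, 700.0)
    n_components: int = 2
    component_grid: tuple[int, ...] = tuple(range(1, 11))
    n_splits: int = 5
    train_fraction: float = 0.75
    n_boot_coefs: int = 100
    n_boot_pi: int = 1000
    triage_method: str = "rf"
    seed: int = 0
    simulate: synth.SyntheticConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if isinstance(cfg.working_range, list):
            cfg.working_range = tuple(cfg.working_range)
        if isinstance(cfg.component_grid, list):
            cfg.component_grid = tuple(cfg.component_grid)
        if sim is not None:
            cfg.simulate = synth.SyntheticConfig(**sim)
        return cfg


@dataclass
class ReportBundle:
    """In-memory results of one run (rounding only at render time)."""

    correlations: pd.DataFrame
    peak_bins: pd.DataFrame
    pca_explained: pd.DataFrame
    pca_scores: pd.DataFrame
    model_card: dict
    split_report: pd.DataFrame
    vip: pd.DataFrame
    coefficients: pd.DataFrame
    predictions: list[evaluation.PredictionRecord]
    reliability: list[evaluation.ReliabilityTier]
    triage_cv: pd.DataFrame
    triage_predictions: list[triage.TriagePrediction]
    rf_importances: pd.DataFrame
    comparison: pd.DataFrame
    run_log: dict


def _load_inputs(
    config: RunConfig,
) -> tuple[SpectraMatrix, list[SampleRecord], synth.GroundTruth | None]:
    if config.spectra_path:
        m = read_spectra_table(config.spectra_path)
        meta = read_metadata(config.metadata_path)
        return m, meta, None
    sim = config.simulate or synth.SyntheticConfig()
    sim = sim.with_(seed=_substream(config.seed, "simulate"))
    m, meta, truth = synth.generate_cohort(sim)
    return m, meta, truth


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and return the bundle (also see render_tables)."""
    m, meta, _truth = _load_inputs(config)
    hi, lo = config.working_range
    m = restrict_range(m, hi, lo)
    log.info("loaded %d spectra on %d-point grid", m.n_spectra, m.n_points)

    known = [r for r in meta if r.cohort == "known"]
    unknown = [r for r in meta if r.cohort == "unknown"]
    y_by_sample = {r.sample_id: float(r.pmi_hours) for r in known}
    known_m = m.select_samples([r.sample_id for r in known])

    # -- peak statistics on EMSC + offset-corrected replicate spectra --------
    pre_known = preprocess.fit_preprocess(known_m)
    emsc_all, _ = preprocess.apply_emsc(pre_known.emsc, m)
    offset = preprocess.offset_correct(emsc_all, anchor=hi)
    intensities = peaks.peak_intensity_table(offset)
    correlations = peaks.correlate_peaks(intensities, meta)
    peak_bins = peaks.bin_peak_intensities(intensities, meta)

    # -- preprocessed sample-level matrices ----------------------------------
    z_known = preprocess.average_replicates(preprocess.apply_preprocess(pre_known, known_m))
    X_known, known_ids = z_known.X, z_known.sample_ids
    y_known = np.array([y_by_sample[s] for s in known_ids])

    pca = fit_pca(X_known, k=min(5, len(known_ids) - 1))
    pca_explained = pd.DataFrame(
        {"component": np.arange(1, len(pca.explained_variance_ratio) + 1),
         "explained_pct": 100 * pca.explained_variance_ratio}
    )
    pca_scores = pd.DataFrame(
        pca.scores[:, :2], columns=["PC1", "PC2"]
    ).assign(sample_id=known_ids, pmi_h=y_known)

    # -- repeated splits and the final PLS model -----------------------------
    protocol = evaluation.SplitProtocol(
        n_splits=config.n_splits,
        train_fraction=config.train_fraction,
        seed=_substream(config.seed, "splits"),
        component_grid=config.component_grid,
    )
    split_report = evaluation.repeated_splits(known_m, y_by_sample, protocol)

    cv = evaluation.loocv_pipeline(
        known_m, y_by_sample,
        lambda: evaluation.SpectralPMIRegressor("PLS", config.n_components),
    )
    diag = evaluation.residual_diagnostics(cv.residuals, predicted=cv.y_pred)
    percentiles = evaluation.error_percentiles(cv.abs_errors)
    halfwidth95 = evaluation.bootstrap_prediction_interval(
        cv.residuals, n_boot=config.n_boot_pi, seed=_substream(config.seed, "bootstrap_pi")
    )
    reliability = evaluation.assign_reliability(
        dict(zip(cv.sample_ids, cv.abs_errors)), cv.rmse
    )
    model_card = {
        "samples_used": len(cv.sample_ids),
        "optimal_components": config.n_components,
        "modal_A_across_splits": int(split_report.attrs["modal_A"]),
        "rmse_h": cv.rmse,
        "mae_h": cv.mae,
        "r2": cv.r2,
        "ci95_halfwidth_h": halfwidth95,
        "error_percentiles_h": dataclasses.asdict(percentiles),
        "shapiro_p": diag.shapiro_p,
        "levene_p": diag.levene_p,
        "split_summary": split_report.attrs["summary"],
    }

    final_pls = fit_pls(X_known, y_known, config.n_components, training_ids=known_ids)
    vip = vip_scores(final_pls)
    vip_df = pd.DataFrame({"wavenumber": m.grid.values, "vip": vip.scores})
    coef_ci = bootstrap_coefficient_ci(
        X_known, y_known, config.n_components,
        n_boot=config.n_boot_coefs, seed=_substream(config.seed, "bootstrap_coefs"),
    )
    coef_df = pd.DataFrame(
        {"wavenumber": m.grid.values,
         "std_coefficient": coef_ci.coefficients,
         "ci_low": coef_ci.ci_low, "ci_high": coef_ci.ci_high}
    )

    # -- query-cohort predictions -------------------------------------------
    predictions = []
    if unknown:
        unknown_m = m.select_samples([r.sample_id for r in unknown])
        z_unknown = preprocess.average_replicates(
            preprocess.apply_preprocess(pre_known, unknown_m)
        )
        y_hat = predict_pls(final_pls, z_unknown.X)
        estimates = {r.sample_id: r.pmi_hours for r in unknown}
        for sid, pred in zip(z_unknown.sample_ids, y_hat):
            predictions.append(
                evaluation.build_prediction_record(
                    sid, float(pred), percentiles, halfwidth95, estimates.get(sid)
                )
            )

    # -- triage ---------------------------------------------------------------
    labels = {r.sample_id: triage.binarize_pmi(r.pmi_hours) for r in known}
    triage_seed = _substream(config.seed, "triage")
    triage_rows = []
    for method in triage.CLASSIFIER_METHODS:
        rep = triage.loocv_classify(known_m, labels, method=method, seed=triage_seed)
        triage_rows.append({"classifier": method, **rep.to_row()})
    triage_cv = pd.DataFrame(triage_rows)

    final_clf = triage.fit_triage_final(known_m, labels, config.triage_method, triage_seed)
    rf_importances = pd.DataFrame(
        {"wavenumber": m.grid.values, "gini_importance": final_clf.importances()}
    ) if config.triage_method == "rf" else pd.DataFrame()
    triage_predictions = (
        triage.predict_triage(final_clf, m.select_samples([r.sample_id for r in unknown]), meta)
        if unknown
        else []
    )

    # -- robustness comparison -----------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparison = evaluation.compare_methods(
            known_m, meta, n_components=config.n_components,
            seed=_substream(config.seed, "compare"),
        )

    run_log = {
        "seed": config.seed,
        "stage_seeds": {name: _substream(config.seed, name) for name in _STAGE_SEEDS},
        "n_known": len(known),
        "n_unknown": len(unknown),
        "n_points": m.n_points,
        "working_range_cm1": list(config.working_range),
    }
    return ReportBundle(
        correlations=peaks.correlations_to_frame(correlations),
        peak_bins=peak_bins,
        pca_explained=pca_explained,
        pca_scores=pca_scores,
        model_card=model_card,
        split_report=split_report,
        vip=vip_df,
        coefficients=coef_df,
        predictions=predictions,
        reliability=reliability,
        triage_cv=triage_cv,
        triage_predictions=triage_predictions,
        rf_importances=rf_importances,
        comparison=comparison.results,
        run_log=run_log,
    )


def round_half_away(x: float) -> int:
    """Round to the nearest hour, halves away from zero (report convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _interval_str(interval: tuple[float, float]) -> str:
    lo, hi = interval
    return f"[{round_half_away(lo)}-{round_half_away(hi)}]"


def predictions_to_frame(records: list[evaluation.PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "estimate_h": [
                None if r.external_estimate is None else round(r.external_estimate, 1)
                for r in records
            ],
            "predicted_h": [round(r.y_hat, 1) for r in records],
            "interval_50": [_interval_str(r.interval_50) for r in records],
            "interval_75": [_interval_str(r.interval_75) for r in records],
            "interval_90": [_interval_str(r.interval_90) for r in records],
            "agreement": [r.agreement for r in records],
        }
    )


def render_tables(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as CSV/JSON files; interval bounds rounded to hours."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path

    write_csv("peak_correlations", bundle.correlations.round(
        {"r": 3, "ci_low": 3, "ci_high": 3}))
    write_csv("peak_bins", bundle.peak_bins)
    write_csv("pca_explained", bundle.pca_explained.round({"explained_pct": 1}))
    write_csv("pca_scores", bundle.pca_scores)
    write_csv("split_report", bundle.split_report.round({"rmse": 2, "mae": 2, "r2": 3}))
    write_csv("vip", bundle.vip)
    write_csv("coefficients", bundle.coefficients)
    write_csv("predictions", predictions_to_frame(bundle.predictions))
    write_csv(
        "reliability",
        pd.DataFrame([dataclasses.asdict(t) for t in bundle.reliability]).round(
            {"abs_error": 2}
        )
        if bundle.reliability
        else pd.DataFrame(columns=["sample_id", "abs_error", "tier"]),
    )
    write_csv("triage_cv", bundle.triage_cv.round(3))
    write_csv(
        "triage_predictions",
        pd.DataFrame([dataclasses.asdict(t) for t in bundle.triage_predictions]).round(
            {"confidence": 2}
        )
        if bundle.triage_predictions
        else pd.DataFrame(
            columns=["sample_id", "predicted_class", "confidence",
                     "external_estimate_h", "agreement", "caveat"]
        ),
    )
    if not bundle.rf_importances.empty:
        write_csv("rf_importances", bundle.rf_importances)
    write_csv("method_comparison", bundle.comparison.round({"rmse": 2, "r2": 3, "mae": 2}))

    card = dict(bundle.model_card)
    for key in ("rmse_h", "mae_h", "ci95_halfwidth_h"):
        card[key] = round(card[key], 2)
    card["r2"] = round(card["r2"], 3)
    (out / "model_card.json").write_text(json.dumps(card, indent=2, default=float))
    paths["model_card"] = out / "model_card.json"
    (out / "run_log.json").write_text(json.dumps(bundle.run_log, indent=2, default=float))
    paths["run_log"] = out / "run_log.json"
    return paths
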