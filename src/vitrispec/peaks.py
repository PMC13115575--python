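"""Diagnostic-peak intensities and their association with PMI.

Peak intensities are read from EMSC-corrected, offset-corrected (at 1800
cm^-1), *non-derivative* spectra: each peak's intensity is the maximum
absorbance inside a +-8 cm^-1 search window around its nominal position,
tolerating small drifts while keeping adjacent panel peaks (1041/1086 cm^-1)
disjoint.

Association with PMI is summarized per peak by the Pearson correlation over
replicate-level (intensity, PMI) pairs, with a 95% confidence interval from
Fisher's z-transformation, a two-sided t-test p-value, Benjamini-Hochberg
FDR correction across the 12-peak family, and a qualitative label
(Strong >= 0.5, Moderate >= 0.4, Weak below, "Not significant" when the
adjusted p >= 0.05).  Replicates are treated as repeated observations with
no within-sample clustering correction; the pseudo-replication caveat is
carried in the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectra import SampleRecord, SpectraMatrix

__all__ = [
    "DiagnosticPeak",
    "PeakCorrelation",
    "DEFAULT_PEAKS",
    "extract_peak_intensity",
    "peak_intensity_table",
    "fisher_ci",
    "pearson_with_ci",
    "bh_fdr",
    "correlate_peaks",
    "correlations_to_frame",
    "label_correlation",
    "bin_peak_intensities",
]


@dataclass(frozen=True)
class DiagnosticPeak:
    """One literature-anchored absorption band of the diagnostic panel."""

    observed_wn: float  # cm^-1, where the band sits in these spectra
    literature_wn: float = 0.0
    search_halfwidth: float = 8.0  # cm^-1
    vibrational_mode: str = ""
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.literature_wn == 0.0:
            object.__setattr__(self, "literature_wn", self.observed_wn)


#: the 12-band vitreous-humor panel (observed position, literature position,
#: vibrational mode, biochemical assignment)
DEFAULT_PEAKS: tuple[DiagnosticPeak, ...] = (
    DiagnosticPeak(1663, 1666, 8.0, "v(C=O), v(C-N) amide I", "alpha helices in peptides, proteins"),
    DiagnosticPeak(1630, 1630, 8.0, "v(C=O), v(C-N) amide I", "beta sheets; small nitrogenous solutes"),
    DiagnosticPeak(1580, 1580, 8.0, "v(C-N), d(N-H) amide II", "proteins; urea, creatinine, uric acid"),
    DiagnosticPeak(1456, 1452, 8.0, "d(CH2), d(CH3)", "lipids, proteins, aliphatic metabolites"),
    DiagnosticPeak(1414, 1417, 8.0, "vs(COO-)", "free amino acids, organic acids, hyaluronic acid"),
    DiagnosticPeak(1315, 1313, 8.0, "v(C-N), d(N-H) amide III", "proteins, peptides"),
    DiagnosticPeak(1121, 1120, 8.0, "v(C-O)", "lactate and small carbohydrates"),
    DiagnosticPeak(1086, 1080, 8.0, "v(P-O), v(C-O)", "phosphate-containing compounds"),
    DiagnosticPeak(1041, 1040, 8.0, "v(C-O), v(C-OH)", "glucose, monosaccharides"),
    DiagnosticPeak(925, 925, 8.0, "v(C-O), v(P-O)", "nucleic acid fragments"),
    DiagnosticPeak(855, 854, 8.0, "v(C-C), v(C-O)", "lactate and small carbohydrates"),
    DiagnosticPeak(780, 780, 8.0, "v(C-O), v(C-C)", "carbohydrate"),
)


@dataclass(frozen=True)
class PeakCorrelation:
    """Pearson summary for one diagnostic peak."""

    peak: DiagnosticPeak
    r: float
    n_obs: int
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float
    label: str
    caveat: str = "replicates treated as independent observations"

    def __post_init__(self) -> None:
        if not (-1 <= self.ci_low <= self.r <= self.ci_high <= 1):
            raise ValueError("confidence interval must bracket r inside [-1, 1]")


def extract_peak_intensity(
    m: SpectraMatrix, peak: DiagnosticPeak
) -> tuple[np.ndarray, np.ndarray]:
    """Max absorbance (and its position) within the peak's search window.

    Returns (intensities, positions) arrays over the matrix rows.
    """
    lo = peak.observed_wn - peak.search_halfwidth
    hi = peak.observed_wn + peak.search_halfwidth
    mask = (m.grid.values >= lo) & (m.grid.values <= hi)
    if not mask.any():
        raise ValueError(
            f"search window {hi:.0f}-{lo:.0f} cm^-1 of peak {peak.observed_wn} is off-grid"
        )
    window = m.X[:, mask]
    wns = m.grid.values[mask]
    arg = np.argmax(window, axis=1)
    return window[np.arange(m.n_spectra), arg], wns[arg]


def peak_intensity_table(
    m: SpectraMatrix, peaks: tuple[DiagnosticPeak, ...] = DEFAULT_PEAKS
) -> pd.DataFrame:
    """Rows = spectra (sample_id, replicate_id), columns = peak positions."""
    data = {"sample_id": m.sample_ids, "replicate_id": m.replicate_ids}
    for peak in peaks:
        intensity, _ = extract_peak_intensity(m, peak)
        data[peak.observed_wn] = intensity
    return pd.DataFrame(data)


def fisher_ci(r: float, n_obs: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform CI for a Pearson correlation.

    CI = tanh(atanh(r) +- z_{1-alpha/2} / sqrt(n - 3)); |r| is clipped just
    inside 1 so the transform stays finite on perfectly collinear input.
    """
    if n_obs < 4:
        raise ValueError("need at least 4 paired observations")
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    z = stats.norm.ppf(0.5 + conf / 2)
    half = z / math.sqrt(n_obs - 3)
    lo, hi = math.tanh(math.atanh(r_c) - half), math.tanh(math.atanh(r_c) + half)
    return min(lo, r), max(hi, r)


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, conf: float = 0.95
) -> tuple[float, float, float]:
    """Pearson r with the Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = fisher_ci(r, n, conf)
    return r, lo, hi


def bh_fdr(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is not None and m != p.size:
        raise ValueError(f"m={m} must equal the number of p-values ({p.size})")
    return multipletests(p, method="fdr_bh")[1]


def label_correlation(r: float, p_fdr: float) -> str:
    """Qualitative call: strength by |r| (0.5/0.4 cut points), sign suffix."""
    if p_fdr >= 0.05:
        return "Not significant"
    if abs(r) >= 0.5:
        strength = "Strong"
    elif abs(r) >= 0.4:
        strength = "Moderate"
    else:
        strength = "Weak"
    return f"{strength} {'positive' if r > 0 else 'negative'}"


def correlate_peaks(
    intensity_table: pd.DataFrame,
    meta: list[SampleRecord],
    peaks: tuple[DiagnosticPeak, ...] = DEFAULT_PEAKS,
) -> list[PeakCorrelation]:
    """One PeakCorrelation per panel peak from replicate-level pairs.

    Only known-cohort samples with a PMI enter; the FDR family is the peak
    panel; output is sorted by |r| descending.
    """
    pmi = {
        rec.sample_id: rec.pmi_hours
        for rec in meta
        if rec.cohort == "known" and rec.pmi_hours is not None
    }
    table = intensity_table[intensity_table.sample_id.isin(pmi)].copy()
    if table.empty:
        raise ValueError("no known-cohort rows with PMI in the intensity table")
    y = table.sample_id.map(pmi).to_numpy(dtype=float)

    rs, cis, ps = [], [], []
    for peak in peaks:
        x = table[peak.observed_wn].to_numpy(dtype=float)
        r, lo, hi = pearson_with_ci(x, y)
        p = float(stats.pearsonr(x, y).pvalue)  # two-sided t, df = n - 2
        rs.append(r)
        cis.append((lo, hi))
        ps.append(p)
    p_adj = bh_fdr(np.array(ps))

    out = [
        PeakCorrelation(
            peak=peak,
            r=rs[i],
            n_obs=len(table),
            ci_low=cis[i][0],
            ci_high=cis[i][1],
            p_raw=ps[i],
            p_fdr=max(float(p_adj[i]), ps[i]),
            label=label_correlation(rs[i], float(p_adj[i])),
        )
        for i, peak in enumerate(peaks)
    ]
    return sorted(out, key=lambda c: abs(c.r), reverse=True)


def correlations_to_frame(correlations: list[PeakCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_cm1": [c.peak.observed_wn for c in correlations],
            "r": [c.r for c in correlations],
            "ci_low": [c.ci_low for c in correlations],
            "ci_high": [c.ci_high for c in correlations],
            "n_obs": [c.n_obs for c in correlations],
            "p_raw": [c.p_raw for c in correlations],
            "p_fdr": [c.p_fdr for c in correlations],
            "interpretation": [c.label for c in correlations],
        }
    )


def bin_peak_intensities(
    intensity_table: pd.DataFrame,
    meta: list[SampleRecord],
    bin_width: float = 10.0,
    peaks: tuple[DiagnosticPeak, ...] = DEFAULT_PEAKS,
) -> pd.DataFrame:
    """Boxplot-style summaries of replicate intensities per PMI bin.

    Bins are [k*w, (k+1)*w) spanning the known-cohort PMI range; per bin and
    peak the summary holds n, quartiles, 1.5*IQR whiskers and the outlying
    points beyond them.
    """
    pmi = {
        rec.sample_id: rec.pmi_hours
        for rec in meta
        if rec.cohort == "known" and rec.pmi_hours is not None
    }
    table = intensity_table[intensity_table.sample_id.isin(pmi)].copy()
    y = table.sample_id.map(pmi).to_numpy(dtype=float)
    first = math.floor(y.min() / bin_width) * bin_width
    last = math.floor(y.max() / bin_width) * bin_width
    edges = np.arange(first, last + bin_width + 1e-9, bin_width)

    rows = []
    for left in edges[:-1]:
        in_bin = (y >= left) & (y < left + bin_width)
        for peak in peaks:
            vals = table[peak.observed_wn].to_numpy(dtype=float)[in_bin]
            if vals.size == 0:
                rows.append(
                    {"bin_left": left, "bin_right": left + bin_width,
                     "peak_cm1": peak.observed_wn, "n": 0, "q1": np.nan,
                     "median": np.nan, "q3": np.nan, "whisker_low": np.nan,
                     "whisker_high": np.nan, "n_outliers": 0}
                )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            rows.append(
                {
                    "bin_left": left,
                    "bin_right": left + bin_width,
                    "peak_cm1": peak.observed_wn,
                    "n": int(vals.size),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "whisker_low": inside.min(),
                    "whisker_high": inside.max(),
                    "n_outliers": int(vals.size - inside.size),
                }
            )
    return pd.DataFrame(rows)
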