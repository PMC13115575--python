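"""Multivariate models on preprocessed spectra: PCA, PLS, VIP, clustering.

PLS here is single-response NIPALS, which is deterministic (the first weight
vector is X'y up to normalization, no random initialization).  For response
``y`` and centered predictors ``X`` the algorithm extracts ``A`` components

    w_a = X'y / ||X'y||,  t_a = X w_a,  p_a = X't_a / t_a't_a,
    q_a = y't_a / t_a't_a,  X <- X - t_a p_a'

and assembles the regression vector ``B = W (P'W)^{-1} q`` so that
predictions are ``y_mean + (X_new - x_mean) B``.

Variable importance in projection (VIP) weighs each wavenumber's squared
weight by the y-variance explained per component,

    VIP_j = sqrt( P * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ),
    SS_a  = q_a^2 t_a't_a

so the mean squared VIP is identically 1; VIP > 1 marks influential
wavenumbers.  Standardized coefficients are ``B_j * sd(X_j)`` (hours per
standard deviation of the predictor), with percentile bootstrap confidence
bands over sample resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "PCAModel",
    "PLSModel",
    "VIPProfile",
    "CoefficientProfile",
    "fit_pca",
    "fit_pls",
    "predict_pls",
    "vip_scores",
    "standardized_coefficients",
    "bootstrap_coefficient_ci",
    "cluster_spectra",
]


@dataclass
class PCAModel:
    loadings: np.ndarray  # k x P, orthonormal rows
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # n x k
    center: np.ndarray  # column mean used


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """PCA by SVD of the column-centered matrix; ratios use n-1 denominators."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, P) = {min(n - 1, p)}")
    pca = _SKPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAModel(
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        center=pca.mean_,
    )


@dataclass
class PLSModel:
    A: int
    W: np.ndarray  # P x A normalized x-weights
    P_load: np.ndarray  # P x A x-loadings
    q: np.ndarray  # A y-loadings
    B: np.ndarray  # P regression vector (centered scale)
    x_mean: np.ndarray
    y_mean: float
    T: np.ndarray  # n x A training scores
    training_ids: list[str] = field(default_factory=list)


def fit_pls(
    X: np.ndarray, y: np.ndarray, A: int, training_ids: list[str] | None = None
) -> PLSModel:
    """Single-response NIPALS PLS; centers X and y internally."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must equal row count of X")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    if n < A + 1:
        raise ValueError(f"need at least A+1={A + 1} samples for {A} components")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, A))
    P_load = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    Xa = Xc.copy()
    used = 0
    for a in range(A):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12:
            warnings.warn(
                f"rank exhausted after {used} components (requested {A}); truncating",
                stacklevel=2,
            )
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            warnings.warn(
                f"degenerate score vector at component {a + 1}; truncating",
                stacklevel=2,
            )
            break
        p_a = Xa.T @ t / tt
        q_a = float(yc @ t / tt)
        Xa = Xa - np.outer(t, p_a)
        W[:, a], P_load[:, a], q[a], T[:, a] = w, p_a, q_a, t
        used += 1

    W, P_load, q, T = W[:, :used], P_load[:, :used], q[:used], T[:, :used]
    B = W @ np.linalg.solve(P_load.T @ W, q)
    return PLSModel(
        A=used, W=W, P_load=P_load, q=q, B=B, x_mean=x_mean, y_mean=y_mean,
        T=T, training_ids=list(training_ids or []),
    )


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.B


@dataclass
class VIPProfile:
    scores: np.ndarray  # per-wavenumber VIP, mean square == 1
    threshold: float = 1.0

    def significant(self) -> np.ndarray:
        return self.scores > self.threshold


def vip_scores(model: PLSModel) -> VIPProfile:
    ss = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)  # y-variance per comp
    p = model.W.shape[0]
    wn2 = model.W**2 / np.maximum(np.sum(model.W**2, axis=0), 1e-300)
    vip = np.sqrt(p * (wn2 @ ss) / ss.sum())
    return VIPProfile(scores=vip)


@dataclass
class CoefficientProfile:
    coefficients: np.ndarray  # hours per SD of predictor
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_boot: int = 0
    n_degenerate_redraws: int = 0


def standardized_coefficients(model: PLSModel, X_train: np.ndarray) -> CoefficientProfile:
    """B_j scaled by the training standard deviation of column j."""
    sd = np.asarray(X_train, dtype=float).std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance predictor columns get coefficient 0", stacklevel=2)
    return CoefficientProfile(coefficients=model.B * sd)


def bootstrap_coefficient_ci(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    n_boot: int = 100,
    seed: int = 0,
    level: float = 0.95,
) -> CoefficientProfile:
    """Percentile bootstrap CIs for the standardized coefficient profile."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples to bootstrap")
    rng = np.random.default_rng(seed)

    # the standardized scale is fixed by the calibration data; bootstrap
    # replicates vary the model fit, not the per-column scaling
    sd = X.std(axis=0, ddof=1)
    point = standardized_coefficients(fit_pls(X, y, A), X).coefficients
    draws = np.empty((n_boot, X.shape[1]))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        if np.std(y[idx]) == 0:
            redraws += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws[b] = fit_pls(X[idx], y[idx], A).B * sd
        b += 1
    alpha = (1 - level) / 2
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return CoefficientProfile(
        coefficients=point, ci_low=lo, ci_high=hi,
        n_boot=n_boot, n_degenerate_redraws=redraws,
    )


def cluster_spectra(X: np.ndarray, method: str = "ward", metric: str = "euclidean") -> np.ndarray:
    """Agglomerative dendrogram (scipy linkage matrix) of spectrum rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spectra to cluster")
    return linkage(X, method=method, metric=metric)
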