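"""PCA and ICA feature extraction from decomposed epochs.

The decomposed signal (20 subbands with their Pisarenko spectra) is first
flattened into per-epoch summary statistics — for every subband, in level
order and band order LFLF/LFHF/HFLF/HFHF: mean, variance, energy, dominant
pseudospectrum frequency and pseudospectrum entropy.  Principal components
(orthogonal, variance-ranked projections of the covariance eigenproblem) and
independent components (non-Gaussianity-maximizing unmixing, FastICA with a
log-cosh contrast) are then extracted from that observation matrix and
concatenated, PCA block first.  The default of 83 components per method is
configuration, enforced against the achievable rank: an input that cannot
support the requested count raises rather than silently truncating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .decomp import DecomposedSignal

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "ICAModel",
    "ConfigurationError",
    "flatten_decomposed",
    "pca_fit_transform",
    "pca_transform",
    "ica_fit_transform",
    "ica_transform",
    "concat_features",
    "SUBBAND_STATS",
]

DEFAULT_COMPONENTS = 83
SUBBAND_STATS = ("mean", "variance", "energy", "dominant_freq", "spectral_entropy")


class ConfigurationError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_epochs, n_features)
    method_tags: np.ndarray  # per-column origin, "PCA" or "ICA"
    component_count: dict[str, int]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.values.shape[1] != len(self.method_tags):
            raise ValueError("method_tags must match the number of columns")


@dataclass
class PCAModel:
    mean_vector: np.ndarray
    eigenvalues: np.ndarray  # descending, nonnegative
    eigenvectors: np.ndarray  # orthonormal columns, one per component


@dataclass
class ICAModel:
    unmixing: np.ndarray  # rows unit-norm
    mixing_estimate: np.ndarray
    component_count: int
    mean_vector: np.ndarray
    converged: bool = True
    non_identifiable: bool = False


def flatten_decomposed(decomposed: list[DecomposedSignal]) -> np.ndarray:
    """Per-epoch subband statistics, concatenated in fixed documented order.

    Layout: for level 1..5, for band LFLF/LFHF/HFLF/HFHF, the five statistics
    of :data:`SUBBAND_STATS`.  A subband without a Pisarenko result (too
    short, or identically zero) contributes 0 for the dominant frequency and
    entropy; the entropy of an all-zero spectrum is 0 by convention.
    """
    if not decomposed:
        raise ValueError("empty decomposition list")
    rows = []
    for d in decomposed:
        stats: list[float] = []
        for (level, name, coeffs), pis in zip(d.subbands.iter_bands(), d.pisarenko):
            stats.append(float(np.mean(coeffs)))
            stats.append(float(np.var(coeffs)))
            stats.append(float(coeffs @ coeffs))
            if pis is None:
                stats.extend((0.0, 0.0))
            else:
                dom = pis.dominant_freqs[0] if pis.dominant_freqs else 0.0
                stats.append(float(dom))
                stats.append(_spectral_entropy(pis.pseudospectrum))
        rows.append(stats)
    return np.asarray(rows, dtype=float)


def _spectral_entropy(pseudospectrum: np.ndarray) -> float:
    total = pseudospectrum.sum()
    if not total > 0:
        return 0.0
    p = pseudospectrum / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _check_components(n_components: int, n_rows: int, n_vars: int) -> None:
    limit = min(n_rows - 1, n_vars)
    if n_components > limit:
        raise ConfigurationError(
            f"n_components={n_components} exceeds the achievable rank "
            f"min(n_epochs - 1, n_vars) = {limit}"
        )
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")


def pca_fit_transform(
    X: np.ndarray, n_components: int = DEFAULT_COMPONENTS
) -> tuple[PCAModel, np.ndarray]:
    """Principal components of the observation matrix (rows = epochs).

    Centers the data, eigendecomposes the sample covariance and projects
    onto the leading ``n_components`` eigenvectors.  Each eigenvector's
    largest-magnitude entry is made positive so the decomposition is
    reproducible up to nothing.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    _check_components(n_components, n, p)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)[:n_components]
    eigvecs = eigvecs[:, order][:, :n_components]
    # deterministic sign: largest-magnitude entry positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    model = PCAModel(mean_vector=mean, eigenvalues=eigvals, eigenvectors=eigvecs)
    return model, Xc @ eigvecs


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - model.mean_vector) @ model.eigenvectors


def ica_fit_transform(
    X: np.ndarray, n_components: int = DEFAULT_COMPONENTS, seed: int = 0
) -> tuple[ICAModel, np.ndarray]:
    """Independent components via the fixed-point (FastICA) iteration.

    Whitening by PCA, log-cosh contrast, at most 500 iterations at tolerance
    1e-6.  Non-convergence is reported on the model (best iterate kept) with
    a warning, never an exception.  Rows of the unmixing matrix are
    normalized to unit norm with the same sign convention as the PCA
    eigenvectors.  When every recovered source looks Gaussian (tiny excess
    kurtosis) the rotation is not identifiable and the model is flagged.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    _check_components(n_components, n, p)
    ica = FastICA(
        n_components=n_components,
        fun="logcosh",
        max_iter=500,
        tol=1e-6,
        whiten="unit-variance",
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "FastICA did not converge within 500 iterations; "
                "returning the best iterate",
                stacklevel=2,
            )

    W = np.asarray(ica.components_, dtype=float)  # overall unmixing (incl. whitening)
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    W = W / norms
    flip = np.sign(W[np.arange(W.shape[0]), np.abs(W).argmax(axis=1)])
    flip[flip == 0] = 1.0
    W = W * flip[:, None]

    mean = ica.mean_
    sources = (X - mean) @ W.T
    k = kurtosis(sources, axis=0, fisher=True, bias=False)
    non_identifiable = bool(np.all(np.abs(k) < 0.25))
    model = ICAModel(
        unmixing=W,
        mixing_estimate=np.linalg.pinv(W),
        component_count=n_components,
        mean_vector=mean,
        converged=converged,
        non_identifiable=non_identifiable,
    )
    return model, sources


def ica_transform(model: ICAModel, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - model.mean_vector) @ model.unmixing.T


def concat_features(pca_cols: np.ndarray, ica_cols: np.ndarray | None) -> FeatureMatrix:
    """Column-wise concatenation, PCA block first."""
    pca_cols = np.asarray(pca_cols, dtype=float)
    if ica_cols is None or np.size(ica_cols) == 0:
        values = pca_cols
        tags = np.array(["PCA"] * pca_cols.shape[1])
        counts = {"PCA": pca_cols.shape[1], "ICA": 0}
    else:
        ica_cols = np.asarray(ica_cols, dtype=float)
        if ica_cols.shape[0] != pca_cols.shape[0]:
            raise ValueError("PCA and ICA blocks must share the epoch count")
        values = np.hstack([pca_cols, ica_cols])
        tags = np.array(["PCA"] * pca_cols.shape[1] + ["ICA"] * ica_cols.shape[1])
        counts = {"PCA": pca_cols.shape[1], "ICA": ica_cols.shape[1]}
    return FeatureMatrix(values=values, method_tags=tags, component_count=counts)
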