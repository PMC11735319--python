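"""Dimensionality and low-dimensional visualization of population activity.

PCA cumulative-variance curves over small neuron subsamples, the
participation ratio PR = (sum lambda)^2 / sum lambda^2, and classical
(metric) multidimensional scaling by diagonalization of the double-centred
dissimilarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def participation_ratio(eigenvalues) -> float:
    """PR = (sum_i lambda_i)^2 / sum_i lambda_i^2.

    1 when a single eigenvalue carries all variance; N when all N
    eigenvalues are equal.  Scale-invariant: PR(c * lambda) = PR(lambda).
    """
    lam = np.asarray(eigenvalues, float)
    if np.any(lam < -1e-10 * max(lam.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    s2 = (lam**2).sum()
    if s2 == 0:
        raise ValueError("all-zero spectrum: participation ratio undefined")
    return float(lam.sum() ** 2 / s2)


@dataclass
class EigenSpectrum:
    cumvar: np.ndarray        # mean cumulative variance fraction per PC
    pr: float                 # mean participation ratio across subsamples
    eigenvalues: np.ndarray   # mean sorted spectrum

    @property
    def features(self) -> np.ndarray:
        """Cumulative variance of the first three PCs (group-decoder input)."""
        return self.cumvar[:3]


def zscore_counts(counts: np.ndarray) -> np.ndarray:
    """Per-row z-scoring; zero-variance rows are dropped with a warning."""
    X = np.asarray(counts, float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn("excluding zero-variance neurons from z-scoring")
    X = X[keep]
    return (X - X.mean(axis=1, keepdims=True)) / sd[keep][:, None]


def pca_cumvar(counts: np.ndarray, subsample_size: int = 5,
               n_subsamples: int = 1000, seed=None) -> EigenSpectrum:
    """Cumulative-variance curve of small-ensemble PCA, averaged over random
    neuron subsamples.

    Each subsample draws ``subsample_size`` neurons, z-scores them across
    time, and eigendecomposes the neuron-by-neuron covariance; the
    per-subsample cumulative-variance curves and participation ratios are
    averaged.  Because rows are z-scored the eigenvalues sum to the number
    of sampled neurons.
    """
    Z = zscore_counts(counts)
    n = Z.shape[0]
    if n < subsample_size:
        raise ValueError(f"need at least {subsample_size} non-silent neurons")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_subsamples, subsample_size))
    prs = np.empty(n_subsamples)
    spectra = np.empty((n_subsamples, subsample_size))
    for s in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        lam = np.linalg.eigvalsh(np.cov(Z[idx]))[::-1]
        lam = np.clip(lam, 0.0, None)
        spectra[s] = lam
        curves[s] = np.cumsum(lam) / lam.sum()
        prs[s] = participation_ratio(lam)
    return EigenSpectrum(curves.mean(axis=0), float(prs.mean()), spectra.mean(axis=0))


@dataclass
class EmbeddingCoords:
    coords: np.ndarray        # (n_items, n_components)
    eigenvalues: np.ndarray   # full eigenvalue diagnostics of B


def mds_embed(features: np.ndarray | None = None,
              dissimilarity: np.ndarray | None = None,
              groups=None, n_components: int = 2) -> EmbeddingCoords:
    """Classical MDS: diagonalize the double-centred squared-dissimilarity
    matrix and embed on the top eigenvectors.

    Either ``features`` (items x features; Euclidean dissimilarities are
    formed, optionally after dividing each group's rows by that group's
    variance) or a symmetric ``dissimilarity`` matrix may be given.
    Negative eigenvalues (non-Euclidean input) are truncated at zero with a
    warning.  Output is unique only up to rotation/reflection.
    """
    if (features is None) == (dissimilarity is None):
        raise ValueError("pass exactly one of features / dissimilarity")
    if features is not None:
        X = np.asarray(features, float).copy()
        if groups is not None:
            groups = np.asarray(groups)
            for g in np.unique(groups):
                m = groups == g
                var = X[m].var()
                if var > 0:
                    X[m] = X[m] / var
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=-1))
    else:
        D = np.asarray(dissimilarity, float)
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(D < 0):
            raise ValueError("dissimilarities must be non-negative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    lam, vec = np.linalg.eigh(B)
    lam, vec = lam[::-1], vec[:, ::-1]
    if lam.min() < -1e-8 * max(abs(lam).max(), 1.0):
        warnings.warn("negative MDS eigenvalues truncated (non-Euclidean input)")
    lam_t = np.clip(lam[:n_components], 0.0, None)
    coords = vec[:, :n_components] * np.sqrt(lam_t)
    return EmbeddingCoords(coords, lam)
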