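"""Per-band Common Spatial Pattern fitting and feature extraction.

CSP finds, for a binary problem, a spatial projection W that
simultaneously diagonalizes the two class-average spatial covariance
matrices so that the paired diagonal entries (eigenvalues) sum to 1:
components at one end of the spectrum maximize class-1 variance while
minimizing class-2 variance, and vice versa.  The construction is the
classical one: whiten the composite covariance C1 + C2, rotate with the
eigenvectors of the whitened C1, and order rows so the projected class-1
variance decreases (class-2 variance is then ascending).

Here CSP is fit independently within each band of a filter-bank
decomposition; all n_channels components are retained per band, so the
feature vector has n_channels x n_bands entries (e.g. 8 x 12 = 96),
reducing each 1536-sample track to a single number (default: the log of
the component variance normalized by the per-band sum of component
variances).

Per-epoch spatial covariances are the sufficient statistics of both the
fit and the feature extraction: the projected variance of an epoch is
diag(W @ Sigma_epoch @ W.T).  :func:`band_covariances` caches them so
that refitting CSP inside every cross-validation partition stays cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filterbank import FilterBank, apply_filter_bank, apply_filter_bank_batch

logger = logging.getLogger(__name__)

__all__ = ["CSPModel", "band_covariances", "fit_csp", "csp_features"]


@dataclass
class CSPModel:
    """Fitted per-band CSP projections.

    Attributes
    ----------
    W : ndarray, shape (n_bands, n_channels, n_channels)
        Per-band projection matrices (components x channels rows).
    eigenvalues : ndarray, shape (n_bands, n_channels)
        Projected class-1 variance fractions, sorted descending; the
        paired class-2 eigenvalues are their complements to 1.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    n_channels: int
    scheme_name: str
    log_variance: bool = True

    @property
    def n_bands(self) -> int:
        return self.W.shape[0]

    @property
    def patterns(self) -> np.ndarray:
        """Spatial patterns: per band, columns of W^-1 (forward model)."""
        return np.stack([np.linalg.inv(w) for w in self.W])

    @property
    def n_features(self) -> int:
        return self.n_channels * self.n_bands


def band_covariances(epochs_data, bank: FilterBank) -> np.ndarray:
    """Trace-normalized per-epoch, per-band spatial covariances.

    Parameters
    ----------
    epochs_data : ndarray, shape (n_epochs, n_channels, n_samples)
    bank : FilterBank

    Returns
    -------
    ndarray, shape (n_epochs, n_bands, n_channels, n_channels)
        For each epoch and band, X @ X.T of the band-filtered, mean-removed
        window, divided by its trace (scale invariance: standard CSP
        covariance conditioning).
    """
    tensors = apply_filter_bank_batch(np.asarray(epochs_data, dtype=float), bank)
    tensors = tensors - tensors.mean(axis=-1, keepdims=True)
    cov = np.einsum("ebct,ebdt->ebcd", tensors.transpose(0, 2, 1, 3),
                    tensors.transpose(0, 2, 1, 3))
    tr = np.trace(cov, axis1=-2, axis2=-1)[..., None, None]
    return cov / tr


def _csp_single_band(c1: np.ndarray, c2: np.ndarray, ridge: float):
    n = c1.shape[0]
    comp = c1 + c2
    comp = comp + ridge * np.trace(comp) / n * np.eye(n)
    evals, evecs = np.linalg.eigh(comp)
    if evals[0] <= 0 or evals[0] / evals[-1] < 1e-12:
        raise np.linalg.LinAlgError(
            "rank-deficient composite covariance; increase the regularization "
            "ridge (config, default 1e-8)"
        )
    whitener = (evecs / np.sqrt(evals)).T
    s1 = whitener @ c1 @ whitener.T
    lam, rot = np.linalg.eigh((s1 + s1.T) / 2)
    order = np.argsort(lam)[::-1]  # class-1 variance decreasing
    lam = np.clip(lam[order], 0.0, 1.0)
    W = rot[:, order].T @ whitener
    return W, lam


def fit_csp(covariances, labels, scheme_name: str = "", ridge: float = 1e-8,
            log_variance: bool = True) -> CSPModel:
    """Fit per-band CSP from cached per-epoch covariances.

    Parameters
    ----------
    covariances : ndarray, shape (n_epochs, n_bands, n_channels, n_channels)
        Output of :func:`band_covariances`.
    labels : array of int
        0 for class 1 (attentive), 1 for class 2 (distracted).
    ridge : float
        Shrinkage added to the composite covariance diagonal (fraction of
        its mean eigenvalue) before whitening.
    """
    cov = np.asarray(covariances)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fit_csp requires exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 epochs per class")
    c1 = cov[y == classes[0]].mean(axis=0)
    c2 = cov[y == classes[1]].mean(axis=0)
    n_bands, n_ch = c1.shape[0], c1.shape[1]
    W = np.empty((n_bands, n_ch, n_ch))
    lam = np.empty((n_bands, n_ch))
    for b in range(n_bands):
        W[b], lam[b] = _csp_single_band(c1[b], c2[b], ridge)
    logger.info("fit_csp: %d bands x %d channels on %d epochs",
                n_bands, n_ch, len(y))
    return CSPModel(W=W, eigenvalues=lam, n_channels=n_ch,
                    scheme_name=scheme_name, log_variance=log_variance)


def csp_features(covariances, model: CSPModel) -> np.ndarray:
    """Project epochs through the fitted CSP and reduce to features.

    Each component's band-filtered time course collapses to its variance,
    computed directly from the cached epoch covariance as
    diag(W @ Sigma @ W.T), normalized by the per-band sum over components,
    and (by default) log-transformed.  The per-epoch output is the
    flattened channels x bands matrix — 96 features for the 12-band
    scheme on 8 channels, i.e. a dimensionality reduction by a factor of
    1536 (the samples per track) relative to the band-filtered tensor.

    Parameters
    ----------
    covariances : ndarray, (n_epochs, n_bands, n_channels, n_channels)
    model : CSPModel

    Returns
    -------
    ndarray, shape (n_epochs, n_channels * n_bands)
        Component-major, band-minor layout ("c{channel}_b{band}").
    """
    cov = np.asarray(covariances)
    if cov.ndim == 3:  # single epoch
        cov = cov[None]
    if cov.shape[1] != model.n_bands or cov.shape[2] != model.n_channels:
        raise ValueError(
            f"covariance tensor {cov.shape[1:]} does not match the fitted "
            f"model ({model.n_bands} bands x {model.n_channels} channels)"
        )
    # var[e, b, i] = W[b] Sigma[e, b] W[b].T diagonal
    var = np.einsum("bic,ebcd,bid->ebi", model.W, cov, model.W)
    var = np.maximum(var, 1e-300)
    var = var / var.sum(axis=2, keepdims=True)
    if model.log_variance:
        var = np.log(var)
    # flatten component-major, band-minor: feature (i, b) -> i * n_bands + b
    return var.transpose(0, 2, 1).reshape(cov.shape[0], -1)


def feature_names(model: CSPModel):
    return [
        f"c{i + 1}_b{b + 1}"
        for i in range(model.n_channels)
        for b in range(model.n_bands)
    ]
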