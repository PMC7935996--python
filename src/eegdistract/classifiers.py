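"""Small scikit-learn-compatible classifiers for hyperparameter families
that the stock estimators do not cover.

``GaussianDiscriminant`` implements the six discriminant variants
(linear, quadratic, their diagonal-covariance forms, and pseudo-inverse
forms) with two regularizers: ``gamma`` shrinks each covariance toward
its own diagonal, ``delta`` zeroes linear coefficients with magnitude
below the threshold (an embedded feature selector, meaningful for the
linear variants).

``KernelNaiveBayes`` implements naive Bayes with either a per-feature
normal model or a per-feature kernel density estimate with a choice of
kernel (normal, box, epanechnikov, triangle) and bandwidth.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["GaussianDiscriminant", "KernelNaiveBayes"]

DISCRIM_TYPES = (
    "linear", "quadratic", "diagLinear", "diagQuadratic",
    "pseudoLinear", "pseudoQuadratic",
)


class GaussianDiscriminant(BaseEstimator, ClassifierMixin):
    """Gaussian discriminant analysis with selectable covariance model.

    Parameters
    ----------
    discrim_type : str
        'linear'/'pseudoLinear' share one pooled covariance,
        'quadratic'/'pseudoQuadratic' fit one per class, 'diag*' force the
        covariance diagonal.  'pseudo*' invert with the pseudo-inverse, so
        singular covariances are legal.
    gamma : float in [0, 1]
        Shrinkage of each covariance toward its diagonal:
        (1 - gamma) * S + gamma * diag(S).
    delta : float >= 0
        Linear-coefficient threshold: entries of the class-difference
        weight vector with |w| <= delta are zeroed (linear variants only).
    """

    def __init__(self, discrim_type="linear", gamma=0.0, delta=0.0):
        self.discrim_type = discrim_type
        self.gamma = gamma
        self.delta = delta

    def _regularize(self, S):
        return (1.0 - self.gamma) * S + self.gamma * np.diag(np.diag(S))

    def fit(self, X, y):
        if self.discrim_type not in DISCRIM_TYPES:
            raise ValueError(f"unknown discrim_type {self.discrim_type!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        diag = self.discrim_type.startswith("diag")
        pseudo = self.discrim_type.startswith("pseudo")
        quadratic = "uadratic" in self.discrim_type

        self.means_ = np.stack([X[y_idx == k].mean(axis=0)
                                for k in range(len(self.classes_))])
        self.priors_ = np.bincount(y_idx) / n

        covs = []
        for k in range(len(self.classes_)):
            Xk = X[y_idx == k] - self.means_[k]
            covs.append(Xk.T @ Xk)
        if quadratic:
            covs = [c / max(1, (y_idx == k).sum() - 1)
                    for k, c in enumerate(covs)]
        else:
            pooled = sum(covs) / max(1, n - len(self.classes_))
            covs = [pooled] * len(self.classes_)
        covs = [np.diag(np.diag(c)) if diag else self._regularize(c)
                for c in covs]

        inv = np.linalg.pinv if pseudo else None
        self._inv_covs, self._logdets = [], []
        for c in covs:
            c = c + 1e-12 * np.trace(c) / d * np.eye(d)
            if inv is None:
                try:
                    ic = np.linalg.inv(c)
                except np.linalg.LinAlgError:
                    ic = np.linalg.pinv(c)
            else:
                ic = inv(c)
            sign, logdet = np.linalg.slogdet(c)
            self._inv_covs.append(ic)
            self._logdets.append(logdet if sign > 0 else np.inf)

        # delta: threshold the linear class-difference weights
        self._keep = np.ones(d, dtype=bool)
        if not quadratic and self.delta > 0 and len(self.classes_) == 2:
            w = self._inv_covs[0] @ (self.means_[1] - self.means_[0])
            self._keep = np.abs(w) > self.delta
            if not self._keep.any():
                self._keep[np.argmax(np.abs(w))] = True
        return self

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            dx = (X - self.means_[k])[:, self._keep]
            ic = self._inv_covs[k][np.ix_(self._keep, self._keep)]
            maha = np.einsum("ij,jk,ik->i", dx, ic, dx)
            scores[:, k] = -0.5 * (maha + self._logdets[k]) + np.log(
                self.priors_[k]
            )
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def _kernel_density(u, kind):
    """Standard kernel functions K(u), u = (x - xi) / h."""
    if kind == "normal":
        return np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)
    if kind == "box":
        return 0.5 * (np.abs(u) <= 1)
    if kind == "epanechnikov":
        return 0.75 * np.maximum(1 - u**2, 0.0)
    if kind == "triangle":
        return np.maximum(1 - np.abs(u), 0.0)
    raise ValueError(f"unknown kernel {kind!r}")


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with normal or kernel-density per-feature likelihoods.

    Parameters
    ----------
    distribution : {'normal', 'kernel'}
    width : float or None
        Kernel bandwidth; None uses Silverman's rule per class/feature.
    kernel : {'normal', 'box', 'epanechnikov', 'triangle'}
    """

    def __init__(self, distribution="normal", width=None, kernel="normal"):
        self.distribution = distribution
        self.width = width
        self.kernel = kernel

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.priors_ = np.bincount(y_idx) / len(y)
        if self.distribution == "normal":
            self.means_ = np.stack([X[y_idx == k].mean(axis=0)
                                    for k in range(len(self.classes_))])
            self.vars_ = np.stack([X[y_idx == k].var(axis=0)
                                   for k in range(len(self.classes_))])
            self.vars_ = np.maximum(self.vars_, 1e-12 * self.vars_.max() + 1e-300)
        elif self.distribution == "kernel":
            self._train = [X[y_idx == k] for k in range(len(self.classes_))]
            self._widths = []
            for Xk in self._train:
                if self.width is not None:
                    h = np.full(Xk.shape[1], float(self.width))
                else:  # Silverman
                    s = Xk.std(axis=0)
                    h = 1.06 * np.maximum(s, 1e-12) * len(Xk) ** (-1 / 5)
                self._widths.append(h)
        else:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        ll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            if self.distribution == "normal":
                ll[:, k] = -0.5 * np.sum(
                    np.log(2 * np.pi * self.vars_[k])
                    + (X - self.means_[k]) ** 2 / self.vars_[k],
                    axis=1,
                )
            else:
                Xk, h = self._train[k], self._widths[k]
                # (n_test, n_train_k, n_feat) pairwise kernel evaluation
                u = (X[:, None, :] - Xk[None, :, :]) / h
                dens = _kernel_density(u, self.kernel).mean(axis=1) / h
                ll[:, k] = np.log(np.maximum(dens, 1e-300)).sum(axis=1)
            ll[:, k] += np.log(self.priors_[k])
        return ll

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]
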