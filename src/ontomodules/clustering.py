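"""Gaussian-mixture clustering of FPC scores with BIC model selection.

Genes are clustered in the plane of their first two functional principal
component scores by a full-covariance Gaussian mixture fitted by EM
(k-means++ initialisation, multiple restarts, fixed seed). The number of
modules k is chosen by minimising BIC = -2 logL + p ln(n) with
p = (k-1) + 2k + 3k free parameters for 2-D data (mixture weights, means,
symmetric covariances). Each gene is assigned to the component with the
highest posterior membership probability, and modules are relabelled
deterministically by decreasing size so labels are reproducible.

The EM loop is implemented here so that convergence (relative log-likelihood
change below 1e-8, at most 500 iterations), the covariance ridge floor and
the per-iteration monotone-likelihood check are exactly as documented;
scikit-learn's GaussianMixture serves as an independent cross-check in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

EM_RTOL = 1e-8
EM_MAX_ITER = 500


@dataclass
class BICTrace:
    k_values: list
    bic: np.ndarray
    chosen_k: int
    delta_bic: np.ndarray

    def frame(self) -> pd.DataFrame:
        d = np.concatenate([[np.nan], self.delta_bic])
        return pd.DataFrame({"k": self.k_values, "bic": self.bic, "delta_bic": d})


@dataclass
class ModuleAssignment:
    """Fitted mixture plus per-gene hard labels (1..k) and posteriors."""

    gene_ids: pd.Index | None
    labels: np.ndarray            # 1-based module index per gene
    membership: np.ndarray        # gene x k posterior probabilities
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    seed: int
    n_restarts: int

    @property
    def k(self) -> int:
        return self.membership.shape[1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": self.labels, "max_membership": self.membership.max(axis=1)},
            index=self.gene_ids,
        )


def ridge_floor(scores: np.ndarray) -> float:
    """Covariance regularisation floor: 1e-6 * trace(sample covariance) / d."""
    scores = np.asarray(scores, dtype=float)
    cov = np.cov(scores.T) if scores.shape[1] > 1 else np.var(scores, ddof=1)
    return 1e-6 * float(np.trace(np.atleast_2d(cov))) / scores.shape[1]


def _scores_array(scores) -> tuple[np.ndarray, pd.Index | None]:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), scores.index
    return np.asarray(scores, dtype=float), None


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, k) log-density of each point under each component (batched over k)."""
    d = X.shape[1]
    if d == 2:
        # closed-form 2x2 inverse/determinant avoids batched linalg overhead
        a, b, c = covs[:, 0, 0], covs[:, 0, 1], covs[:, 1, 1]
        det = a * c - b * b
        if (det <= 0).any():
            raise np.linalg.LinAlgError("non-positive-definite component covariance")
        d0 = X[:, 0, None] - means[None, :, 0]
        d1 = X[:, 1, None] - means[None, :, 1]
        maha = (c * d0 * d0 - 2.0 * b * d0 * d1 + a * d1 * d1) / det
        logdet = np.log(det)
    else:
        sign, logdet = np.linalg.slogdet(covs)
        if (sign <= 0).any():
            raise np.linalg.LinAlgError("non-positive-definite component covariance")
        inv = np.linalg.inv(covs)
        dev = X[:, None, :] - means[None, :, :]
        maha = np.einsum("nki,kij,nkj->nk", dev, inv, dev)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet[None, :] + maha)


def _em_step(X, weights, means, covs, reg):
    logp = _log_gauss(X, means, covs) + np.log(weights)
    mx = logp.max(axis=1)
    norm = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
    resp = np.exp(logp - norm[:, None])
    ll = float(norm.sum())
    nk = resp.sum(axis=0)
    weights = nk / len(X)
    means = resp.T @ X / nk[:, None]
    d = X.shape[1]
    if d == 2:
        x0, x1 = X[:, 0], X[:, 1]
        s00 = (x0 * x0) @ resp / nk - means[:, 0] ** 2
        s11 = (x1 * x1) @ resp / nk - means[:, 1] ** 2
        s01 = (x0 * x1) @ resp / nk - means[:, 0] * means[:, 1]
        covs = np.empty((len(nk), 2, 2))
        covs[:, 0, 0] = s00 + reg
        covs[:, 1, 1] = s11 + reg
        covs[:, 0, 1] = covs[:, 1, 0] = s01
    else:
        dev = X[:, None, :] - means[None, :, :]
        covs = np.einsum("nk,nki,nkj->kij", resp, dev, dev) / nk[:, None, None]
        covs += reg * np.eye(d)[None, :, :]
    return ll, resp, weights, means, covs


def _fit_single(X: np.ndarray, k: int, rng, reg: float):
    """One EM run from a k-means++ start; returns (logL, resp, params)."""
    n, d = X.shape
    centers, _ = kmeans_plusplus(X, k, random_state=rng)
    assign = np.argmin(((X[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1)
    weights = np.maximum(np.bincount(assign, minlength=k), 1) / n
    means = centers.copy()
    covs = np.empty((k, d, d))
    for j in range(k):
        pts = X[assign == j]
        covs[j] = (np.cov(pts.T) if len(pts) > d else np.cov(X.T)) + reg * np.eye(d)
    prev_ll = -np.inf
    # Pure EM is monotone; the ridge added to each covariance shifts the
    # M-step off the exact maximiser, which for a collapsing component can
    # lower the likelihood by an amount on the order of n * reg. Allow that
    # much slack plus rounding error.
    slack = 1e-7 * n * max(1.0, float(np.abs(X).max()) ** 2) + n * reg
    for _ in range(EM_MAX_ITER):
        ll, resp, weights, means, covs = _em_step(X, weights, means, covs, reg)
        assert ll >= prev_ll - slack, "EM log-likelihood decreased"
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < EM_RTOL * abs(prev_ll):
            break
        prev_ll = ll
    ll = float(logsumexp(_log_gauss(X, means, covs) + np.log(weights), axis=1).sum())
    return ll, resp, weights, means, covs


def fit_gmm(scores, k: int, n_restarts: int = 10, seed: int = 0,
            reg_covar: float | None = None) -> ModuleAssignment:
    """EM fit of a k-component full-covariance Gaussian mixture.

    Best of ``n_restarts`` k-means++-initialised runs by final log-likelihood.
    Ties in the posterior argmax resolve to the lower component index.
    """
    X, gene_ids = _scores_array(scores)
    if X.ndim == 1:
        X = X[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > np.unique(X, axis=0).shape[0]:
        raise ValueError(f"k={k} exceeds number of distinct points")
    reg = reg_covar if reg_covar is not None else ridge_floor(X)
    rngs = [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n_restarts)]
    best = None
    for rng in rngs:
        # forward a 32-bit seed to kmeans_plusplus for reproducibility
        fit = _fit_single(X, k, int(rng.integers(2**31)), reg)
        if best is None or fit[0] > best[0]:
            best = fit
    ll, resp, weights, means, covs = best
    labels = resp.argmax(axis=1) + 1  # argmax takes the lower index on ties
    return ModuleAssignment(
        gene_ids=gene_ids,
        labels=labels,
        membership=resp,
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=ll,
        seed=seed,
        n_restarts=n_restarts,
    )


def n_parameters(k: int, d: int = 2) -> int:
    """Free parameters of a k-component full-covariance mixture in d dims."""
    return (k - 1) + d * k + k * d * (d + 1) // 2


def bic(scores, ma: ModuleAssignment) -> float:
    """BIC = -2 logL + p ln(n)."""
    X, _ = _scores_array(scores)
    n, d = (X.shape if X.ndim == 2 else (len(X), 1))
    return -2.0 * ma.log_likelihood + n_parameters(ma.k, d) * np.log(n)


def select_k_by_bic(scores, k_range=range(2, 21), n_restarts: int = 10,
                    seed: int = 0) -> BICTrace:
    """Fit mixtures across ``k_range`` and choose k minimising BIC (ties -> smaller k)."""
    k_values = list(k_range)
    if not k_values:
        raise ValueError("k_range is empty")
    bics = np.array([bic(scores, fit_gmm(scores, k, n_restarts, seed)) for k in k_values])
    chosen = k_values[int(np.argmin(bics))]  # argmin takes the first (smaller k) on ties
    return BICTrace(k_values=k_values, bic=bics, chosen_k=chosen, delta_bic=np.diff(bics))


def assign_modules(ma: ModuleAssignment, module_alpha=None) -> ModuleAssignment:
    """Relabel mixture components deterministically as modules 1..k.

    Components are ordered by decreasing gene count; exact size ties break by
    decreasing module mean overall-expression alpha when provided (a mapping
    of original component index 1..k -> alpha), else by original index.
    """
    sizes = np.array([(ma.labels == j + 1).sum() for j in range(ma.k)])
    if module_alpha is not None:
        alphas = np.array([module_alpha.get(j + 1, 0.0) for j in range(ma.k)])
    else:
        alphas = np.zeros(ma.k)
    order = sorted(range(ma.k), key=lambda j: (-sizes[j], -alphas[j], j))
    relabel = np.empty(ma.k, dtype=int)
    for new, old in enumerate(order):
        relabel[old] = new + 1
    return ModuleAssignment(
        gene_ids=ma.gene_ids,
        labels=relabel[ma.labels - 1],
        membership=ma.membership[:, order],
        weights=ma.weights[order],
        means=ma.means[order],
        covariances=ma.covariances[order],
        log_likelihood=ma.log_likelihood,
        seed=ma.seed,
        n_restarts=ma.n_restarts,
    )
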