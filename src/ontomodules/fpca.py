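"""Functional PCA of expression trajectories on a dense regular time grid.

Each gene contributes one curve observed at the T ordered timepoints. On a
dense regular grid with uniform quadrature weights, functional PCA reduces to
ordinary PCA of the gene x timepoint matrix: the mean function is the
per-timepoint mean over genes, the eigenfunctions are eigenvectors of the
T x T sample covariance of the centered trajectories, and each gene's scores
are the inner products of its centered trajectory with the eigenfunctions.
An optional Gaussian presmoothing bandwidth is exposed for noisy input; it is
off by default because replicate averaging already suppresses noise here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FPCAResult:
    """Decomposition of a set of trajectories into mean + eigenfunctions.

    ``eigenfunctions`` has one row per retained component, orthonormal over
    the time grid; ``eigenvalues`` are sorted descending; ``varfrac`` is each
    retained component's fraction of *total* variance (so the full spectrum
    sums to 1); ``scores`` is gene x component with zero mean per component.
    """

    mean_curve: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    varfrac: np.ndarray
    total_variance: float
    eigenvalues_all: np.ndarray
    gene_ids: pd.Index | None = None

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]


def _as_matrix(em) -> tuple[np.ndarray, pd.Index | None]:
    if hasattr(em, "values") and isinstance(getattr(em, "values"), pd.DataFrame):
        return em.values.to_numpy(dtype=float), em.values.index
    if isinstance(em, pd.DataFrame):
        return em.to_numpy(dtype=float), em.index
    return np.asarray(em, dtype=float), None


def fit_fpca(em, n_components: int = 2, smooth_bandwidth: float | None = None) -> FPCAResult:
    """Fit FPCA to gene trajectories.

    Parameters
    ----------
    em
        ExpressionMatrix, DataFrame or (n_genes, T) array; no missing values.
    n_components
        Number of components to retain (1 <= n_components <= T).
    smooth_bandwidth
        Optional Gaussian kernel bandwidth (in grid units) applied to each
        trajectory before decomposition.

    The sign of each eigenfunction is fixed so its largest-magnitude entry is
    positive, making scores reproducible across platforms.
    """
    X, gene_ids = _as_matrix(em)
    n, T = X.shape
    if not 1 <= n_components <= T:
        raise ValueError(f"n_components must be in [1, {T}], got {n_components}")
    if np.isnan(X).any():
        raise ValueError("missing values in trajectory matrix")
    if smooth_bandwidth is not None:
        grid = np.arange(T)[:, None]
        K = np.exp(-0.5 * ((grid - grid.T) / smooth_bandwidth) ** 2)
        K /= K.sum(axis=1, keepdims=True)
        X = X @ K.T

    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    cov = Xc.T @ Xc / (n - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    # sign convention: largest-magnitude entry of each eigenfunction positive
    for j in range(T):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    total = float(w.sum())
    phi = v[:, :n_components].T
    scores = Xc @ phi.T
    return FPCAResult(
        mean_curve=mean_curve,
        eigenfunctions=phi,
        eigenvalues=w[:n_components],
        scores=scores,
        varfrac=w[:n_components] / total,
        total_variance=total,
        eigenvalues_all=w,
        gene_ids=gene_ids,
    )


def variance_explained(res: FPCAResult, j: int) -> float:
    """Cumulative fraction of total variance through component j (1-based)."""
    if not 1 <= j <= res.n_components:
        raise ValueError(f"component index {j} out of range 1..{res.n_components}")
    return float(res.varfrac[:j].sum())


def reconstruct(res: FPCAResult) -> np.ndarray:
    """Rebuild trajectories from mean curve + retained scores/eigenfunctions."""
    return res.mean_curve + res.scores @ res.eigenfunctions


def scores_frame(res: FPCAResult) -> pd.DataFrame:
    cols = [f"FPC{j + 1}" for j in range(res.n_components)]
    return pd.DataFrame(res.scores, index=res.gene_ids, columns=cols)
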