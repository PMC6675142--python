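"""Orthogonal cubic parameterisation of expression trajectories.

Each trajectory is summarised by four shape metrics from a least-squares fit
on an orthogonal cubic basis over the rescaled time grid: alpha (overall
expression level, equal to the profile mean because the constant basis column
is all ones), beta1 (linear trend), beta2 (quadratic curvature) and beta3
(cubic S-shape). Because the basis columns are mutually orthogonal the
coefficients are independent projections: dropping the cubic column leaves
alpha, beta1, beta2 unchanged. Module identity is validated by linear
discriminant analysis on the four metrics, and module-level coefficient
vectors are related by hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

COEF_NAMES = ("alpha", "beta1", "beta2", "beta3")


@dataclass
class CubicBasis:
    """Constant column of ones plus three orthogonal polynomial columns.

    The grid is timepoint index 1..T rescaled to [-1, 1]. Columns 1-3
    (degrees 1-3) are orthogonal to each other and to the constant, each
    scaled to Euclidean norm sqrt(T) so that coefficients are invariant to
    the grid scale and alpha stays in log2-CPM units.
    """

    grid: np.ndarray
    columns: np.ndarray  # (T, 4)

    @property
    def T(self) -> int:
        return self.columns.shape[0]


@dataclass
class CubicFit:
    alpha: float
    beta1: float
    beta2: float
    beta3: float
    rss: float

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.alpha, self.beta1, self.beta2, self.beta3])


def build_basis(T: int) -> CubicBasis:
    """Gram-Schmidt orthogonalisation of {1, t, t^2, t^3} on the rescaled grid."""
    if T < 4:
        raise ValueError("need at least 4 timepoints for a cubic basis")
    x = np.linspace(-1.0, 1.0, T)
    cols = [np.ones(T)]
    for deg in (1, 2, 3):
        v = x**deg
        for u in cols:
            v = v - (v @ u) / (u @ u) * u
        v = v / np.linalg.norm(v) * np.sqrt(T)
        cols.append(v)
    return CubicBasis(grid=x, columns=np.column_stack(cols))


def fit_cubic(profile, basis: CubicBasis) -> CubicFit:
    """Least-squares cubic fit; coefficients are orthogonal projections.

    Every basis column has squared norm T, so coef_j = <profile, col_j> / T
    and alpha equals the arithmetic mean of the profile exactly.
    """
    y = np.asarray(profile, dtype=float)
    if y.shape != (basis.T,):
        raise ValueError(f"profile length {y.shape} does not match basis T={basis.T}")
    coef = basis.columns.T @ y / basis.T
    resid = y - basis.columns @ coef
    return CubicFit(*coef, rss=float(resid @ resid))


def fit_genes(values: pd.DataFrame, basis: CubicBasis) -> pd.DataFrame:
    """Cubic shape metrics for every gene (rows) of a trajectory matrix."""
    X = values.to_numpy(dtype=float)
    coef = X @ basis.columns / basis.T
    resid = X - coef @ basis.columns.T
    out = pd.DataFrame(coef, index=values.index, columns=list(COEF_NAMES))
    out["rss"] = (resid**2).sum(axis=1)
    return out


def fit_module_trend(values: pd.DataFrame, labels, module: int,
                     basis: CubicBasis, pooled: bool = False) -> CubicFit:
    """Cubic fit to a module's mean trajectory.

    With an identical design for every member gene, fitting the pooled member
    points gives the same coefficients as fitting the mean trajectory; only
    the residual sum of squares differs, so ``pooled`` changes rss alone.
    """
    labels = pd.Series(np.asarray(labels), index=values.index)
    members = values.loc[labels == module]
    if members.empty:
        raise ValueError(f"module {module} is empty")
    fit = fit_cubic(members.mean(axis=0).to_numpy(), basis)
    if pooled:
        resid = members.to_numpy() - fit.coef @ basis.columns.T
        fit = CubicFit(fit.alpha, fit.beta1, fit.beta2, fit.beta3,
                       rss=float((resid**2).sum()))
    return fit


def module_trend_frame(values: pd.DataFrame, labels, basis: CubicBasis) -> pd.DataFrame:
    labels = np.asarray(labels)
    rows = {}
    for m in sorted(np.unique(labels)):
        fit = fit_module_trend(values, labels, m, basis)
        rows[m] = {**dict(zip(COEF_NAMES, fit.coef)), "rss": fit.rss,
                   "n_genes": int((labels == m).sum())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def discriminant_validation(params: pd.DataFrame, labels, cv: bool = False):
    """LDA of module identity from (alpha, beta1, beta2, beta3).

    Returns (accuracy, confusion matrix DataFrame, ridge_used flag). By
    default the accuracy is resubstitution (training-set) accuracy; with
    ``cv`` a stratified 5-fold cross-validated accuracy is reported instead.
    A singular pooled covariance falls back to a shrinkage estimator and is
    flagged.
    """
    X = params[list(COEF_NAMES)].to_numpy(dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("discriminant validation needs >= 2 modules")
    ridge_used = False
    lda = LinearDiscriminantAnalysis(solver="svd")
    try:
        lda.fit(X, y)
        pred = lda.predict(X)
    except np.linalg.LinAlgError:
        ridge_used = True
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(X, y)
        pred = lda.predict(X)
    if cv:
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        acc = float(np.mean(cross_val_score(
            lda, X, y, cv=StratifiedKFold(5, shuffle=True, random_state=0))))
    else:
        acc = float(np.mean(pred == y))
    mods = sorted(np.unique(y))
    conf = pd.DataFrame(0, index=mods, columns=mods)
    for t, p in zip(y, pred):
        conf.loc[t, p] += 1
    return acc, conf, ridge_used


@dataclass
class ModuleDendrogram:
    linkage: np.ndarray
    leaf_order: list
    labels: list
    newick: str


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}"
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_module_coefficients(module_coefs: pd.DataFrame,
                                method: str = "average") -> ModuleDendrogram:
    """Agglomerative clustering of module (alpha, beta) vectors.

    Euclidean distance, average linkage by default. The merge order is
    deterministic (scipy breaks distance ties by cluster index), and the leaf
    order follows the linkage traversal. The tree is also rendered as a
    Newick string with module labels.
    """
    if len(module_coefs) < 2:
        raise ValueError("need >= 2 modules to cluster")
    X = module_coefs[list(COEF_NAMES)].to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    labels = [f"M{m}" for m in module_coefs.index]
    tree = hierarchy.to_tree(Z)
    return ModuleDendrogram(
        linkage=Z,
        leaf_order=hierarchy.leaves_list(Z).tolist(),
        labels=labels,
        newick=_to_newick(tree, labels) + ";",
    )
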