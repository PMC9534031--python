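"""Pattern analysis: hierarchical clustering and PCA biplot of BLUP profiles.

Families (or family x treatment entries) are clustered on their standardized
multi-trait BLUP profiles by Ward's minimum-variance hierarchical
agglomeration — the natural companion of the squared Euclidean dissimilarity,
chosen because the traits mix incommensurate units (mg, %, ratio).  The
number of groups is chosen by the classical Hartigan stopping rule: the
smallest k with

    H(k) = (n - k - 1) * (W_k / W_{k+1} - 1) <= 10,

where W_k is the total within-group sum of squares at k groups.

The biplot comes from an eigendecomposition of the trait correlation matrix;
scores are the standardized data projected on the eigenvectors, loadings the
eigenvectors scaled by the square-rooted eigenvalues (so acute angles between
loading vectors indicate positively correlated traits), and variance
proportions the eigenvalues over their sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

HARTIGAN_THRESHOLD = 10.0


@dataclass
class ClusterResult:
    assignments: pd.Series
    k: int
    wss: dict  # k -> total within-group sum of squares


@dataclass
class BiplotResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_proportions: np.ndarray


def standardize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance columns; constant columns excluded with warning."""
    matrix = matrix.dropna()
    sd = matrix.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant column(s) {constant} excluded", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    if matrix.shape[1] == 0:
        raise ValueError("no non-constant columns remain")
    return (matrix - matrix.mean()) / sd


def _within_ss(z: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in np.unique(labels):
        block = z[labels == g]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def hierarchical_cluster(
    matrix: pd.DataFrame, k: int, k_max: int | None = None
) -> ClusterResult:
    """Cut the Ward merge tree at ``k`` groups; also returns the WSS curve.

    ``matrix`` rows are entries (families), columns traits; columns are
    standardized internally.  ``k_max`` bounds the WSS curve (default
    min(10, n-1) or k, whichever is larger).
    """
    try:
        z = standardize_columns(matrix)
    except ValueError:
        # all points identical: a single degenerate merge chain
        warnings.warn("all entries identical; any cut yields identical groups",
                      stacklevel=2)
        z = pd.DataFrame(0.0, index=matrix.dropna().index, columns=matrix.columns)
    n = len(z)
    if n < 2:
        raise ValueError("need at least two entries to cluster")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    link = hierarchy.linkage(z.to_numpy(), method="ward")
    if k_max is None:
        k_max = max(k, min(10, n - 1))
    wss = {}
    zv = z.to_numpy()
    for kk in range(1, min(k_max, n) + 1):
        labels = hierarchy.fcluster(link, t=kk, criterion="maxclust")
        wss[kk] = _within_ss(zv, labels)
    assignments = pd.Series(
        hierarchy.fcluster(link, t=k, criterion="maxclust"),
        index=z.index,
        name="group",
    )
    return ClusterResult(assignments=assignments, k=k, wss=wss)


def hartigan_optimal_k(
    wss, n: int, threshold: float = HARTIGAN_THRESHOLD
) -> int:
    """Smallest k whose Hartigan statistic drops to the threshold.

    ``wss`` is the sequence W_1, W_2, ... of within-group sums of squares
    (non-increasing in k); ``n`` the number of entries.  Returns len(wss) if
    no k satisfies the rule within the sequence.
    """
    wss = list(wss)
    if len(wss) < 2:
        raise ValueError("need the WSS for at least two values of k")
    if any(b > a + 1e-9 * max(1.0, abs(a)) for a, b in zip(wss, wss[1:])):
        raise ValueError("WSS sequence must be non-increasing in k")
    for k in range(1, len(wss)):
        w_k, w_next = wss[k - 1], wss[k]
        if w_next == 0:
            h = 0.0 if w_k == 0 else np.inf
        else:
            h = (n - k - 1) * (w_k / w_next - 1.0)
        if h <= threshold:
            return k
    return len(wss)


def optimal_cluster(
    matrix: pd.DataFrame,
    k_max: int | None = None,
    threshold: float = HARTIGAN_THRESHOLD,
) -> ClusterResult:
    """Cluster with k chosen by the Hartigan rule on the Ward WSS curve."""
    n = len(matrix.dropna())
    if k_max is None:
        k_max = min(10, n - 1)
    probe = hierarchical_cluster(matrix, k=1, k_max=k_max)
    wss_seq = [probe.wss[k] for k in sorted(probe.wss)]
    k = hartigan_optimal_k(wss_seq, n, threshold)
    result = hierarchical_cluster(matrix, k=k, k_max=k_max)
    return result


def pca_biplot(matrix: pd.DataFrame, n_components: int = 2) -> BiplotResult:
    """PCA of the trait correlation matrix with biplot coordinates.

    Eigenvector signs are fixed so the largest-magnitude loading of each
    component is positive, making outputs reproducible across BLAS builds.
    """
    z = standardize_columns(matrix)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need at least two entries and two non-constant traits")
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    proportions = eigvals / eigvals.sum()
    n_components = min(n_components, z.shape[1])
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs[:, :n_components], index=z.index, columns=pcs
    )
    loadings = pd.DataFrame(
        eigvecs[:, :n_components] * np.sqrt(eigvals[:n_components]),
        index=z.columns,
        columns=pcs,
    )
    return BiplotResult(
        scores=scores, loadings=loadings, variance_proportions=proportions
    )
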