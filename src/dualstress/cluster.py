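"""Hierarchical clustering of expression profiles and treatments.

Probe clustering: each probe's six treatment-by-time expected values are
standardised (z-score per cell by default; a principal-component-score
variant is available behind the same switch, since the source description
of the standardisation is ambiguous), then clustered with Euclidean
distance and Ward linkage.  Assignments are reported at the candidate
levels 3, 6, 9 and 12 with their merge-height gaps; the default cut is 6.

Treatment clustering: Eisen-style agglomeration of treatment columns using
Pearson-correlation distance (1 - r) or a covariance-based distance, with
single/complete/average/ward linkage.  Default is pearson + average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError

__all__ = [
    "LinkageTree",
    "ClusterAssignment",
    "cluster_probes",
    "cluster_treatments",
    "variance_scree",
    "to_newick",
]


@dataclass
class LinkageTree:
    """A scipy linkage matrix plus its leaf labels."""

    merges: np.ndarray            # scipy (n-1, 4) linkage matrix
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def newick(self) -> str:
        return to_newick(self.merges, self.labels)


@dataclass
class ClusterAssignment:
    k: int
    labels: pd.Series             # leaf -> cluster id in 1..k
    mean_profiles: pd.DataFrame   # cluster x feature means
    candidates: pd.DataFrame      # k, merge gap, relative gap
    degenerate: bool = False


def _gap_table(Z: np.ndarray, ks) -> pd.DataFrame:
    n = Z.shape[0] + 1
    h = Z[:, 2]
    rows = []
    for k in ks:
        if not 2 <= k <= n - 1:
            rows.append((k, np.nan, np.nan))
            continue
        upper = h[n - k - 1]          # height of the merge that destroys k clusters
        lower = h[n - k - 2] if n - k - 2 >= 0 else 0.0
        gap = upper - lower
        rows.append((k, gap, gap / upper if upper > 0 else np.nan))
    return pd.DataFrame(rows, columns=["k", "gap", "relative_gap"])


def cluster_probes(
    vectors: pd.DataFrame,
    standardize: str = "zscore",
    k: int = 6,
    candidate_ks: tuple[int, ...] = (3, 6, 9, 12),
) -> tuple[LinkageTree, ClusterAssignment]:
    """Ward-cluster per-probe expression vectors (rows = probes).

    Rows containing NaN must be excluded by the caller; fewer than two
    complete vectors is an error.
    """
    V = vectors.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValidationError("vectors contain missing values; exclude them upstream")
    if V.shape[0] < 2:
        raise ValidationError("need at least 2 complete vectors to cluster")
    if standardize == "zscore":
        sd = V.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (V - V.mean(axis=0)) / sd
    elif standardize == "pca":
        sd = V.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (V - V.mean(axis=0)) / sd
        _, _, vt = np.linalg.svd(Xs, full_matrices=False)
        Z = Xs @ vt.T
    elif standardize == "none":
        Z = V
    else:
        raise ValidationError(f"unknown standardize option {standardize!r}")

    merges = hierarchy.linkage(Z, method="ward")
    tree = LinkageTree(merges, list(vectors.index))
    k_eff = min(k, V.shape[0])
    labels = pd.Series(
        hierarchy.fcluster(merges, t=k_eff, criterion="maxclust"),
        index=vectors.index, name="cluster",
    )
    means = vectors.groupby(labels).mean()
    means.index.name = "cluster"
    degenerate = bool(np.allclose(merges[:, 2], 0.0))
    assign = ClusterAssignment(k_eff, labels, means,
                               _gap_table(merges, candidate_ks), degenerate)
    return tree, assign


def _pearson_distance(M: pd.DataFrame) -> np.ndarray:
    sd = M.std(ddof=1)
    zero = sd.index[~(sd > 0)]
    if len(zero):
        raise ValidationError(
            f"zero-variance column(s) make correlations undefined: {list(zero)}"
        )
    r = M.corr(method="pearson", min_periods=2).to_numpy()
    return 1.0 - r


def _covariance_distance(M: pd.DataFrame) -> np.ndarray:
    """Covariance similarity turned into a distance: max(cov) - cov."""
    c = M.cov().to_numpy()
    return c.max() - c


def cluster_treatments(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
) -> LinkageTree:
    """Cluster treatment columns of a gene x treatment expression matrix.

    Genes with missing values are handled pairwise-complete via pandas'
    corr/cov.  ``distance`` is ``pearson`` (1 - r) or ``covariance``.
    """
    if matrix.shape[1] < 3:
        raise ValidationError("need at least 3 treatment columns")
    if linkage not in ("single", "complete", "average", "ward"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    if distance == "pearson":
        D = _pearson_distance(matrix)
    elif distance == "covariance":
        D = _covariance_distance(matrix)
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    if not np.all(np.isfinite(D)):
        raise ValidationError("distance matrix contains non-finite entries "
                              "(insufficient pairwise-complete data?)")
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    merges = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return LinkageTree(merges, list(matrix.columns))


def variance_scree(matrix: pd.DataFrame, target: float = 0.85):
    """Eigenvalue scree of the column covariance matrix.

    Returns ``(eigenvalues desc, cumulative fractions, suggested k)`` where
    the suggestion is the smallest k whose cumulative variance fraction
    reaches ``target``.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValidationError("need a numeric matrix with >= 2 columns")
    if not np.all(np.isfinite(M)):
        raise ValidationError("matrix contains non-finite entries")
    C = np.cov(M, rowvar=False, ddof=1)
    vals = np.linalg.eigvalsh(C)[::-1]
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    cum = np.cumsum(vals) / total if total > 0 else np.ones_like(vals)
    k = int(np.searchsorted(cum, target - 1e-12) + 1)
    return vals, cum, min(k, len(vals))


def to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch lengths."""
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    for r in range(Z.shape[0]):
        height[n + r] = Z[r, 2]

    def render(node: int) -> str:
        if node < n:
            return str(labels[node])
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height[node]
        return (f"({render(a)}:{h - height[a]:.6g},"
                f"{render(b)}:{h - height[b]:.6g})")

    return render(n + Z.shape[0] - 1) + ";"
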