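"""Semantic clustering analysis: Ward tree, pruning-height sweep, silhouettes,
and within-cluster form-meaning correlations.

The semantic vectors are clustered bottom-up with Ward's minimum-variance
criterion on Euclidean distance.  Flat solutions are obtained by cutting the
dendrogram at a pruning height expressed as a percentage of the largest merge
height (0% = every sign its own cluster, 100% = one cluster).  Each solution
is scored with the mean silhouette, and the semantic-phonological correlation
is recomputed using only sign pairs that do not cross cluster boundaries,
pooled over clusters into a single Pearson correlation per parameter scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score as _sk_silhouette

from .errors import ParameterError
from .pairwise import DEFAULT_ALPHA, CorrelationResult, _StreamingPearson
from .phonology import cosine_matrix
from .semantics import AlignedLexicon

logger = logging.getLogger(__name__)

DEFAULT_HEIGHTS: tuple[int, ...] = tuple(range(1, 101))


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage-matrix form."""

    Z: np.ndarray  # (n-1, 4): node a, node b, merge height, new size
    n_leaves: int
    max_height: float

    @property
    def merge_list(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.Z]


@dataclass
class ClusterSolution:
    """Flat clustering obtained by cutting the tree at one pruning height."""

    height_percent: float
    cut_height: float
    labels: np.ndarray  # per-sign cluster id, 0-based, ordered by smallest member
    n_clusters: int
    silhouette: float | None = None


def ward_linkage(vectors: np.ndarray) -> LinkageTree:
    """Ward's-method agglomerative linkage on Euclidean distance.

    Merge heights are non-decreasing (Ward is monotone) and deterministic;
    ties in merge cost are resolved by scipy's nearest-neighbor-chain order.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ParameterError("ward_linkage needs a 2-d matrix with at least 2 rows")
    Z = linkage(vectors, method="ward")
    return LinkageTree(Z=Z, n_leaves=vectors.shape[0], max_height=float(Z[:, 2].max()))


def _stable_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 in order of their smallest member index."""
    order: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def cut_at_percent(tree: LinkageTree, height_percent: float) -> ClusterSolution:
    """Cut the dendrogram at ``height_percent`` of the maximum merge height."""
    if not 0 <= height_percent <= 100:
        raise ParameterError(f"height_percent={height_percent} outside [0, 100]")
    cut = height_percent / 100.0 * tree.max_height
    if height_percent == 0:
        labels = np.arange(tree.n_leaves)
    else:
        labels = _stable_labels(fcluster(tree.Z, t=cut, criterion="distance"))
    return ClusterSolution(
        height_percent=float(height_percent),
        cut_height=float(cut),
        labels=labels,
        n_clusters=int(labels.max()) + 1,
    )


def silhouette(X: np.ndarray, labels: np.ndarray, *, precomputed: bool = False) -> float:
    """Mean silhouette score with Euclidean distance, or NaN when undefined.

    Per point: (b - a) / max(a, b), where a is the mean distance to the
    point's own cluster and b the smallest mean distance to another cluster;
    singleton points contribute 0.  Undefined (NaN) for a single cluster or
    when every cluster is a singleton.
    """
    labels = np.asarray(labels)
    n = labels.size
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        return float("nan")
    return float(
        _sk_silhouette(X, labels, metric="precomputed" if precomputed else "euclidean")
    )


def within_cluster_pairs(sol: ClusterSolution) -> np.ndarray:
    """All unordered sign pairs that do not cross cluster boundaries.

    Returns an (m, 2) index array in lexicographic order;
    m = sum over clusters c of s_c (s_c - 1) / 2, possibly zero.
    """
    blocks = []
    for c in range(sol.n_clusters):
        idx = np.flatnonzero(sol.labels == c)
        if idx.size >= 2:
            iu = np.triu_indices(idx.size, k=1)
            blocks.append(np.column_stack((idx[iu[0]], idx[iu[1]])))
    if not blocks:
        return np.empty((0, 2), dtype=int)
    pairs = np.concatenate(blocks)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def height_for_cluster_count(
    tree: LinkageTree, k: int, heights: Iterable[float] = DEFAULT_HEIGHTS
) -> float:
    """Pruning height (percent) whose cut yields the cluster count closest to *k*.

    Ties resolve to the smaller height.  Used to locate the generative
    granularity of synthetic lexicons with a known number of planted clusters.
    """
    heights = list(heights)
    counts = [cut_at_percent(tree, h).n_clusters for h in heights]
    best = min(range(len(heights)), key=lambda i: (abs(counts[i] - k), heights[i]))
    return heights[best]


@dataclass
class SweepResult:
    """Grid over (dimension, pruning height, scope) of cluster-level results."""

    grid: pd.DataFrame
    trees: dict[int, LinkageTree] = field(default_factory=dict)

    def silhouette_profile(self, dimension: int | None = None) -> pd.DataFrame:
        """Per-height silhouette and cluster count (one row per height)."""
        g = self.grid
        if dimension is not None:
            g = g[g["dimension"] == dimension]
        return (
            g.drop_duplicates(subset=["dimension", "height_percent"])
            [["dimension", "height_percent", "n_clusters", "silhouette"]]
            .reset_index(drop=True)
        )


def _pooled_within_correlation(
    S_sem: np.ndarray,
    S_phono: np.ndarray,
    sol: ClusterSolution,
    alpha: float,
    scope: str,
) -> CorrelationResult:
    acc = _StreamingPearson()
    for c in range(sol.n_clusters):
        idx = np.flatnonzero(sol.labels == c)
        if idx.size < 2:
            continue
        iu = np.triu_indices(idx.size, k=1)
        acc.update(S_sem[np.ix_(idx, idx)][iu], S_phono[np.ix_(idx, idx)][iu])
    return acc.result(alpha, scope)


def run_sweep(
    aligned: AlignedLexicon | Mapping[int, AlignedLexicon],
    heights: Sequence[float] = DEFAULT_HEIGHTS,
    scopes: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> SweepResult:
    """Cluster, score and correlate across the full (dimension, height, scope) grid.

    For each embedding dimension: build the Ward tree once, then for every
    pruning height cut the tree, compute the silhouette, pool the
    within-cluster pairs, and compute one pooled Pearson correlation per
    parameter scope.  Records with fewer than 3 within-cluster pairs keep
    their silhouette but carry an undefined (NaN) correlation.

    Full n-by-n similarity matrices are held per scope, so memory is
    quadratic in the lexicon size (fine up to a few thousand signs).
    """
    if isinstance(aligned, AlignedLexicon):
        aligned = {aligned.sem_vectors.shape[1]: aligned}
    rows = []
    trees: dict[int, LinkageTree] = {}
    for dim, al in aligned.items():
        use_scopes = list(scopes) if scopes is not None else list(al.phono_spaces)
        S_sem = cosine_matrix(al.sem_vectors)
        S_phono = {}
        for scope in use_scopes:
            space = al.phono_spaces[scope]
            M = space.reduced if space.reduced is not None else space.onehot
            S_phono[scope] = cosine_matrix(M)
        tree = ward_linkage(al.sem_vectors)
        trees[dim] = tree
        D = squareform(pdist(al.sem_vectors))
        for h in heights:
            sol = cut_at_percent(tree, h)
            sil = silhouette(D, sol.labels, precomputed=True)
            n_within = sum(
                s * (s - 1) // 2 for s in np.bincount(sol.labels) if s >= 2
            )
            for scope in use_scopes:
                res = _pooled_within_correlation(S_sem, S_phono[scope], sol, alpha, scope)
                rows.append(
                    {
                        "dimension": dim,
                        "height_percent": float(h),
                        "scope": scope,
                        "n_clusters": sol.n_clusters,
                        "silhouette": sil,
                        "n_within_pairs": int(n_within),
                        "r": res.r,
                        "df": res.df if not res.degenerate else np.nan,
                        "p": res.p,
                        "significant": res.significant,
                    }
                )
        logger.info("run_sweep: dimension %d done (%d heights)", dim, len(heights))
    return SweepResult(grid=pd.DataFrame(rows), trees=trees)


def extract_cluster(
    sol: ClusterSolution,
    al: AlignedLexicon,
    query_glosses: Sequence[str],
    scopes: Sequence[str] | None = None,
) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Clusters containing query glosses, with their within-cluster pair table.

    Supports post-hoc inspection of, say, body-part or kinship clusters:
    returns every cluster holding at least one query gloss, its full
    membership, and the within-cluster pair similarities per scope.
    """
    scopes = list(scopes) if scopes is not None else list(al.phono_spaces)
    glosses = al.glosses
    pos = {g: i for i, g in enumerate(glosses)}
    hit_clusters = sorted({int(sol.labels[pos[g]]) for g in query_glosses if g in pos})
    if not hit_clusters:
        logger.warning("extract_cluster: no query gloss found in the lexicon")
        return {}, pd.DataFrame(
            columns=["cluster", "gloss_i", "gloss_j", "sem_sim"]
            + [f"phono_sim_{s}" for s in scopes]
        )
    membership = {
        c: [glosses[i] for i in np.flatnonzero(sol.labels == c)] for c in hit_clusters
    }
    S_sem = cosine_matrix(al.sem_vectors)
    S_ph = {}
    for scope in scopes:
        space = al.phono_spaces[scope]
        M = space.reduced if space.reduced is not None else space.onehot
        S_ph[scope] = cosine_matrix(M)
    rows = []
    for c in hit_clusters:
        idx = np.flatnonzero(sol.labels == c)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                row = {
                    "cluster": c,
                    "gloss_i": glosses[i],
                    "gloss_j": glosses[j],
                    "sem_sim": S_sem[i, j],
                }
                for scope in scopes:
                    row[f"phono_sim_{scope}"] = S_ph[scope][i, j]
                rows.append(row)
    return membership, pd.DataFrame(rows)


class WardHeightClusterer(ClusterMixin, BaseEstimator):
    """Scikit-learn estimator: Ward clustering cut at a percentage pruning height.

    Parameters
    ----------
    height_percent : float, default 50.0
        Dendrogram cut height as a percentage of the maximum merge height.

    Attributes
    ----------
    labels_ : ndarray
        Cluster id per sample, ordered by smallest member index.
    n_clusters_ : int
    linkage_tree_ : LinkageTree
    """

    def __init__(self, height_percent: float = 50.0):
        self.height_percent = height_percent

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        tree = ward_linkage(X)
        sol = cut_at_percent(tree, self.height_percent)
        self.linkage_tree_ = tree
        self.labels_ = sol.labels
        self.n_clusters_ = sol.n_clusters
        self.n_features_in_ = X.shape[1]
        return self
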