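"""PhenoGraph-style phenoclustering of the cell x marker matrix.

The procedure: a k-nearest-neighbour graph (Euclidean distance on the
rescaled 0-1 marker intensities, default k = 30), re-weighted by the
Jaccard index of the two endpoints' neighbour sets, then Louvain
modularity community detection.  Louvain runs on igraph's C
implementation; determinism is obtained by visiting nodes in a
seed-derived random permutation.  2-D embeddings (tSNE / UMAP) are
produced by the standard implementations and are visualization-only —
no downstream computation depends on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

DEFAULT_K = 30


def knn_adjacency(X: np.ndarray, k: int = DEFAULT_K) -> sparse.csr_matrix:
    """Directed kNN adjacency (k out-neighbours per node, self excluded)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n <= k:
        raise ValueError(f"k exceeds sample size: k={k}, n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    for i in range(n):
        neigh = idx[i]
        neigh = neigh[neigh != i][:k]
        if len(neigh) < k:  # self not in list (duplicate points): drop one
            neigh = idx[i][:k]
        cols[i * k : (i + 1) * k] = neigh
    data = np.ones(n * k, dtype=np.int32)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_knn_jaccard_graph(X: np.ndarray, k: int = DEFAULT_K) -> sparse.csr_matrix:
    """Symmetric weighted graph: w(i,j) = Jaccard index of the kNN sets.

    The neighbour set of a cell is the cell itself plus its k nearest
    neighbours (so two cells with identical neighbourhoods get weight
    exactly 1).  Edges exist where i and j are kNN-linked in either
    direction; the weight is |N(i) & N(j)| / |N(i) | N(j)| =
    c / (2(k+1) - c); zero-weight edges are dropped.
    """
    A = knn_adjacency(X, k)
    M = ((A + A.T) > 0).astype(np.int8)
    A1 = (A + sparse.identity(A.shape[0], dtype=A.dtype, format="csr")).tocsr()
    C = (A1 @ A1.T).multiply(M).tocsr()
    C.setdiag(0)
    C.eliminate_zeros()
    W = C.astype(float)
    W.data = W.data / (2.0 * (k + 1) - W.data)
    W.eliminate_zeros()
    return W


def louvain_communities(graph: sparse.spmatrix, seed: int = 0) -> np.ndarray:
    """Louvain labels (0..C-1) for a symmetric weighted adjacency matrix.

    Deterministic given the seed: nodes are visited in a seed-derived
    permutation.  Communities are relabelled by decreasing size.  An
    empty graph yields an empty labelling.
    """
    W = sparse.csr_matrix(graph)
    n = W.shape[0]
    if n == 0:
        return np.array([], dtype=int)
    # igraph's community_multilevel consults igraph's global RNG; pin it so
    # identical (graph, seed) always yields the identical partition
    import random

    ig.set_random_number_generator(random.Random(int(seed) & 0x7FFFFFFF))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    P = sparse.csr_matrix(
        (np.ones(n), (perm, np.arange(n))), shape=(n, n)
    )
    Wp = (P @ W @ P.T).tocoo()
    mask = Wp.row < Wp.col
    edges = list(zip(Wp.row[mask].tolist(), Wp.col[mask].tolist()))
    weights = Wp.data[mask].tolist()
    g = ig.Graph(n=n, edges=edges)
    part = g.community_multilevel(weights=weights) if edges else ig.VertexClustering(
        g, list(range(n))
    )
    member_p = np.asarray(part.membership)
    labels = np.empty(n, dtype=int)
    labels[:] = member_p[perm]
    # relabel by decreasing community size (ties by first occurrence)
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=int)


def modularity(graph: sparse.spmatrix, labels: np.ndarray) -> float:
    W = sparse.csr_matrix(graph).tocoo()
    n = W.shape[0]
    g = ig.Graph(n=n)
    mask = W.row < W.col
    g.add_edges(list(zip(W.row[mask].tolist(), W.col[mask].tolist())))
    return float(g.modularity(list(labels), weights=W.data[mask].tolist()))


@dataclass
class ClusterResult:
    """Per-cell labels plus cluster-level summaries of one clustering run."""

    labels: np.ndarray
    cluster_means: pd.DataFrame
    cluster_sizes: pd.Series
    k_neighbors: int
    seed: int
    modularity: float = float("nan")
    embedding: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


class PhenoGraphClusterer(BaseEstimator, ClusterMixin):
    """sklearn-style estimator wrapping the kNN-Jaccard-Louvain procedure.

    Parameters
    ----------
    k : size of the nearest-neighbour set (default 30).
    seed : RNG seed controlling the Louvain node-visit order.
    """

    def __init__(self, k: int = DEFAULT_K, seed: int = 0):
        self.k = k
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        self.graph_ = build_knn_jaccard_graph(X, self.k)
        self.labels_ = louvain_communities(self.graph_, self.seed)
        self.modularity_ = modularity(self.graph_, self.labels_)
        sizes = pd.Series(self.labels_).value_counts().sort_index()
        self.cluster_sizes_ = sizes
        self.n_clusters_ = len(sizes)
        return self

    def result(self, table: pd.DataFrame | np.ndarray, markers: list[str] | None = None,
               embedding: pd.DataFrame | None = None) -> ClusterResult:
        means = cluster_mean_matrix(table, self.labels_, markers)
        return ClusterResult(self.labels_, means, self.cluster_sizes_, self.k,
                             self.seed, self.modularity_, embedding)


def embed(X: np.ndarray, method: str = "umap", seed: int = 0, **kwargs) -> np.ndarray:
    """2-D embedding for plotting (tsne or umap); deterministic per seed."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = kwargs.pop("perplexity", min(30.0, max(1.0, (n - 2) / 3.0)))
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity,
            init="random", **kwargs
        ).fit_transform(X)
    if method == "umap":
        import umap

        n_neighbors = kwargs.pop("n_neighbors", min(15, max(2, n - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return umap.UMAP(
                n_components=2, random_state=seed, n_neighbors=n_neighbors, **kwargs
            ).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r} (expected 'tsne' or 'umap')")


def cluster_mean_matrix(
    table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Row c = per-marker mean of the rescaled intensities over cluster c.

    Accepts a cell table (uses its ``<marker>_scaled`` columns) or a raw
    matrix.  Labels present in ``labels``'s range but empty are excluded
    with a warning.
    """
    if isinstance(table, pd.DataFrame):
        if markers is None:
            markers = [c[: -len("_scaled")] for c in table.columns if c.endswith("_scaled")]
        X = table[[f"{m}_scaled" for m in markers]].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        if markers is None:
            markers = [f"m{i}" for i in range(X.shape[1])]
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels are not aligned with the table rows")
    present = np.unique(labels)
    full = np.arange(labels.max() + 1) if len(labels) else np.array([], dtype=int)
    missing = sorted(set(full.tolist()) - set(present.tolist()))
    if missing:
        warnings.warn(f"cluster id(s) {missing} have zero cells; excluded")
    rows = {c: X[labels == c].mean(axis=0) for c in present}
    return pd.DataFrame.from_dict(rows, orient="index", columns=markers).sort_index()


def replicate_entropy(labels: np.ndarray, sample_ids: np.ndarray) -> pd.Series:
    """Shannon entropy of the sample composition of every cluster (nats)."""
    df = pd.DataFrame({"cluster": labels, "sample": sample_ids})
    out = {}
    for c, grp in df.groupby("cluster"):
        p = grp["sample"].value_counts(normalize=True).to_numpy()
        out[c] = float(-(p * np.log(p)).sum())
    return pd.Series(out).sort_index()
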