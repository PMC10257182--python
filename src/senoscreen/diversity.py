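"""Chemical-diversity quality control of the positive training compounds.

A training set mined from heterogeneous literature sources risks
over-representing particular chemical families.  Three complementary checks
quantify how clustered the positives really are:

* a k-means / silhouette curve under the cosine distance (no clear elbow and
  low silhouettes indicate diversity),
* a sparsified continuous-Tanimoto distance graph (minimum spanning tree
  united with a symmetrised k-nearest-neighbour graph) whose edge-distance
  distribution summarises pairwise dissimilarity, and
* a Louvain community-detection sweep over the resolution parameter γ, with
  the adjusted Rand index against the literature source labels measuring
  whether communities simply recover the data's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "CurveSummary",
    "SweepResult",
    "cosine_distance",
    "continuous_tanimoto_distance",
    "tanimoto_distance_matrix",
    "kmeans_diversity_curve",
    "build_diversity_graph",
    "graph_edge_summary",
    "louvain_sweep",
    "detect_plateaus",
    "adjusted_rand_index",
    "export_edge_list",
]


def cosine_distance(u, v) -> float:
    """1 − cos(u, v); in [0, 2]. Zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def continuous_tanimoto_distance(u, v) -> float:
    """Continuous Tanimoto distance 1 − u·v/(‖u‖² + ‖v‖² − u·v), clamped to [0, 1].

    Defined for non-negative feature vectors (rescale descriptors to [0, 1]
    per feature first; see :func:`senoscreen.featurisation.minmax_rescale`).
    Two all-zero vectors are defined to be at distance 0 by convention.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    denom = np.dot(u, u) + np.dot(v, v) - np.dot(u, v)
    if denom == 0:
        return 0.0
    return float(np.clip(1.0 - np.dot(u, v) / denom, 0.0, 1.0))


def tanimoto_distance_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise continuous Tanimoto distances between rows of X (and Y)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    dot = X @ Y.T
    sx = np.einsum("ij,ij->i", X, X)[:, None]
    sy = np.einsum("ij,ij->i", Y, Y)[None, :]
    denom = sx + sy - dot
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = 1.0 - np.where(denom > 0, dot / np.where(denom == 0, 1, denom), 1.0)
    return np.clip(dist, 0.0, 1.0)


@dataclass
class CurveSummary:
    """k-means score and mean silhouette as functions of k, over repeats."""

    k_values: list[int]
    score_mean: np.ndarray
    score_sd: np.ndarray
    silhouette_mean: np.ndarray  # NaN at k=1 where the silhouette is undefined
    silhouette_sd: np.ndarray


def _unit_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-norm rows cannot be clustered under cosine distance")
    return X / norms


def kmeans_diversity_curve(X, k_range, repeats: int = 100, seed: int = 0) -> CurveSummary:
    """k-means under the cosine distance, repeated with different initial seeds.

    Rows are normalised to unit length so Euclidean k-means performs
    spherical updates (‖u−v‖² = 2·cosine distance on the unit sphere).  The
    reported score is the within-cluster sum of point-to-centroid cosine
    distances, summed over clusters; the silhouette uses the same cosine
    distance and is averaged across compounds.
    """
    U = _unit_rows(X)
    n = U.shape[0]
    k_range = [int(k) for k in k_range]
    if max(k_range) > n:
        raise ValueError(f"k={max(k_range)} exceeds the {n} available rows")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repeats)

    score_m, score_s, sil_m, sil_s = [], [], [], []
    for k in k_range:
        scores, sils = [], []
        for rs in rep_seeds:
            km = KMeans(n_clusters=k, n_init=1, random_state=int(rs)).fit(U)
            labels = km.labels_
            score = 0.0
            for c in range(k):
                members = U[labels == c]
                centroid = members.mean(axis=0)
                cn = np.linalg.norm(centroid)
                if cn == 0:  # degenerate cluster centred at the origin
                    score += float(len(members))
                    continue
                score += float(np.sum(1.0 - members @ (centroid / cn)))
            scores.append(max(score, 0.0))
            if 2 <= k <= n - 1 and len(set(labels)) > 1:
                sils.append(silhouette_score(U, labels, metric="cosine"))
            else:
                sils.append(np.nan)
        score_m.append(np.mean(scores))
        score_s.append(np.std(scores))
        sil_m.append(np.nanmean(sils) if not np.all(np.isnan(sils)) else np.nan)
        sil_s.append(np.nanstd(sils) if not np.all(np.isnan(sils)) else np.nan)
    return CurveSummary(k_range, np.array(score_m), np.array(score_s),
                        np.array(sil_m), np.array(sil_s))


def build_diversity_graph(X, ids, k: int = 7, combine: str = "union") -> nx.Graph:
    """Sparsified continuous-Tanimoto graph over compounds.

    The complete pairwise distance graph is reduced to the minimum spanning
    tree combined with the symmetrised k-nearest-neighbour graph (an edge is
    kept if either endpoint ranks the other among its k nearest; rank ties
    break by id order).  ``combine='union'`` (default) keeps MST ∪ kNN so the
    graph is connected by construction; ``'intersection'`` keeps MST ∩ kNN
    for sensitivity checks.  Edges carry ``distance`` and ``similarity``
    (= 1 − distance) attributes.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = np.asarray(X, dtype=float)
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 compounds to build a graph")
    D = tanimoto_distance_matrix(X)

    complete = nx.Graph()
    complete.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            complete.add_edge(ids[i], ids[j], weight=float(D[i, j]))
    mst = nx.minimum_spanning_tree(complete, weight="weight")
    mst_edges = {frozenset(e) for e in mst.edges}

    knn_edges: set[frozenset] = set()
    for i in range(n):
        cand = [(float(D[i, j]), ids[j], j) for j in range(n) if j != i]
        cand.sort(key=lambda t: (t[0], t[1]))
        for _, _, j in cand[:k]:
            knn_edges.add(frozenset((ids[i], ids[j])))

    if combine == "union":
        edges = mst_edges | knn_edges
    elif combine == "intersection":
        edges = mst_edges & knn_edges
    else:
        raise ValueError("combine must be 'union' or 'intersection'")

    g = nx.Graph()
    g.add_nodes_from(ids)
    index = {cid: i for i, cid in enumerate(ids)}
    for e in edges:
        a, b = tuple(e)
        d = float(D[index[a], index[b]])
        g.add_edge(a, b, distance=d, similarity=1.0 - d)
    g.graph["knn_k"] = k
    g.graph["combine"] = combine
    g.graph["distance"] = "continuous_tanimoto"
    return g


def graph_edge_summary(g: nx.Graph, bins: int = 20) -> dict:
    """Edge count, median edge distance, and a distance histogram."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    dists = np.array([d["distance"] for _, _, d in g.edges(data=True)])
    hist, edges = np.histogram(dists, bins=bins, range=(0.0, 1.0))
    return {
        "n_edges": int(g.number_of_edges()),
        "median_distance": float(np.median(dists)) if dists.size else float("nan"),
        "histogram": {"counts": hist.tolist(), "bin_edges": edges.tolist()},
    }


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two labellings (1 = identical)."""
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError(f"labelling lengths differ: {len(a)} vs {len(b)}")
    return float(adjusted_rand_score(a, b))


@dataclass
class SweepResult:
    """Louvain community structure as a function of the resolution γ."""

    gamma_grid: np.ndarray
    n_clusters_mean: np.ndarray
    n_clusters_sd: np.ndarray
    ari_mean: np.ndarray | None = None  # vs a reference labelling, if given
    plateaus: list[dict] = field(default_factory=list)


def louvain_sweep(
    g: nx.Graph,
    gamma_grid,
    runs: int = 100,
    seed: int = 0,
    reference_labels: dict | None = None,
) -> SweepResult:
    """Louvain community detection across a γ grid, repeated with fresh seeds.

    Modularity is computed on similarity weights (1 − Tanimoto distance);
    γ multiplies the null-model term, so larger γ yields more, smaller
    communities.  If ``reference_labels`` maps node → label, the mean ARI
    between each run's partition and the reference is reported per γ.
    """
    gamma_grid = np.asarray(list(gamma_grid), dtype=float)
    if gamma_grid.size == 0:
        raise ValueError("gamma_grid is empty")
    nodes = list(g.nodes)
    rng = np.random.default_rng(seed)
    run_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=runs)]

    counts_m, counts_s, aris = [], [], []
    for gamma in gamma_grid:
        counts, run_aris = [], []
        for rs in run_seeds:
            comms = nx.community.louvain_communities(
                g, weight="similarity", resolution=float(gamma), seed=rs
            )
            counts.append(len(comms))
            if reference_labels is not None:
                node_to_comm = {v: ci for ci, comm in enumerate(comms) for v in comm}
                run_aris.append(adjusted_rand_index(
                    [reference_labels[v] for v in nodes],
                    [node_to_comm[v] for v in nodes],
                ))
        counts_m.append(np.mean(counts))
        counts_s.append(np.std(counts))
        if reference_labels is not None:
            aris.append(np.mean(run_aris))
    return SweepResult(
        gamma_grid=gamma_grid,
        n_clusters_mean=np.array(counts_m),
        n_clusters_sd=np.array(counts_s),
        ari_mean=np.array(aris) if reference_labels is not None else None,
    )


def detect_plateaus(sweep: SweepResult, min_width: float) -> list[dict]:
    """Maximal γ intervals where the rounded mean cluster count is constant.

    Returns plateaus of width ≥ ``min_width`` in γ order, each as
    ``{"gamma_lo", "gamma_hi", "n_clusters"}``.
    """
    gg = sweep.gamma_grid
    if gg.size < 2:
        raise ValueError("sweep needs at least two gamma points")
    rounded = np.round(sweep.n_clusters_mean).astype(int)
    plateaus = []
    start = 0
    for i in range(1, len(gg) + 1):
        if i == len(gg) or rounded[i] != rounded[start]:
            width = gg[i - 1] - gg[start]
            if width >= min_width:
                plateaus.append({
                    "gamma_lo": float(gg[start]),
                    "gamma_hi": float(gg[i - 1]),
                    "n_clusters": int(rounded[start]),
                })
            start = i
    sweep.plateaus = plateaus
    return plateaus


def export_edge_list(g: nx.Graph, path) -> None:
    """Write the graph as an edge-list CSV (source, target, distance)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "distance"])
        for a, b, d in g.edges(data=True):
            w.writerow([a, b, f"{d['distance']:.6f}"])
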