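"""K-means over electrogram waveforms with metric-matched centroid rules.

Regionalization of cardiac tissue clusters the per-node single-beat
waveforms under one of four distances, each paired with the centroid
update that minimizes its intra-cluster objective:

* L2: squared Euclidean norm; centroid = mean.
* L1: sum of absolute differences; centroid = per-coordinate median.
* cosine: 1 - cos(x, c); centroid = mean of unit-normalized members.
* correlation: 1 - corr(x, c); centroid = mean of zero-mean, unit-norm
  members.

Cosine and correlation are scale- (and, for correlation, offset-)
invariant, which is what makes them suit smoothly varying electrogram
morphology: nearby nodes share shape while amplitude drifts with
distance.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import SurfaceMesh, build_adjacency

log = logging.getLogger(__name__)

METRICS = ("l1", "l2", "cosine", "correlation")
_DEGENERATE_DISTANCE = 1.0  # fallback for zero-norm / constant vectors


@dataclasses.dataclass
class ClusterConfig:
    K: int = 4
    metric: str = "cosine"
    max_iter: int = 300
    n_restarts: int = 10
    rng_seed: int = 0
    tol: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclasses.dataclass
class ClusterResult:
    centroids: np.ndarray        # (K, n)
    labels: np.ndarray           # (m,)
    objective_trace: np.ndarray  # per-iteration total intra-cluster distance
    metric: str
    n_iter: int = 0


def _unit(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=-1, keepdims=True)
    out = np.divide(X, norms, out=np.zeros_like(X, dtype=float),
                    where=norms > 0)
    return out


def _center_unit(X: np.ndarray) -> np.ndarray:
    return _unit(X - X.mean(axis=-1, keepdims=True))


def distance(x: np.ndarray, c: np.ndarray, metric: str) -> float:
    """Distance between one observation and one centroid under ``metric``.

    L2 is the *squared* Euclidean norm.  A zero-norm vector under cosine
    (or a constant vector under correlation) gets the defined fallback
    distance 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError("vectors must have equal length")
    if metric == "l2":
        d = x - c
        return float(d @ d)
    if metric == "l1":
        return float(np.abs(x - c).sum())
    if metric == "cosine":
        nx, nc = np.linalg.norm(x), np.linalg.norm(c)
        if nx == 0 or nc == 0:
            log.warning("cosine distance: zero-norm vector, returning 1")
            return _DEGENERATE_DISTANCE
        return float(1.0 - (x @ c) / (nx * nc))
    if metric == "correlation":
        xc, cc = x - x.mean(), c - c.mean()
        nx, nc = np.linalg.norm(xc), np.linalg.norm(cc)
        if nx == 0 or nc == 0:
            log.warning("correlation distance: constant vector, returning 1")
            return _DEGENERATE_DISTANCE
        return float(1.0 - (xc @ cc) / (nx * nc))
    raise ValueError(f"unknown metric {metric!r}")


def _distance_matrix(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    """(m, K) distances, vectorized; degenerate rows/centroids get 1."""
    if metric == "l2":
        return cdist(X, C, "sqeuclidean")
    if metric == "l1":
        return cdist(X, C, "cityblock")
    if metric == "cosine":
        Xn, Cn = _unit(X), _unit(C)
    elif metric == "correlation":
        Xn, Cn = _center_unit(X), _center_unit(C)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sim = Xn @ Cn.T
    degenerate = (np.linalg.norm(Xn, axis=1) == 0)[:, None] | \
                 (np.linalg.norm(Cn, axis=1) == 0)[None, :]
    dist = 1.0 - sim
    dist[degenerate] = _DEGENERATE_DISTANCE
    return dist


def update_centroids(X: np.ndarray, labels: np.ndarray, metric: str,
                     K: int | None = None) -> np.ndarray:
    """Metric-matched centroid update.

    Empty clusters are re-seeded with the observation farthest from its
    own centroid (logged), so every centroid stays data-supported.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    K = int(labels.max()) + 1 if K is None else K
    if metric == "cosine":
        source = _unit(X)
    elif metric == "correlation":
        source = _center_unit(X)
    else:
        source = X
    centroids = np.zeros((K, X.shape[1]))
    empty = []
    for k in range(K):
        members = source[labels == k]
        if members.shape[0] == 0:
            empty.append(k)
            continue
        if metric == "l1":
            centroids[k] = np.median(members, axis=0)
        else:
            centroids[k] = members.mean(axis=0)
    if empty:
        dists = _distance_matrix(X, centroids, metric)
        per_point = dists[np.arange(X.shape[0]), np.clip(labels, 0, K - 1)]
        order = np.argsort(-per_point)
        for j, k in enumerate(empty):
            idx = order[j % X.shape[0]]
            centroids[k] = source[idx]
            log.warning("cluster %d empty; re-seeded with observation %d", k, idx)
    return centroids


def _objective(X: np.ndarray, C: np.ndarray, labels: np.ndarray,
               metric: str) -> float:
    d = _distance_matrix(X, C, metric)
    return float(d[np.arange(X.shape[0]), labels].sum())


def _init_centroids(X: np.ndarray, K: int, metric: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++-style) seeding from the data."""
    m = X.shape[0]
    first = int(rng.integers(m))
    chosen = [first]
    for _ in range(1, K):
        C = X[chosen]
        d = _distance_matrix(X, C, metric).min(axis=1)
        d = np.maximum(d, 0.0)
        total = d.sum()
        if total == 0:
            probs = np.full(m, 1.0 / m)
        else:
            probs = d / total
        chosen.append(int(rng.choice(m, p=probs)))
    if metric == "cosine":
        return _unit(X[chosen]).copy()
    if metric == "correlation":
        return _center_unit(X[chosen]).copy()
    return X[chosen].astype(float).copy()


def kmeans_fit(X: np.ndarray, cfg: ClusterConfig) -> ClusterResult:
    """Lloyd-style alternation of assignment and metric-matched update.

    Stops when labels no longer change or the objective improvement falls
    below ``tol``; keeps the best of ``n_restarts`` seeded restarts by
    final objective.  The objective trace is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (observations, features)")
    m = X.shape[0]
    if cfg.K > m:
        raise ValueError(f"K={cfg.K} exceeds number of observations {m}")
    master = np.random.default_rng(cfg.rng_seed)
    best: ClusterResult | None = None
    for _ in range(max(1, cfg.n_restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        C = _init_centroids(X, cfg.K, cfg.metric, rng)
        labels = np.argmin(_distance_matrix(X, C, cfg.metric), axis=1)
        trace = [_objective(X, C, labels, cfg.metric)]
        n_iter = 0
        for n_iter in range(1, cfg.max_iter + 1):
            C = update_centroids(X, labels, cfg.metric, cfg.K)
            new_labels = np.argmin(_distance_matrix(X, C, cfg.metric), axis=1)
            obj = _objective(X, C, new_labels, cfg.metric)
            trace.append(obj)
            if np.array_equal(new_labels, labels) or \
                    trace[-2] - obj <= cfg.tol:
                labels = new_labels
                break
            labels = new_labels
        result = ClusterResult(C, labels, np.asarray(trace), cfg.metric, n_iter)
        if best is None or result.objective_trace[-1] < best.objective_trace[-1]:
            best = result
    assert best is not None
    return best


def cluster_map(result: ClusterResult, mesh: SurfaceMesh
                ) -> tuple[np.ndarray, dict[int, int]]:
    """Map cluster labels onto the mesh for reporting.

    Labels are reindexed by descending cluster size (stable across runs up
    to genuine ties), and each cluster's number of edge-connected
    components is computed as a spatial-consistency diagnostic: a compact
    regionalization has one component per cluster.
    """
    labels = np.asarray(result.labels)
    if mesh.node_count == 0:
        return np.array([], dtype=np.int64), {}
    if labels.size != mesh.node_count:
        raise ValueError("one observation per mesh node required")
    K = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=K)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(K, dtype=np.int64)
    remap[order] = np.arange(K)
    new_labels = remap[labels]

    adjacency = build_adjacency(mesh)
    components: dict[int, int] = {}
    for k in range(K):
        nodes = set(np.flatnonzero(new_labels == k).tolist())
        n_comp = 0
        unseen = set(nodes)
        while unseen:
            n_comp += 1
            stack = [unseen.pop()]
            while stack:
                u = stack.pop()
                for v in adjacency[u]:
                    v = int(v)
                    if v in unseen:
                        unseen.discard(v)
                        stack.append(v)
        components[k] = n_comp
    return new_labels, components
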