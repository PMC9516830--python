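"""Density-based cluster validity (DBCV) index.

Scores a flat clustering by density connectedness: each cluster's density
sparseness (the largest edge of a minimum spanning tree built on mutual
reachability distances within the cluster) is compared with its density
separation from the other clusters (the smallest between-cluster mutual
reachability distance). The index is the cluster-size-weighted average of

    (min separation - sparseness) / max(min separation, sparseness)

and lies in [-1, 1]; higher means denser, better-separated clusters. Noise
points count in the denominator but belong to no cluster, so heavy noise
drags the score toward zero.

Mutual reachability uses the all-points core distance,

    core(x) = [ mean over y != x in the same cluster of (1/d(x,y))^dim ]^(-1/dim),

computed in log space to stay finite in high-dimensional embeddings. The
MST maximum is taken over all tree edges (a common simplification of the
internal-edge restriction).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

_EPS = 1e-12


def _core_distances(D: np.ndarray, dim: int) -> np.ndarray:
    """All-points core distance per point from a within-cluster distance
    matrix (log-space inverse-distance power mean)."""
    n = D.shape[0]
    if n < 2:
        return np.zeros(n)
    logD = np.log(np.maximum(D, _EPS))
    np.fill_diagonal(logD, np.nan)
    # log( mean_y (1/d)^dim ) = logsumexp(-dim * log d) - log(n-1)
    vals = -dim * logD
    vals[np.isnan(vals)] = -np.inf
    log_mean = logsumexp(vals, axis=1) - np.log(n - 1)
    return np.exp(-log_mean / dim)


def _mutual_reachability(D: np.ndarray, core: np.ndarray) -> np.ndarray:
    return np.maximum(D, np.maximum(core[:, None], core[None, :]))


def dbcv_score(X: np.ndarray, labels: np.ndarray) -> float:
    """DBCV index of a labelled point set; noise is labelled -1.

    Returns -1.0 for degenerate clusterings (fewer than two clusters, or
    every cluster smaller than two points), so invalid candidates lose any
    argmax selection over a hyperparameter grid.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n_total = len(labels)
    cluster_ids = [c for c in np.unique(labels) if c != -1]
    cluster_ids = [c for c in cluster_ids if np.sum(labels == c) >= 2]
    if len(cluster_ids) < 2:
        return -1.0
    dim = X.shape[1]

    cores: dict = {}
    sparseness: dict = {}
    members: dict = {}
    for c in cluster_ids:
        idx = np.flatnonzero(labels == c)
        members[c] = idx
        D = cdist(X[idx], X[idx])
        core = _core_distances(D, dim)
        cores[c] = core
        mreach = _mutual_reachability(D, core)
        mst = minimum_spanning_tree(np.triu(mreach)).toarray()
        sparseness[c] = float(mst.max()) if mst.size else 0.0

    validity = 0.0
    for c in cluster_ids:
        seps = []
        for other in cluster_ids:
            if other == c:
                continue
            D = cdist(X[members[c]], X[members[other]])
            m = np.maximum(D, np.maximum(cores[c][:, None], cores[other][None, :]))
            seps.append(float(m.min()))
        min_sep = min(seps)
        denom = max(min_sep, sparseness[c])
        vc = 0.0 if denom <= 0 else (min_sep - sparseness[c]) / denom
        validity += (len(members[c]) / n_total) * vc
    return float(validity)
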