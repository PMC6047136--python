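"""Unipartite link-prediction scores.

Two families of vertex-pair similarity indices, each returning a full score
matrix aligned to the graph's labels:

* neighborhood indices — common neighbors, Jaccard, cosine (Salton), hub
  promoted, hub depressed, Adamic-Adar, preferential attachment, resource
  allocation, Leicht-Holme-Newman;
* path-based metrics — local path (A^2 + eps*A^3), Katz, geodesic (1/d),
  random-walk hitting time, and random walk with restart.

All neighborhood indices operate on the binarized adjacency.  Ratio indices
define 0/0 = 0 so isolated nodes score zero instead of NaN; Adamic-Adar skips
degree-1 common neighbors (ln 1 = 0 would divide by zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .graph_core import ConvergenceError, UnipartiteGraph

NEIGHBORHOOD_METHODS = (
    "common_neighbors",
    "jaccard",
    "cosine",
    "hpi",
    "hdi",
    "adamic_adar",
    "pref_attach",
    "resource_alloc",
    "lhn",
)

#: sentinel for unreachable pairs in hitting-time matrices
INF = np.inf


@dataclass
class ScoreMatrixU:
    """Square score matrix aligned to a UnipartiteGraph's labels."""

    values: np.ndarray
    labels: list[str]
    method: str
    params: dict[str, float] = field(default_factory=dict)

    def score(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Entrywise num/den with 0/0 (and x/0) defined as 0."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den != 0)
    return out


def neighborhood_score(g: UnipartiteGraph, method: str) -> ScoreMatrixU:
    """One of the nine neighborhood indices on the binarized adjacency."""
    if method not in NEIGHBORHOOD_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {NEIGHBORHOOD_METHODS}")
    A = g.binary()
    k = A.sum(axis=1)
    CN = A @ A

    if method == "common_neighbors":
        S = CN
    elif method == "jaccard":
        union = k[:, None] + k[None, :] - CN
        S = _safe_div(CN, union)
    elif method == "cosine":
        S = _safe_div(CN, np.sqrt(np.outer(k, k)))
    elif method == "hpi":
        S = _safe_div(CN, np.minimum(k[:, None], k[None, :]))
    elif method == "hdi":
        S = _safe_div(CN, np.maximum(k[:, None], k[None, :]))
    elif method == "adamic_adar":
        w = np.zeros_like(k)
        mask = k > 1
        w[mask] = 1.0 / np.log(k[mask])
        S = A @ np.diag(w) @ A
    elif method == "pref_attach":
        S = np.outer(k, k)
    elif method == "resource_alloc":
        w = np.zeros_like(k)
        mask = k > 0
        w[mask] = 1.0 / k[mask]
        S = A @ np.diag(w) @ A
    else:  # lhn
        S = _safe_div(CN, np.outer(k, k))
    return ScoreMatrixU(S.astype(float), list(g.labels), method)


def local_path_score(g: UnipartiteGraph, epsilon: float = 0.01) -> ScoreMatrixU:
    """Local path index S = A^2 + eps * A^3 (2- and 3-step path counts)."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    A = g.binary()
    A2 = A @ A
    S = A2 + epsilon * (A2 @ A)
    return ScoreMatrixU(S, list(g.labels), "local_path", {"epsilon": epsilon})


def katz_score(g: UnipartiteGraph, beta: float = 0.01) -> ScoreMatrixU:
    """Katz index S = (I - beta*A)^-1 - I = sum_{l>=1} beta^l A^l.

    Requires beta < 1/rho(A) for the geometric series to converge.
    """
    A = g.binary()
    n = A.shape[0]
    rho = max(np.abs(np.linalg.eigvalsh(A))) if n else 0.0
    if rho > 0 and beta >= 1.0 / rho:
        raise ValueError(
            f"beta={beta} diverges: spectral radius rho(A)={rho:.6g} requires "
            f"beta < {1.0 / rho:.6g}"
        )
    S = np.linalg.inv(np.eye(n) - beta * A) - np.eye(n)
    return ScoreMatrixU(S, list(g.labels), "katz", {"beta": beta})


def geodesic_score(g: UnipartiteGraph) -> ScoreMatrixU:
    """Inverse shortest-path distance; 0 for unreachable pairs.

    Weighted graphs use edge weights as distances.
    """
    adj = g.adjacency if g.weighted else g.binary()
    D = _csgraph_sp(adj, method="D", directed=False, unweighted=False)
    with np.errstate(divide="ignore"):
        S = 1.0 / D
    S[~np.isfinite(S)] = 0.0
    np.fill_diagonal(S, 0.0)
    return ScoreMatrixU(S, list(g.labels), "geodesic")


def hitting_time(g: UnipartiteGraph) -> ScoreMatrixU:
    """Expected steps H[x, y] for a uniform random walk from x to reach y.

    Solved exactly per destination from the linear system
    ``H[x,y] = 1 + sum_{z in Gamma(x)} H[z,y] / k_x`` with ``H[y,y] = 0``;
    pairs in different components (and rows of isolated nodes) get +inf.
    The matrix is generally asymmetric.
    """
    A = g.binary()
    n = A.shape[0]
    k = A.sum(axis=1)
    H = np.full((n, n), INF)
    np.fill_diagonal(H, 0.0)
    # transition matrix over non-isolated nodes
    P = np.zeros((n, n))
    nz = k > 0
    P[nz] = A[nz] / k[nz, None]
    # solve per connected component
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(A > 0, directed=False)
    for ci in range(n_comp):
        idx = np.where(comp == ci)[0]
        if len(idx) < 2:
            continue
        Pc = P[np.ix_(idx, idx)]
        for jpos, _ in enumerate(idx):
            # remove destination row/col: (I - P_minus) h = 1
            mask = np.arange(len(idx)) != jpos
            M = np.eye(mask.sum()) - Pc[np.ix_(mask, mask)]
            h = np.linalg.solve(M, np.ones(mask.sum()))
            H[idx[mask], idx[jpos]] = h
    return ScoreMatrixU(H, list(g.labels), "hitting_time")


def rwr_unipartite(
    g: UnipartiteGraph,
    c: float = 0.3,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> ScoreMatrixU:
    """Random walk with restart: column s is the fixed point of
    ``p = (1-c) W' p + c e_s`` with W the row-normalized adjacency.

    Each returned column is a probability vector.  Restart probability ``c``
    defaults to 0.3.  Weighted graphs normalize by weight sums.
    """
    if not 0 < c < 1:
        raise ValueError("restart probability c must be in (0, 1)")
    adj = g.adjacency if g.weighted else g.binary()
    n = adj.shape[0]
    rowsum = adj.sum(axis=1)
    W = np.zeros((n, n))
    nz = rowsum > 0
    W[nz] = adj[nz] / rowsum[nz, None]
    # isolated nodes: walker stays put so the column remains a point mass
    W[~nz, ~nz] = 1.0
    P = np.eye(n)  # columns = p vectors for every start node
    E = np.eye(n)
    WT = W.T
    for _ in range(max_iter):
        P_new = (1 - c) * (WT @ P) + c * E
        delta = np.abs(P_new - P).sum(axis=0).max()
        P = P_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"RWR did not converge in {max_iter} iterations (residual {delta:g})"
        )
    return ScoreMatrixU(P, list(g.labels), "rwr", {"c": c})
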