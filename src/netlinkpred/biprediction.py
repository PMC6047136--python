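"""Bipartite drug-target recommenders.

Four scorers that fill in a real-valued target-by-drug score matrix from a
binary interaction matrix A (targets in rows, drugs in columns), optionally
blending drug-drug and target-target similarity matrices:

* **NBI** (network-based inference / mass diffusion): two-phase resource
  transfer.  A drug's column of A is the initial resource over targets;
  phase 1 spreads it targets->drugs splitting each target's resource by its
  degree, phase 2 spreads it back drugs->targets splitting by drug degree.
  Similarities, when supplied, blend the topology score as
  ``F' = S_t_hat @ F @ S_d_hat.T`` with row-normalized similarity matrices.
* **HeatS** (heat conduction): the same two phases but averaging at the
  receiver instead of splitting at the sender.
* **heterogeneous RWR**: a random walk with restart on the combined
  drug+target graph whose blocks are the two similarity networks (weight
  1-lambda) and the bipartite adjacency (weight lambda).
* **netcombo**: the average of min-max-scaled NBI and RWR scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_core import (
    BipartiteNetwork,
    ConvergenceError,
    SimilarityMatrix,
)

logger = logging.getLogger("netlinkpred")

BIPARTITE_ALGORITHMS = ("heats", "nbi", "rwr", "netcombo")


@dataclass
class ScoreMatrixB:
    """Real target-by-drug score matrix aligned to a BipartiteNetwork."""

    values: np.ndarray
    target_labels: list[str]
    drug_labels: list[str]
    method: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")

    def score(self, target: str, drug: str) -> float:
        return float(
            self.values[self.target_labels.index(target), self.drug_labels.index(drug)]
        )


def _row_normalize(M: np.ndarray) -> np.ndarray:
    """Rows scaled to sum 1; all-zero rows stay zero."""
    s = M.sum(axis=1)
    out = np.zeros_like(M, dtype=float)
    nz = s > 0
    out[nz] = M[nz] / s[nz, None]
    return out


def _aligned_similarity(
    sim: SimilarityMatrix | None, labels: list[str], what: str
) -> np.ndarray | None:
    if sim is None:
        return None
    return sim.reorder(labels).values


def nbi_score(
    net: BipartiteNetwork,
    drug_sim: SimilarityMatrix | None = None,
    target_sim: SimilarityMatrix | None = None,
) -> ScoreMatrixB:
    """Two-phase mass-diffusion scores, optionally similarity-blended.

    Topology-only diffusion conserves each drug column's total resource
    (the drug's degree).  Degree-zero drug columns score all-zero.
    """
    A = net.adjacency.astype(float)
    k_t = A.sum(axis=1)  # target degrees
    k_d = A.sum(axis=0)  # drug degrees
    if (k_d == 0).any():
        logger.warning("nbi_score: %d drug(s) with no interactions score zero",
                       int((k_d == 0).sum()))
    inv_t = np.divide(1.0, k_t, out=np.zeros_like(k_t), where=k_t > 0)
    inv_d = np.divide(1.0, k_d, out=np.zeros_like(k_d), where=k_d > 0)
    # phase 1 (targets->drugs, sender-degree split), phase 2 (drugs->targets)
    F = (A * inv_d[None, :]) @ (A.T * inv_t[None, :]) @ A
    Sd = _aligned_similarity(drug_sim, net.drug_labels, "drug")
    St = _aligned_similarity(target_sim, net.target_labels, "target")
    if Sd is not None or St is not None:
        St_hat = _row_normalize(St) if St is not None else np.eye(net.n_targets)
        Sd_hat = _row_normalize(Sd) if Sd is not None else np.eye(net.n_drugs)
        F = St_hat @ F @ Sd_hat.T
    return ScoreMatrixB(F, list(net.target_labels), list(net.drug_labels), "nbi")


def heats_score(net: BipartiteNetwork) -> ScoreMatrixB:
    """Heat-conduction scores: receiver-degree averaging in both phases."""
    A = net.adjacency.astype(float)
    k_t = A.sum(axis=1)
    k_d = A.sum(axis=0)
    inv_t = np.divide(1.0, k_t, out=np.zeros_like(k_t), where=k_t > 0)
    inv_d = np.divide(1.0, k_d, out=np.zeros_like(k_d), where=k_d > 0)
    # phase 1: r_d(i) = (1/k_d(i)) sum_l A[l,i] r(l);  phase 2 mirrors on targets
    F = (inv_t[:, None] * A) @ (inv_d[:, None] * A.T) @ A
    return ScoreMatrixB(F, list(net.target_labels), list(net.drug_labels), "heats")


def rwr_hetero_score(
    net: BipartiteNetwork,
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    c: float = 0.7,
    lam: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> ScoreMatrixB:
    """Random walk with restart on the heterogeneous drug+target network.

    The walker restarts at the query drug with probability ``c``; at each
    step it crosses to the other node set with probability ``lam`` (when the
    node has bipartite links) and otherwise moves within its similarity
    network.  Column j of the result is the target block of the stationary
    distribution for drug j.
    """
    if not 0 < c < 1:
        raise ValueError("restart probability c must be in (0, 1)")
    if not 0 < lam < 1:
        raise ValueError("jump probability lam must be in (0, 1)")
    if drug_sim is None or target_sim is None:
        raise ValueError("heterogeneous RWR requires both similarity matrices")
    A = net.adjacency.astype(float)
    n_t, n_d = A.shape
    Sd = _aligned_similarity(drug_sim, net.drug_labels, "drug")
    St = _aligned_similarity(target_sim, net.target_labels, "target")
    for name, S in (("drug", Sd), ("target", St)):
        if (S.sum(axis=1) == 0).any():
            logger.warning("rwr_hetero_score: all-zero %s similarity row; uniform fallback", name)
    Sd_n = _row_normalize(Sd)
    St_n = _row_normalize(St)
    # uniform fallback for degenerate all-zero similarity rows
    for S_n in (Sd_n, St_n):
        zero = S_n.sum(axis=1) == 0
        S_n[zero] = 1.0 / S_n.shape[1]
    drug_linked = A.sum(axis=0) > 0
    target_linked = A.sum(axis=1) > 0
    # block transition matrix, node order [drugs, targets]
    dd = Sd_n * np.where(drug_linked, 1 - lam, 1.0)[:, None]
    tt = St_n * np.where(target_linked, 1 - lam, 1.0)[:, None]
    dt = lam * _row_normalize(A.T)  # drugs -> targets
    td = lam * _row_normalize(A)    # targets -> drugs
    n = n_d + n_t
    M = np.zeros((n, n))
    M[:n_d, :n_d] = dd
    M[:n_d, n_d:] = dt
    M[n_d:, n_d:] = tt
    M[n_d:, :n_d] = td
    MT = M.T
    # restart vectors: point mass on each drug
    E = np.zeros((n, n_d))
    E[np.arange(n_d), np.arange(n_d)] = 1.0
    P = E.copy()
    for _ in range(max_iter):
        P_new = (1 - c) * (MT @ P) + c * E
        delta = np.abs(P_new - P).sum(axis=0).max()
        P = P_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"heterogeneous RWR did not converge in {max_iter} iterations "
            f"(residual {delta:g})"
        )
    F = P[n_d:, :]  # target block, one column per drug
    return ScoreMatrixB(
        F, list(net.target_labels), list(net.drug_labels), "rwr", {"c": c, "lam": lam}
    )


def _minmax_unknown(values: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Min-max scale to [0,1] using the range of the unknown-pair entries."""
    unknown = values[~known]
    if unknown.size == 0:
        return np.clip(values, 0.0, 1.0)
    lo, hi = unknown.min(), unknown.max()
    if hi == lo:
        return np.where(values >= hi, 1.0, 0.0)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def netcombo_score(
    net: BipartiteNetwork,
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    c: float = 0.7,
    lam: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> ScoreMatrixB:
    """Average of min-max-scaled NBI and heterogeneous-RWR scores.

    NBI and RWR scores live on incomparable scales, so each child matrix is
    scaled to [0,1] over the unknown pairs before the entrywise average.
    """
    known = net.adjacency.astype(bool)
    nbi = nbi_score(net, drug_sim, target_sim)
    rwr = rwr_hetero_score(net, drug_sim, target_sim, c=c, lam=lam,
                           tol=tol, max_iter=max_iter)
    F = 0.5 * (_minmax_unknown(nbi.values, known) + _minmax_unknown(rwr.values, known))
    return ScoreMatrixB(
        F, list(net.target_labels), list(net.drug_labels), "netcombo",
        {"c": c, "lam": lam},
    )


def bipartite_score(
    net: BipartiteNetwork,
    algo: str,
    drug_sim: SimilarityMatrix | None = None,
    target_sim: SimilarityMatrix | None = None,
    **params,
) -> ScoreMatrixB:
    """Dispatch to one of the four recommenders by name."""
    if algo == "heats":
        return heats_score(net)
    if algo == "nbi":
        return nbi_score(net, drug_sim, target_sim)
    if algo == "rwr":
        return rwr_hetero_score(net, drug_sim, target_sim, **params)
    if algo == "netcombo":
        return netcombo_score(net, drug_sim, target_sim, **params)
    raise ValueError(f"unknown algorithm {algo!r}; choose from {BIPARTITE_ALGORITHMS}")


def rank_predictions(
    net: BipartiteNetwork, scores: ScoreMatrixB, top: int | None = None
) -> pd.DataFrame:
    """Ranked prediction table: (drug, target, score, outcome).

    Sorted by score descending with deterministic (drug, target) label
    tie-break; known interactions are labelled ``true``, the rest
    ``predicted``.
    """
    if scores.values.shape != net.adjacency.shape:
        raise ValueError("score matrix shape does not match network")
    rows, cols = np.indices(net.adjacency.shape)
    df = pd.DataFrame(
        {
            "drug": np.array(net.drug_labels)[cols.ravel()],
            "target": np.array(net.target_labels)[rows.ravel()],
            "score": scores.values.ravel(),
            "outcome": np.where(net.adjacency.ravel() > 0, "true", "predicted"),
        }
    )
    df = df.sort_values(
        ["score", "drug", "target"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df
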