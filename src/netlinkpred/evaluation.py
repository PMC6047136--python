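"""Validation protocols: link-removal benchmarking and permutation testing.

The benchmark hides a fraction of the known interactions, re-scores the
reduced network, and measures how early the hidden links appear in the ranked
list of candidate pairs.  Early-recognition metrics follow the virtual
screening conventions: with actives at ranks r_1 < ... < r_n among N scored
pairs,

* AUC    = 1 - (sum r_i - n(n+1)/2) / (n(N-n))          (Mann-Whitney)
* AUAC   = 1 - (1/n) sum r_i / N                        (accumulation curve)
* AUCTOP = AUC restricted to the top ceil(chi*N) rows; actives below the
  cutoff count as missed
* EF     = (fraction of actives in the top window) / (n/N)
* BEDROC = Truchon-Bailey exponentially weighted early recognition with
  parameter alpha (default 20)

The permutation test rewires the bipartite adjacency with degree-preserving
checkerboard swaps, re-scores, and reports per-pair z-scores and upper-tail
normal p-values (plus Benjamini-Hochberg q-values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biprediction import bipartite_score, ScoreMatrixB
from .graph_core import BipartiteNetwork, NetworkFormatError, SimilarityMatrix

METRIC_NAMES = ("auac", "auc", "auctop", "bedroc", "ef")


@dataclass
class EvalReport:
    """Per-repetition and mean metrics from the link-removal benchmark."""

    per_rep: list[dict[str, float]]
    mean: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_rep)
        df.insert(0, "rep", np.arange(1, len(self.per_rep) + 1))
        return df


@dataclass
class PermutationResult:
    """Per-pair permutation significance table."""

    table: pd.DataFrame  # drug, target, observed, perm_mean, perm_sd, z, p, q
    n_perm: int
    seed: int


def rank_metrics(
    relative_ranks,
    n: int,
    N: int,
    alpha: float = 20.0,
    chi: float = 0.1,
) -> dict[str, float]:
    """Early-recognition metrics from the active positions in a ranked list.

    ``relative_ranks`` are the 1-based positions of the n actives among the N
    scored items, strictly increasing.
    """
    r = np.asarray(sorted(relative_ranks), dtype=float)
    if r.size != n:
        raise ValueError("rank count does not match n")
    if n == 0 or n == N:
        raise ValueError("metrics undefined for n=0 or n=N")
    if r[0] < 1 or r[-1] > N or np.any(np.diff(r) <= 0):
        raise ValueError("ranks must satisfy 1 <= r_1 < ... < r_n <= N")
    if alpha <= 0 or not 0 < chi < 1:
        raise ValueError("need alpha > 0 and 0 < chi < 1")

    auc = 1.0 - (r.sum() - n * (n + 1) / 2.0) / (n * (N - n))
    auac = 1.0 - r.sum() / (n * N)

    top = math.ceil(chi * N)
    in_top = r[r <= top]
    n_top = in_top.size
    decoys_top = top - n_top
    if decoys_top > 0:
        # concordant (active, decoy-in-top) pairs; missed actives beat none
        concordant = sum(decoys_top - (rank - (j + 1)) for j, rank in enumerate(in_top))
        auctop = concordant / (n * decoys_top)
    else:
        auctop = n_top / n  # degenerate window of pure actives
    ef = (n_top / top) / (n / N)

    ra = n / N
    rie_denom = ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)
    rie = float(np.exp(-alpha * r / N).sum()) / rie_denom
    bedroc = rie * ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    ) + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return {"auac": auac, "auc": auc, "auctop": auctop, "bedroc": bedroc, "ef": ef}


def remove_links(
    net: BipartiteNetwork,
    fraction: float,
    weighting: str = "uniform",
    seed: int = 0,
) -> tuple[BipartiteNetwork, list[tuple[str, str]]]:
    """Hide floor(fraction*m) interactions; returns (training net, hidden).

    ``uniform`` samples edges uniformly without replacement; ``degree``
    samples with probability proportional to k(d_i)*k(t_l), preferentially
    hiding links between high-degree (frequent) nodes.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if weighting not in ("uniform", "degree"):
        raise ValueError("weighting must be 'uniform' or 'degree'")
    m = net.n_interactions
    n_remove = int(fraction * m)
    if n_remove == 0:
        raise ValueError(
            f"fraction {fraction} removes 0 of {m} edges; increase the fraction"
        )
    if n_remove >= m:
        raise ValueError("removal would empty the network")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(net.adjacency)
    if weighting == "uniform":
        pick = rng.choice(m, size=n_remove, replace=False)
    else:
        k_t = net.target_degrees()[rows]
        k_d = net.drug_degrees()[cols]
        w = (k_t * k_d).astype(float)
        pick = rng.choice(m, size=n_remove, replace=False, p=w / w.sum())
    A = net.adjacency.copy()
    hidden = []
    for idx in pick:
        A[rows[idx], cols[idx]] = 0
        hidden.append((net.target_labels[rows[idx]], net.drug_labels[cols[idx]]))
    training = BipartiteNetwork(A, list(net.target_labels), list(net.drug_labels))
    return training, hidden


def degree_baseline_score(net: BipartiteNetwork) -> ScoreMatrixB:
    """Null recommender: score(t, d) = k(t) * k(d) on the training network."""
    F = np.outer(net.target_degrees(), net.drug_degrees()).astype(float)
    return ScoreMatrixB(F, list(net.target_labels), list(net.drug_labels), "degree")


def _score(net, algo, drug_sim, target_sim, **params) -> ScoreMatrixB:
    if algo == "degree":
        return degree_baseline_score(net)
    return bipartite_score(net, algo, drug_sim, target_sim, **params)


def _active_ranks(
    training: BipartiteNetwork,
    scores: np.ndarray,
    hidden: list[tuple[str, str]],
) -> tuple[np.ndarray, int]:
    """1-based ranks of hidden edges among all non-training pairs.

    Sorting is by score descending with deterministic (drug label, target
    label) tie-break, matching the prediction table's ordering.
    """
    mask = training.adjacency == 0  # candidate pairs
    rows, cols = np.nonzero(mask)
    s = scores[rows, cols]
    d_lab = np.array(training.drug_labels, dtype=object)[cols]
    t_lab = np.array(training.target_labels, dtype=object)[rows]
    order = np.lexsort((t_lab, d_lab, -s))
    t_index = {lab: i for i, lab in enumerate(training.target_labels)}
    d_index = {lab: i for i, lab in enumerate(training.drug_labels)}
    hidden_keys = {(t_index[t], d_index[d]) for t, d in hidden}
    ranked_keys = list(zip(rows[order].tolist(), cols[order].tolist()))
    ranks = np.array(
        [i + 1 for i, key in enumerate(ranked_keys) if key in hidden_keys], dtype=int
    )
    return ranks, len(ranked_keys)


def benchmark(
    net: BipartiteNetwork,
    drug_sim: SimilarityMatrix | None = None,
    target_sim: SimilarityMatrix | None = None,
    algo: str = "nbi",
    fraction: float = 0.2,
    reps: int = 50,
    seed: int = 0,
    alpha: float = 20.0,
    chi: float = 0.1,
    weighting: str = "uniform",
    **algo_params,
) -> EvalReport:
    """Repeated random link removal, re-scoring, and early-recognition metrics.

    Each repetition hides ``fraction`` of the interactions, scores the reduced
    network with ``algo``, ranks every non-training pair, and treats the
    hidden links as actives.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    per_rep = []
    for _ in range(reps):
        rep_seed = int(rng.integers(2**31))
        training, hidden = remove_links(net, fraction, weighting, seed=rep_seed)
        scores = _score(training, algo, drug_sim, target_sim, **algo_params)
        ranks, N = _active_ranks(training, scores.values, hidden)
        per_rep.append(rank_metrics(ranks, len(hidden), N, alpha=alpha, chi=chi))
    mean = {k: float(np.mean([rec[k] for rec in per_rep])) for k in METRIC_NAMES}
    return EvalReport(
        per_rep=per_rep,
        mean=mean,
        config={
            "algo": algo, "fraction": fraction, "reps": reps, "seed": seed,
            "alpha": alpha, "chi": chi, "weighting": weighting,
        },
    )


# ---------------------------------------------------------------------------
# Degree-preserving permutation null
# ---------------------------------------------------------------------------

def checkerboard_swap_chain(
    adjacency: np.ndarray, rng: np.random.Generator, n_swaps: int, max_tries: int
) -> np.ndarray:
    """Apply ``n_swaps`` successful 2x2 checkerboard flips in place.

    A swap picks two edges (r1,c1), (r2,c2) with A[r1,c2] = A[r2,c1] = 0 and
    flips the 2x2 submatrix, preserving every row and column sum.  Raises when
    ``max_tries`` attempts cannot produce the requested swaps (the matrix has
    no swappable checkerboard left).
    """
    A = adjacency
    rows, cols = np.nonzero(A)
    edges = list(zip(rows.tolist(), cols.tolist()))
    m = len(edges)
    done = 0
    tries = 0
    while done < n_swaps:
        if tries >= max_tries:
            raise NetworkFormatError(
                "network too constrained to rewire: no swappable checkerboard "
                f"found in {max_tries} attempts"
            )
        tries += 1
        i, j = rng.integers(m), rng.integers(m)
        (r1, c1), (r2, c2) = edges[i], edges[j]
        if r1 == r2 or c1 == c2 or A[r1, c2] or A[r2, c1]:
            continue
        A[r1, c1] = A[r2, c2] = 0
        A[r1, c2] = A[r2, c1] = 1
        edges[i] = (r1, c2)
        edges[j] = (r2, c1)
        done += 1
    return A


def shuffle_null(adjacency: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-shuffling null: permute rows and columns independently."""
    return adjacency[rng.permutation(adjacency.shape[0])][
        :, rng.permutation(adjacency.shape[1])
    ]


def permutation_test(
    net: BipartiteNetwork,
    drug_sim: SimilarityMatrix | None = None,
    target_sim: SimilarityMatrix | None = None,
    algo: str = "nbi",
    n_perm: int = 100,
    seed: int = 0,
    p_keep: float = 1.0,
    null: str = "checkerboard",
    **algo_params,
) -> PermutationResult:
    """Permutation significance of every drug-target score.

    Observed scores come from the intact network; the null rewires the
    adjacency with degree-preserving checkerboard swaps (burn-in 10*m swaps,
    m swaps between samples) and re-scores.  Per pair, z = (observed - mean)/sd
    and p is the upper-tail standard-normal probability; sd = 0 pairs get the
    p = 0.5 sentinel.  ``null='shuffle'`` permutes row/column labels instead.
    Rows are filtered to p <= p_keep; q is the Benjamini-Hochberg adjusted p
    over all pairs (computed before filtering).
    """
    if algo not in ("nbi", "rwr"):
        raise ValueError("permutation testing supports algo 'nbi' or 'rwr'")
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if not 0 < p_keep <= 1:
        raise ValueError("p_keep must be in (0, 1]")
    if null not in ("checkerboard", "shuffle"):
        raise ValueError("null must be 'checkerboard' or 'shuffle'")
    rng = np.random.default_rng(seed)
    observed = _score(net, algo, drug_sim, target_sim, **algo_params).values
    m = net.n_interactions
    A = net.adjacency.copy()
    row_sums = A.sum(axis=1).copy()
    col_sums = A.sum(axis=0).copy()
    max_tries_per_swap = 1000
    if null == "checkerboard":
        checkerboard_swap_chain(A, rng, 10 * m, 10 * m * max_tries_per_swap)
    acc = np.zeros_like(observed)
    acc2 = np.zeros_like(observed)
    for _ in range(n_perm):
        if null == "checkerboard":
            checkerboard_swap_chain(A, rng, m, m * max_tries_per_swap)
            sample = A
            assert (sample.sum(axis=1) == row_sums).all()
            assert (sample.sum(axis=0) == col_sums).all()
        else:
            sample = shuffle_null(net.adjacency, rng)
        perm_net = BipartiteNetwork(
            sample.copy(), list(net.target_labels), list(net.drug_labels)
        )
        s = _score(perm_net, algo, drug_sim, target_sim, **algo_params).values
        acc += s
        acc2 += s * s
    mean = acc / n_perm
    var = np.maximum(acc2 / n_perm - mean**2, 0.0)
    sd = np.sqrt(var)
    z = np.zeros_like(observed)
    np.divide(observed - mean, sd, out=z, where=sd > 0)
    p = np.where(sd > 0, stats.norm.sf(z), 0.5)
    p = np.clip(p, np.nextafter(0, 1), np.nextafter(1, 0))
    q = stats.false_discovery_control(p.ravel(), method="bh").reshape(p.shape)
    rows, cols = np.indices(observed.shape)
    table = pd.DataFrame(
        {
            "drug": np.array(net.drug_labels)[cols.ravel()],
            "target": np.array(net.target_labels)[rows.ravel()],
            "observed": observed.ravel(),
            "perm_mean": mean.ravel(),
            "perm_sd": sd.ravel(),
            "z": z.ravel(),
            "p": p.ravel(),
            "q": q.ravel(),
        }
    )
    table = table[table["p"] <= p_keep].sort_values(
        ["p", "drug", "target"], kind="mergesort"
    ).reset_index(drop=True)
    return PermutationResult(table=table, n_perm=n_perm, seed=seed)
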