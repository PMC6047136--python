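"""Seeded generators for planted-module bipartite benchmarks.

``gen_bipartite`` draws a drug-target interaction matrix with block (module)
structure: drugs and targets are split near-evenly into ``n_modules`` groups
and an interaction appears with probability ``p_in`` within a group pair and
``p_out`` across groups.  ``gen_similarity`` derives drug-drug / target-target
similarity matrices as a convex blend of the Jaccard similarity of interaction
profiles (the learnable signal: nodes with shared partners look alike, the way
chemically similar drugs share targets) and symmetric uniform noise.

Everything is deterministic per seed, so the generators double as test
fixtures for every other module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import BipartiteNetwork, SimilarityMatrix


@dataclass
class SyntheticSpec:
    """Parameters of a planted-module bipartite benchmark network."""

    n_drugs: int = 50
    n_targets: int = 40
    n_modules: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    sim_signal: float = 0.8
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_modules > min(self.n_drugs, self.n_targets):
            raise ValueError("n_modules cannot exceed min(n_drugs, n_targets)")
        if not 0 <= self.sim_signal <= 1:
            raise ValueError("sim_signal must lie in [0, 1]")


def _block_split(n: int, k: int) -> np.ndarray:
    """Assign n items to k near-even contiguous blocks (0..k-1)."""
    return np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))


def gen_bipartite(spec: SyntheticSpec) -> tuple[BipartiteNetwork, dict[str, int]]:
    """Planted-module bipartite network plus its ground-truth module map.

    Empty rows/columns are repaired with one forced within-module edge so the
    network satisfies the prediction modules' m >= 1 per-node assumptions.
    """
    rng = np.random.default_rng(spec.seed)
    t_block = _block_split(spec.n_targets, spec.n_modules)
    d_block = _block_split(spec.n_drugs, spec.n_modules)
    same = t_block[:, None] == d_block[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    A = (rng.random((spec.n_targets, spec.n_drugs)) < p).astype(np.int8)
    # repair empty rows/columns with one within-module edge
    for l in np.where(A.sum(axis=1) == 0)[0]:
        pool = np.where(d_block == t_block[l])[0]
        A[l, rng.choice(pool)] = 1
    for i in np.where(A.sum(axis=0) == 0)[0]:
        pool = np.where(t_block == d_block[i])[0]
        A[rng.choice(pool), i] = 1
    target_labels = [f"T{l:03d}" for l in range(spec.n_targets)]
    drug_labels = [f"D{i:03d}" for i in range(spec.n_drugs)]
    net = BipartiteNetwork(A, target_labels, drug_labels)
    truth = dict(zip(target_labels, t_block.tolist()))
    truth.update(zip(drug_labels, d_block.tolist()))
    return net, truth


def _profile_jaccard(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of binary row profiles; 0/0 -> 0, diag 1."""
    inter = profiles.astype(float) @ profiles.T.astype(float)
    sizes = profiles.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    J = np.zeros_like(inter)
    np.divide(inter, union, out=J, where=union > 0)
    np.fill_diagonal(J, 1.0)
    return J


def gen_similarity(
    net: BipartiteNetwork, side: str, sim_signal: float = 0.8, seed: int = 1
) -> SimilarityMatrix:
    """Similarity matrix: sim_signal * profile-Jaccard + (1-sim_signal) * noise.

    The noise part is symmetric uniform on [0,1]; the diagonal is forced to 1
    and the result clipped to [0,1].
    """
    if not 0 <= sim_signal <= 1:
        raise ValueError("sim_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if side == "drugs":
        profiles = net.adjacency.T
        labels = net.drug_labels
    elif side == "targets":
        profiles = net.adjacency
        labels = net.target_labels
    else:
        raise ValueError("side must be 'drugs' or 'targets'")
    n = profiles.shape[0]
    noise = rng.random((n, n))
    noise = (noise + noise.T) / 2.0
    S = sim_signal * _profile_jaccard(profiles) + (1 - sim_signal) * noise
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(np.clip(S, 0.0, 1.0), list(labels))


def gen_benchmark(
    spec: SyntheticSpec,
) -> tuple[BipartiteNetwork, SimilarityMatrix, SimilarityMatrix, dict[str, int]]:
    """Network plus both similarity matrices from one spec (seeded)."""
    net, truth = gen_bipartite(spec)
    d_sim = gen_similarity(net, "drugs", spec.sim_signal, seed=spec.seed + 101)
    t_sim = gen_similarity(net, "targets", spec.sim_signal, seed=spec.seed + 211)
    return net, d_sim, t_sim, truth
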