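"""Bipartite community detection: label propagation seeded BRIM (LP-BRIM).

The objective is Barber's bipartite modularity

    Q_B = (1/m) * sum_{l,i} (A[l,i] - k(t_l)*k(d_i)/m) * delta(g(t_l), g(d_i))

which compares within-module interaction weight to the degree-product null.
Label propagation gives a cheap initial partition (each node repeatedly adopts
the most common label among its bipartite neighbors); BRIM then refines it by
alternately reassigning every drug to its best module given the targets, and
vice versa, until Q_B stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import BipartiteNetwork

#: BRIM stops when a full alternation improves Q_B by less than this
BRIM_TOL = 1e-12


@dataclass
class ModulePartition:
    """Module assignment for every drug and target, plus its Q_B."""

    drug_module: dict[str, int]
    target_module: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        mods = set(self.drug_module.values()) | set(self.target_module.values())
        return len(mods)

    def compact(self) -> "ModulePartition":
        """Renumber module ids to a contiguous 0..K-1 range."""
        mods = sorted(set(self.drug_module.values()) | set(self.target_module.values()))
        remap = {old: new for new, old in enumerate(mods)}
        return ModulePartition(
            {k: remap[v] for k, v in self.drug_module.items()},
            {k: remap[v] for k, v in self.target_module.items()},
            self.modularity,
        )


def _partition_arrays(
    net: BipartiteNetwork, part: ModulePartition
) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([part.target_module[lab] for lab in net.target_labels])
    d = np.array([part.drug_module[lab] for lab in net.drug_labels])
    return t, d


def _modularity_matrix(net: BipartiteNetwork) -> tuple[np.ndarray, int]:
    A = net.adjacency.astype(float)
    m = net.n_interactions
    B = A - np.outer(net.target_degrees(), net.drug_degrees()) / m
    return B, m


def barber_modularity(net: BipartiteNetwork, part: ModulePartition) -> float:
    """Barber bipartite modularity Q_B of a partition."""
    if set(part.target_module) != set(net.target_labels) or set(part.drug_module) != set(
        net.drug_labels
    ):
        raise ValueError("partition must cover exactly the network's nodes")
    B, m = _modularity_matrix(net)
    t_mod, d_mod = _partition_arrays(net, part)
    same = t_mod[:, None] == d_mod[None, :]
    return float(B[same].sum() / m)


def label_propagation(net: BipartiteNetwork, seed: int = 0) -> ModulePartition:
    """Seed partition by synchronous-free label propagation.

    Every node starts with a unique label; nodes are swept in a seeded random
    order (reshuffled each sweep), each adopting the most frequent label among
    its bipartite neighbors with uniform-random tie-break under the seed.
    Stops when a sweep changes nothing or when Q_B stops increasing.
    """
    rng = np.random.default_rng(seed)
    A = net.adjacency
    n_t, n_d = A.shape
    # labels: targets occupy ids 0..n_t-1, drugs n_t..n_t+n_d-1
    t_lab = np.arange(n_t)
    d_lab = np.arange(n_t, n_t + n_d)

    def current_partition() -> ModulePartition:
        part = ModulePartition(
            dict(zip(net.drug_labels, d_lab.tolist())),
            dict(zip(net.target_labels, t_lab.tolist())),
            0.0,
        ).compact()
        part.modularity = barber_modularity(net, part)
        return part

    best_part = current_partition()
    best_q = best_part.modularity
    neighbors_t = [np.nonzero(A[l])[0] for l in range(n_t)]  # drugs of target l
    neighbors_d = [np.nonzero(A[:, i])[0] for i in range(n_d)]  # targets of drug i
    max_sweeps = 10 * (n_t + n_d)
    for _ in range(max_sweeps):
        order = rng.permutation(n_t + n_d)
        changed = False
        had_tie = False
        for node in order:
            if node < n_t:
                nbrs = neighbors_t[node]
                if nbrs.size == 0:
                    continue
                labels = d_lab[nbrs]
            else:
                nbrs = neighbors_d[node - n_t]
                if nbrs.size == 0:
                    continue
                labels = t_lab[nbrs]
            uniq, counts = np.unique(labels, return_counts=True)
            winners = uniq[counts == counts.max()]
            if winners.size > 1:
                had_tie = True
            new = winners[rng.integers(winners.size)]
            if node < n_t:
                if t_lab[node] != new:
                    t_lab[node] = new
                    changed = True
            else:
                if d_lab[node - n_t] != new:
                    d_lab[node - n_t] = new
                    changed = True
        part = current_partition()
        if not changed and not had_tie:
            # a genuine fixed point: every label is the unique local winner
            return part if part.modularity >= best_q else best_part
        # a strict drop means consensus passed its peak; plateaus keep
        # sweeping so random tie-breaks can resolve
        if part.modularity < best_q - BRIM_TOL:
            return best_part
        if part.modularity > best_q:
            best_q, best_part = part.modularity, part
    return best_part


def brim_refine(net: BipartiteNetwork, part: ModulePartition) -> ModulePartition:
    """BRIM refinement: alternate best-module reassignment until Q_B stalls.

    Holding target assignments fixed, each drug moves to the module maximizing
    its Q_B contribution (ties to the lowest module id), then the converse;
    the returned Q_B is never below the input's.
    """
    B, m = _modularity_matrix(net)
    t_mod, d_mod = _partition_arrays(net, part)
    mods = sorted(set(t_mod.tolist()) | set(d_mod.tolist()))
    remap = {old: new for new, old in enumerate(mods)}
    t_mod = np.array([remap[x] for x in t_mod])
    d_mod = np.array([remap[x] for x in d_mod])
    K = len(mods)

    def indicator(assign: np.ndarray) -> np.ndarray:
        M = np.zeros((assign.size, K))
        M[np.arange(assign.size), assign] = 1.0
        return M

    def q_of(t_assign: np.ndarray, d_assign: np.ndarray) -> float:
        return float(B[t_assign[:, None] == d_assign[None, :]].sum() / m)

    q = q_of(t_mod, d_mod)
    while True:
        # drugs given targets: contribution of drug i to module k = (B^T T)[i,k]
        gains_d = B.T @ indicator(t_mod)
        d_new = gains_d.argmax(axis=1)
        # keep current module when it ties the max (stability)
        cur = gains_d[np.arange(d_new.size), d_mod]
        d_new = np.where(cur >= gains_d.max(axis=1), d_mod, d_new)
        gains_t = B @ indicator(d_new)
        t_new = gains_t.argmax(axis=1)
        cur_t = gains_t[np.arange(t_new.size), t_mod]
        t_new = np.where(cur_t >= gains_t.max(axis=1), t_mod, t_new)
        q_new = q_of(t_new, d_new)
        if q_new <= q + BRIM_TOL:
            break
        t_mod, d_mod, q = t_new, d_new, q_new
    result = ModulePartition(
        dict(zip(net.drug_labels, d_mod.tolist())),
        dict(zip(net.target_labels, t_mod.tolist())),
        q,
    ).compact()
    result.modularity = barber_modularity(net, result)
    return result


def lpbrim(net: BipartiteNetwork, seed: int = 0, restarts: int = 5) -> ModulePartition:
    """Best-of-restarts label propagation followed by BRIM refinement."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: ModulePartition | None = None
    for _ in range(restarts):
        sub_seed = int(rng.integers(2**31))
        part = brim_refine(net, label_propagation(net, seed=sub_seed))
        if best is None or part.modularity > best.modularity:
            best = part
    return best
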