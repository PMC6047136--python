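"""Core data model and I/O for bipartite and unipartite networks.

The central object is the :class:`BipartiteNetwork`: a binary target-by-drug
adjacency matrix with row (target) and column (drug) labels.  Side information
enters as square symmetric :class:`SimilarityMatrix` objects (drug-drug chemical
similarity, target-target sequence similarity), and one-mode projections and
protein-protein interaction graphs are :class:`UnipartiteGraph` objects.

All matrices travel as labelled delimited text (CSV/TSV) with a header row of
column labels and a first column of row labels; unipartite graphs may also be
given as 2/3-column edge lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netlinkpred")

#: tolerance below which a similarity matrix is symmetrized instead of rejected
SYM_TOL = 1e-6


class NetworkFormatError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative solver fails to reach its tolerance."""


def _check_unique(labels, axis_name: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise NetworkFormatError(f"duplicate {axis_name} label: {lab!r}")
        seen.add(lab)


@dataclass
class BipartiteNetwork:
    """Binary bipartite adjacency: targets in rows, drugs in columns."""

    adjacency: np.ndarray
    target_labels: list[str]
    drug_labels: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.ndim != 2 or self.adjacency.size == 0:
            raise NetworkFormatError("adjacency must be a non-empty 2-D matrix")
        bad = ~np.isin(self.adjacency, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise NetworkFormatError(
                f"non-binary entry {self.adjacency[r, c]!r} at "
                f"row {self.target_labels[r] if r < len(self.target_labels) else r!r}, "
                f"column {self.drug_labels[c] if c < len(self.drug_labels) else c!r}"
            )
        self.adjacency = self.adjacency.astype(np.int8)
        n_t, n_d = self.adjacency.shape
        if len(self.target_labels) != n_t or len(self.drug_labels) != n_d:
            raise NetworkFormatError("label count does not match matrix dimension")
        self.target_labels = [str(x) for x in self.target_labels]
        self.drug_labels = [str(x) for x in self.drug_labels]
        _check_unique(self.target_labels, "target")
        _check_unique(self.drug_labels, "drug")

    @property
    def n_targets(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.adjacency.shape[1]

    @property
    def n_interactions(self) -> int:
        return int(self.adjacency.sum())

    def target_degrees(self) -> np.ndarray:
        """k(t_l): number of drugs each target interacts with."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    def drug_degrees(self) -> np.ndarray:
        """k(d_i): number of targets each drug interacts with."""
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """List of (target, drug) interaction pairs in row-major order."""
        rows, cols = np.nonzero(self.adjacency)
        return [(self.target_labels[r], self.drug_labels[c]) for r, c in zip(rows, cols)]

    def copy(self) -> "BipartiteNetwork":
        return BipartiteNetwork(
            self.adjacency.copy(), list(self.target_labels), list(self.drug_labels)
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric side-information matrix with unit diagonal."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise NetworkFormatError("similarity matrix must be square and match labels")
        self.labels = [str(x) for x in self.labels]
        _check_unique(self.labels, "similarity")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYM_TOL:
            raise NetworkFormatError(f"similarity matrix asymmetric (max |S-S'| = {asym:g})")
        self.values = (self.values + self.values.T) / 2.0
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise NetworkFormatError("similarity diagonal entries must equal 1")
        off = self.values[~np.eye(n, dtype=bool)] if n > 1 else np.empty(0)
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise NetworkFormatError("off-diagonal similarities must lie in [0, 1]")

    def reorder(self, labels: list[str]) -> "SimilarityMatrix":
        """Return a copy aligned to ``labels`` (must be a permutation of ours)."""
        missing = set(labels) - set(self.labels)
        extra = set(self.labels) - set(labels)
        if missing or extra:
            raise NetworkFormatError(
                f"similarity labels do not match network labels; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        idx = [self.labels.index(lab) for lab in labels]
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(labels))


@dataclass
class UnipartiteGraph:
    """Undirected graph as a symmetric non-negative adjacency matrix."""

    adjacency: np.ndarray
    labels: list[str]
    weighted: bool = False

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.labels)
        if self.adjacency.shape != (n, n):
            raise NetworkFormatError("adjacency must be square and match labels")
        self.labels = [str(x) for x in self.labels]
        _check_unique(self.labels, "node")
        if (self.adjacency < 0).any():
            raise NetworkFormatError("edge weights must be non-negative")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise NetworkFormatError("unipartite adjacency must be symmetric")
        if np.diag(self.adjacency).any():
            raise NetworkFormatError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def binary(self) -> np.ndarray:
        """Unweighted 0/1 view of the adjacency."""
        return (self.adjacency > 0).astype(float)

    def degrees(self) -> np.ndarray:
        return self.binary().sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        rows, cols = np.nonzero(np.triu(self.adjacency))
        for r, c in zip(rows, cols):
            g.add_edge(self.labels[r], self.labels[c], weight=float(self.adjacency[r, c]))
        return g


@dataclass
class PropertyReport:
    """Summary statistics of a bipartite network and its projections."""

    n_drugs: int
    n_targets: int
    n_interactions: int
    density: float
    degree_per_node: dict[str, int] = field(default_factory=dict)
    betweenness_per_node: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": lab,
                "degree": self.degree_per_node[lab],
                "betweenness": self.betweenness_per_node.get(lab, 0.0),
            }
            for lab in self.degree_per_node
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_labelled(path: str, delimiter: str | None) -> pd.DataFrame:
    delim = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise NetworkFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise NetworkFormatError(f"{path}: empty matrix")
    return df


def read_bipartite_matrix(path: str, delimiter: str | None = None) -> BipartiteNetwork:
    """Read a labelled binary target-by-drug matrix (targets in rows)."""
    df = _read_labelled(path, delimiter)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~numeric.isin((0, 1))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise NetworkFormatError(
            f"{path}: non-binary entry {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return BipartiteNetwork(
        numeric.to_numpy().astype(np.int8), list(df.index), list(df.columns)
    )


def write_bipartite_matrix(net: BipartiteNetwork, path: str, delimiter: str = ",") -> None:
    df = pd.DataFrame(net.adjacency, index=net.target_labels, columns=net.drug_labels)
    df.to_csv(path, sep=delimiter)


def read_similarity_matrix(path: str, delimiter: str | None = None) -> SimilarityMatrix:
    df = _read_labelled(path, delimiter)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise NetworkFormatError(f"{path}: row and column labels differ")
    return SimilarityMatrix(df.to_numpy(dtype=float), list(df.index))


def write_similarity_matrix(sim: SimilarityMatrix, path: str, delimiter: str = ",") -> None:
    df = pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels)
    df.to_csv(path, sep=delimiter, float_format="%.12g")


def read_unipartite_matrix(path: str, delimiter: str | None = None) -> UnipartiteGraph:
    df = _read_labelled(path, delimiter)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise NetworkFormatError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    weighted = bool(np.any((values > 0) & (values != 1)))
    return UnipartiteGraph(values, list(df.index), weighted=weighted)


def read_edge_list(path: str, delimiter: str = "\t") -> UnipartiteGraph:
    """Read a 2/3-column edge list ``source<TAB>target[<TAB>weight]``."""
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[str, str, float]] = []
    weighted = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) not in (2, 3):
                raise NetworkFormatError(f"{path}:{lineno}: expected 2 or 3 columns")
            a, b = parts[0].strip(), parts[1].strip()
            w = 1.0
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkFormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                weighted = True
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            edges.append((a, b, w))
    if not labels:
        raise NetworkFormatError(f"{path}: empty edge list")
    n = len(labels)
    adj = np.zeros((n, n))
    for a, b, w in edges:
        if a == b:
            continue  # drop self-loops
        adj[index[a], index[b]] = w
        adj[index[b], index[a]] = w
    return UnipartiteGraph(adj, labels, weighted=weighted)


def read_unipartite(path: str, delimiter: str | None = None) -> UnipartiteGraph:
    """Read a unipartite graph, auto-detecting matrix vs edge-list layout."""
    try:
        return read_unipartite_matrix(path, delimiter)
    except NetworkFormatError:
        return read_edge_list(path, delimiter or _sniff_delimiter(path))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def project(net: BipartiteNetwork, side: str) -> UnipartiteGraph:
    """One-mode projection: two nodes connect iff they share >=1 neighbor.

    ``side='drugs'`` connects two drugs sharing a target; ``side='targets'``
    connects two targets sharing a drug.  The result is unweighted.
    """
    if side == "drugs":
        A = net.adjacency.astype(np.int64)
        shared = A.T @ A
        labels = net.drug_labels
    elif side == "targets":
        A = net.adjacency.astype(np.int64)
        shared = A @ A.T
        labels = net.target_labels
    else:
        raise ValueError(f"side must be 'drugs' or 'targets', got {side!r}")
    adj = (shared > 0).astype(float)
    np.fill_diagonal(adj, 0.0)
    return UnipartiteGraph(adj, list(labels), weighted=False)


def bipartite_properties(net: BipartiteNetwork) -> PropertyReport:
    """Counts, density, per-node degree, and projection betweenness.

    Betweenness is the standard unnormalized shortest-path node betweenness,
    computed on the drugs projection for drug nodes and on the targets
    projection for target nodes.
    """
    degree = dict(zip(net.target_labels, net.target_degrees().tolist()))
    degree.update(zip(net.drug_labels, net.drug_degrees().tolist()))
    betw: dict[str, float] = {}
    for side in ("targets", "drugs"):
        g = project(net, side).to_networkx()
        betw.update(nx.betweenness_centrality(g, normalized=False))
    return PropertyReport(
        n_drugs=net.n_drugs,
        n_targets=net.n_targets,
        n_interactions=net.n_interactions,
        density=net.n_interactions / (net.n_drugs * net.n_targets),
        degree_per_node=degree,
        betweenness_per_node={k: float(v) for k, v in betw.items()},
    )


def induced_subgraph(g: UnipartiteGraph, nodes: list[str]) -> UnipartiteGraph:
    """Subgraph on ``nodes`` with all edges among them; weights preserved.

    Unknown labels are logged and skipped; an empty intersection is an error.
    """
    index = {lab: i for i, lab in enumerate(g.labels)}
    keep, unknown = [], []
    for lab in nodes:
        (keep if lab in index else unknown).append(lab)
    if unknown:
        logger.warning("induced_subgraph: skipping %d unknown label(s): %s",
                       len(unknown), ", ".join(map(str, unknown[:10])))
    if not keep:
        raise NetworkFormatError("none of the requested nodes are in the graph")
    idx = [index[lab] for lab in keep]
    return UnipartiteGraph(g.adjacency[np.ix_(idx, idx)], keep, weighted=g.weighted)
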