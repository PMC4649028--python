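"""Multiscale community detection on the positive co-occurrence subgraph.

Markov stability scores a partition H of a graph by how well it traps an
unbiased random walk over a time horizon t:

    R(t, H) = trace(H' B(t) H)

with B(t) = Pi expm(-t (I - D^-1 A)) - pi pi'  (symmetrized) in the full
exponential mode, or its first-order linearization
B(t) = (1 - t) Pi + t A / (2m) - pi pi', which at t = 1 reduces exactly to
Newman-Girvan modularity.  Small t favors fine partitions, large t coarse
ones; scanning a grid of Markov times and keeping, among community counts
k > 2, the longest plateau of identical, label-stable k (variation of
information within tolerance) selects the reported partition.

Optimization is a generalized Louvain: greedy node moves plus aggregation on
the quality matrix B(t), best of ``n_restarts`` random node orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm
from sklearn.metrics import mutual_info_score


@dataclass
class Graph:
    """Symmetric unweighted graph with walk quantities precomputed."""

    nodes: list[str]
    adjacency: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValueError("adjacency shape must match node count")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if (np.diag(a) != 0).any():
            raise ValueError("self-loops are not allowed")
        if (a < 0).any():
            raise ValueError("adjacency must be non-negative")
        self.adjacency = a

    @classmethod
    def from_networkx(cls, g: nx.Graph, weighted: bool = False) -> "Graph":
        """Build from a networkx graph, dropping isolated nodes.

        Unweighted by default (an edge above threshold counts 1); with
        ``weighted=True`` the |rho| edge attribute is used when present.
        """
        isolated = [v for v in g.nodes if g.degree(v) == 0]
        if isolated:
            warnings.warn(
                f"{len(isolated)} isolated node(s) excluded from clustering",
                stacklevel=2,
            )
        keep = [v for v in g.nodes if g.degree(v) > 0]
        idx = {v: i for i, v in enumerate(keep)}
        a = np.zeros((len(keep), len(keep)))
        for u, v, data in g.edges(data=True):
            if u in idx and v in idx:
                w = abs(data.get("rho", 1.0)) if weighted else 1.0
                a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
        return cls([str(v) for v in keep], a)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """m = sum of edge weights."""
        return float(self.degrees.sum() / 2.0)

    @property
    def stationary(self) -> np.ndarray:
        """pi = d / 2m, the stationary distribution of the unbiased walk."""
        return self.degrees / (2.0 * self.total_weight)


@dataclass
class Partition:
    """Node -> community labels, contiguous from 0."""

    nodes: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if len(labels) != len(self.nodes):
            raise ValueError("one label per node required")
        # relabel to contiguous 0..k-1 in order of first appearance
        _, labels = np.unique(labels, return_inverse=True)
        order = {}
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            out[i] = order.setdefault(int(lab), len(order))
        self.labels = out

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def as_dict(self) -> dict[str, int]:
        return {v: int(c) for v, c in zip(self.nodes, self.labels)}

    def members(self, community: int) -> list[str]:
        return [v for v, c in zip(self.nodes, self.labels) if c == community]

    def indicator(self) -> np.ndarray:
        h = np.zeros((len(self.nodes), self.k))
        h[np.arange(len(self.nodes)), self.labels] = 1.0
        return h


def stability_matrix(graph: Graph, t: float, mode: str = "linearized") -> np.ndarray:
    """Quality matrix B(t); R(t, H) = trace(H' B H) for one-hot H.

    The all-in-one partition scores exactly 0 at any t (rows of B sum to 0),
    and linearized B at t = 1 is the modularity matrix scaled by 1/2m.
    """
    if t < 0:
        raise ValueError("Markov time must be >= 0")
    d = graph.degrees
    if (d == 0).any():
        raise ValueError("zero-degree nodes must be removed before scoring")
    pi = graph.stationary
    if mode == "linearized":
        b = (1.0 - t) * np.diag(pi) + t * graph.adjacency / (
            2.0 * graph.total_weight
        )
    elif mode == "exponential":
        p = graph.adjacency / d[:, None]  # D^-1 A, row-stochastic
        m = expm(-t * (np.eye(graph.n_nodes) - p))
        pm = pi[:, None] * m
        b = 0.5 * (pm + pm.T)
    else:
        raise ValueError(f"unknown stability mode {mode!r}")
    return b - np.outer(pi, pi)


def partition_quality(b: np.ndarray, partition: Partition) -> float:
    """R(t, H) = trace(H' B H)."""
    h = partition.indicator()
    return float(np.trace(h.T @ b @ h))


def _labels_quality(b: np.ndarray, labels: np.ndarray) -> float:
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        q += b[np.ix_(idx, idx)].sum()
    return float(q)


def _louvain_level(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: greedy node moves on quality matrix b."""
    n = b.shape[0]
    labels = np.arange(n)
    improved = True
    while improved:
        improved = False
        for v in rng.permutation(n):
            current = labels[v]
            # strength[c] = sum of B[v, u] over u in community c, excluding v;
            # v's quality contribution in community c is B[v, v] + 2 strength[c]
            strength = np.zeros(n)
            np.add.at(strength, labels, b[v])
            strength[current] -= b[v, v]
            stay = strength[current]
            best = int(np.argmax(strength))
            if best != current and strength[best] > max(stay, 0.0) + 1e-12:
                labels[v] = best
                improved = True
            elif stay < -1e-12 and strength[best] <= 1e-12:
                # a fresh singleton (strength 0) beats every community
                if (labels == current).sum() > 1:
                    labels[v] = np.setdiff1d(np.arange(n), labels)[0]
                    improved = True
    return labels


def _louvain_run(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Full Louvain: node moves + aggregation until quality stops improving."""
    n = b.shape[0]
    assignment = np.arange(n)  # original node -> current community
    current_b = b
    while True:
        labels = _louvain_level(current_b, rng)
        uniq, labels = np.unique(labels, return_inverse=True)
        if len(uniq) == current_b.shape[0]:
            break
        h = np.zeros((current_b.shape[0], len(uniq)))
        h[np.arange(current_b.shape[0]), labels] = 1.0
        current_b = h.T @ current_b @ h
        assignment = labels[assignment]
    return assignment


def louvain_optimize(
    b: np.ndarray, n_restarts: int = 20, seed: int = 0, nodes: list[str] | None = None
) -> Partition:
    """Best-of-restarts generalized Louvain on a symmetric quality matrix."""
    if not np.allclose(b, b.T):
        raise ValueError("quality matrix must be symmetric")
    n = b.shape[0]
    nodes = nodes if nodes is not None else [str(i) for i in range(n)]
    entropy = seed if isinstance(seed, tuple) else (seed,)
    best_labels, best_q = np.zeros(n, dtype=np.int64), -np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((*entropy, r)))
        labels = _louvain_run(b, rng)
        q = _labels_quality(b, labels)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    return Partition(nodes, best_labels)


def variation_of_information(p1: Partition, p2: Partition) -> float:
    """VI(p1, p2) = H(p1) + H(p2) - 2 MI(p1, p2), natural log."""
    if p1.nodes != p2.nodes:
        raise ValueError("partitions must share the same node set")

    def entropy(labels: np.ndarray) -> float:
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log(p)).sum())

    mi = mutual_info_score(p1.labels, p2.labels)
    vi = entropy(p1.labels) + entropy(p2.labels) - 2.0 * mi
    return max(0.0, float(vi))


@dataclass
class StabilityResult:
    """Scan output: per Markov time the best partition and its diagnostics."""

    time_grid: np.ndarray
    partitions: list[Partition]
    stability: np.ndarray  # R(t) of best partition
    community_counts: np.ndarray  # k(t)
    mode: str
    n_restarts: int
    vi_matrix: np.ndarray = field(default=None)  # cross-time VI

    def __post_init__(self) -> None:
        if self.vi_matrix is None:
            n = len(self.partitions)
            vi = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    vi[i, j] = vi[j, i] = variation_of_information(
                        self.partitions[i], self.partitions[j]
                    )
            self.vi_matrix = vi


def scan_markov_times(
    graph: Graph,
    time_grid=None,
    mode: str | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> StabilityResult:
    """Optimize stability at every Markov time of an ascending grid.

    Defaults: 60 log-spaced times in [1e-2, 1e2]; exponential mode up to
    2000 nodes, linearized beyond.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot scan an empty graph")
    if time_grid is None:
        time_grid = np.logspace(-2, 2, 60)
    time_grid = np.asarray(time_grid, dtype=float)
    if (np.diff(time_grid) <= 0).any():
        raise ValueError("time grid must be strictly ascending")
    if mode is None:
        mode = "exponential" if graph.n_nodes <= 2000 else "linearized"
    partitions, scores, counts = [], [], []
    for i, t in enumerate(time_grid):
        b = stability_matrix(graph, t, mode)
        part = louvain_optimize(
            b, n_restarts=n_restarts, seed=(seed, i), nodes=graph.nodes
        )
        partitions.append(part)
        scores.append(partition_quality(b, part))
        counts.append(part.k)
    return StabilityResult(
        time_grid,
        partitions,
        np.array(scores),
        np.array(counts, dtype=np.int64),
        mode,
        n_restarts,
    )


def select_partition(
    result: StabilityResult, k_min: int = 3, vi_tol: float | None = None
) -> Partition:
    """Pick the partition with the longest stable plateau of k > 2.

    A plateau is a maximal contiguous run of grid points with identical
    community count k >= ``k_min`` whose partitions also agree pairwise up to
    ``vi_tol`` (default 0.05 ln n) in variation of information.  The
    all-singletons partition (k = n) is the degenerate fine limit at t -> 0;
    its persistence measures grid coverage rather than structure, so it is
    never a candidate.  Ties go to larger k, then to earlier Markov times;
    the run's midpoint partition is returned.
    """
    ks = result.community_counts
    n_nodes = len(result.partitions[0].nodes)
    if vi_tol is None:
        vi_tol = 0.05 * np.log(max(n_nodes, 2))
    runs = []  # (length, k, start, end) inclusive
    i = 0
    while i < len(ks):
        if ks[i] < k_min or ks[i] == n_nodes:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(ks)
            and ks[j + 1] == ks[i]
            and result.vi_matrix[i : j + 2, i : j + 2].max() <= vi_tol
        ):
            j += 1
        runs.append((j - i + 1, int(ks[i]), i, j))
        i = j + 1
    if not runs:
        raise ValueError(
            f"no plateau with k >= {k_min} found; inspect the network density "
            "or correlation thresholds"
        )
    # longest run; ties -> larger k, then earlier Markov time
    runs.sort(
        key=lambda r: (
            -r[0],
            -r[1],
            float(min(result.time_grid[r[2]], result.time_grid[r[3]])),
        )
    )
    _, _, start, end = runs[0]
    return result.partitions[(start + end) // 2]
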