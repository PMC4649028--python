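"""Spearman co-occurrence networks with a compositionality-corrected null.

Relative abundances are compositions: because each sample is closed to sum 1,
even independent taxa acquire spurious (mostly negative) correlations.  The
permutation-renormalization ("ReBoot"-style) procedure implemented here
estimates, for every OTU pair, (a) a null distribution of Spearman's rho
obtained by permuting each OTU's counts across samples and re-closing every
sample — which preserves the closure artifact while destroying real
association — and (b) a bootstrap distribution of rho over samples resampled
with replacement.  Both distributions are Fisher-z transformed and compared
with a pooled-variance normal test, yielding a two-sided p-value that is
calibrated under closure.

Edges are then thresholded on the observed rho (positive > 0.6, negative
< -0.6) jointly with p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .tables_io import CountTable

_ATANH_CLIP = 1.0 - 1e-7


@dataclass
class Thresholds:
    rho_pos: float = 0.6
    rho_neg: float = -0.6
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.rho_pos <= 1 and -1 <= self.rho_neg < 0):
            raise ValueError("rho thresholds must satisfy 0 < rho_pos <= 1 > -rho_neg")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class EdgeRecord:
    otu_a: str
    otu_b: str
    rho: float
    p: float
    sign: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.otu_a >= self.otu_b:
            raise ValueError("edges are stored with otu_a < otu_b")
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"bad sign {self.sign!r}")


@dataclass
class CooccurrenceNetwork:
    nodes: list[str]
    edges: list[EdgeRecord]
    thresholds: Thresholds = field(default_factory=Thresholds)
    provenance: dict = field(default_factory=dict)

    def positive_edges(self) -> list[EdgeRecord]:
        return [e for e in self.edges if e.sign == "positive"]

    def negative_edges(self) -> list[EdgeRecord]:
        return [e for e in self.edges if e.sign == "negative"]

    def positive_subgraph(self) -> nx.Graph:
        """Unweighted graph of positive edges over the non-isolated nodes."""
        g = nx.Graph()
        for e in self.positive_edges():
            g.add_edge(e.otu_a, e.otu_b, rho=e.rho, p=e.p)
        return g

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.otu_a, e.otu_b, rho=e.rho, p=e.p, sign=e.sign)
        for key, value in self.provenance.items():
            g.graph[key] = value
        return g


def _rank_rows(arr: np.ndarray) -> np.ndarray:
    return rankdata(arr, axis=1)


def _spearman_from_counts(arr: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho of the rows (average ranks; NaN for constant rows)."""
    ranks = _rank_rows(arr)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    return rho


def _close_columns(arr: np.ndarray) -> np.ndarray:
    sums = arr.sum(axis=0, keepdims=True)
    return arr / np.where(sums == 0, 1.0, sums)


def spearman_matrix(table: CountTable) -> pd.DataFrame:
    """Pairwise Spearman correlation of OTUs across samples.

    Requires at least 3 samples.  Constant OTU rows have undefined rank
    correlation; their entries are NaN (never edges).  The diagonal is 1 for
    non-constant rows.
    """
    if table.shape[1] < 3:
        raise ValueError("Spearman correlation needs >= 3 samples")
    rho = _spearman_from_counts(table.counts.to_numpy(dtype=float))
    np.fill_diagonal(rho, np.where(np.isnan(np.diag(rho)), np.nan, 1.0))
    return pd.DataFrame(rho, index=table.otu_ids, columns=table.otu_ids)


class _MomentAccumulator:
    """Streaming mean/variance of Fisher-z rho matrices, NaN-tolerant."""

    def __init__(self, n: int) -> None:
        self.count = np.zeros((n, n))
        self.total = np.zeros((n, n))
        self.total_sq = np.zeros((n, n))

    def add(self, rho: np.ndarray) -> None:
        z = np.arctanh(np.clip(rho, -_ATANH_CLIP, _ATANH_CLIP))
        ok = np.isfinite(z)
        z = np.where(ok, z, 0.0)
        self.count += ok
        self.total += z
        self.total_sq += z**2

    def mean_var(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = self.total / self.count
            var = (self.total_sq - self.count * mean**2) / (self.count - 1)
        return mean, np.clip(var, 0.0, None)


def reboot_pvalues(
    table: CountTable, n_iter: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Compositionality-corrected two-sided p-values for all OTU pairs.

    Works on the *raw filtered* count table: each iteration builds either a
    permutation-null replicate (every OTU row independently permuted across
    samples, samples re-closed) or a bootstrap replicate (samples resampled
    with replacement, re-closed), and records the full Spearman matrix.  The
    Fisher-z means of the two distributions are compared with a pooled
    normal statistic z = (m_boot - m_null) / sqrt((v_boot + v_null) / 2).

    Pairs involving an OTU that is constant across samples get p = 1.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if table.is_relative:
        raise ValueError("reboot_pvalues expects raw (filtered) counts")
    arr = table.counts.to_numpy(dtype=float)
    n_otus, n_samples = arr.shape
    rng = np.random.default_rng(seed)

    null_acc = _MomentAccumulator(n_otus)
    boot_acc = _MomentAccumulator(n_otus)
    for _ in range(n_iter):
        # permutation null: shuffle each row independently, then re-close
        order = np.argsort(rng.random((n_otus, n_samples)), axis=1)
        permuted = np.take_along_axis(arr, order, axis=1)
        null_acc.add(_spearman_from_counts(_close_columns(permuted)))
        # bootstrap: resample samples with replacement, re-close
        idx = rng.integers(0, n_samples, size=n_samples)
        boot_acc.add(_spearman_from_counts(_close_columns(arr[:, idx])))

    m_null, v_null = null_acc.mean_var()
    m_boot, v_boot = boot_acc.mean_var()
    pooled_sd = np.sqrt((v_null + v_boot) / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m_boot - m_null) / pooled_sd
    p = 2.0 * ndtr(-np.abs(z))
    p = np.where(np.isfinite(z), p, 1.0)

    observed = _spearman_from_counts(_close_columns(arr))
    p = np.where(np.isfinite(observed), p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=table.otu_ids, columns=table.otu_ids)


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    thresholds: Thresholds | None = None,
    provenance: dict | None = None,
) -> CooccurrenceNetwork:
    """Threshold rho/p matrices into a signed network.

    Positive edges need rho > ``rho_pos`` and p < ``alpha``; negative edges
    rho < ``rho_neg`` and p < ``alpha``.  Both conditions are conjunctive and
    NaN rho never yields an edge.  All OTUs remain as nodes, including
    unconnected ones.
    """
    thresholds = thresholds or Thresholds()
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices must be aligned")
    otus = list(rho.index)
    rho_arr = rho.to_numpy()
    p_arr = p.to_numpy()
    edges = []
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            r = rho_arr[i, j]
            if not np.isfinite(r) or p_arr[i, j] >= thresholds.alpha:
                continue
            if r > thresholds.rho_pos:
                sign = "positive"
            elif r < thresholds.rho_neg:
                sign = "negative"
            else:
                continue
            a, b = sorted((otus[i], otus[j]))
            edges.append(EdgeRecord(a, b, float(r), float(p_arr[i, j]), sign))
    return CooccurrenceNetwork(otus, edges, thresholds, provenance or {})
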