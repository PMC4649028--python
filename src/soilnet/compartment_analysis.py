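"""Biology-facing summaries downstream of clustering.

Covers the soil-intrinsic core microbiome (present in >= 2 of 3 replicates of
every depth x compartment cell, with sd of relative abundance not exceeding
its mean), cluster-to-compartment attribution via summed member abundance per
design cell, ternary (bulk/drilosphere/rhizosphere) coordinates, Venn-style
shared-OTU counts, and the tabulation of negative correlations between
clusters of co-occurring OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist

from .coocc_network import CooccurrenceNetwork
from .markov_stability import Partition
from .preprocess import to_relative
from .tables_io import COMPARTMENT_LEVELS, CountTable, SampleMetadata, TaxonomyTable


@dataclass
class CoreSet:
    """Intrinsic core microbiome: members plus their share of all reads."""

    members: list[str]
    fraction_of_reads: float
    scope: str = "all"
    stats: pd.DataFrame = field(default=None)  # mean/sd relative abundance


def _presence_ok(
    table: CountTable, meta: SampleMetadata, cells: list[tuple[str, str]]
) -> pd.Series:
    """Per OTU: count > 0 in >= 2 replicates of every given design cell."""
    ok = pd.Series(True, index=table.counts.index)
    for depth, comp in cells:
        samples = meta.samples_in_cell(depth, comp)
        if len(samples) < 2:
            raise ValueError(
                f"design cell ({depth}, {comp}) has fewer than 2 replicates"
            )
        present = (table.counts[samples] > 0).sum(axis=1)
        ok &= present >= 2
    return ok


def core_microbiome(
    table: CountTable, meta: SampleMetadata, sd_rule: bool = True
) -> CoreSet:
    """Soil-intrinsic core OTUs on a subsampled raw table.

    An OTU is core iff (a) it is present (count > 0) in at least 2 replicates
    of every design cell and (b) the standard deviation of its relative
    abundance over all samples does not exceed its mean.  The reported
    fraction_of_reads is the members' share of all reads in the table.
    """
    return scoped_core(table, meta, scope="all", sd_rule=sd_rule)


def scoped_core(
    table: CountTable,
    meta: SampleMetadata,
    scope: str = "all",
    sd_rule: bool = True,
) -> CoreSet:
    """Core microbiome restricted to one depth ("topsoil"/"subsoil") or "all"."""
    if scope == "all":
        sub_meta = meta
        sub_table = table
    elif scope in ("topsoil", "subsoil"):
        samples = list(meta.table.index[meta.table["depth"] == scope])
        sub_meta = meta.subset(samples)
        sub_table = CountTable(table.counts[samples].copy())
    else:
        raise ValueError(f"unknown scope {scope!r}")
    cells = sub_meta.cells()
    if not cells:
        raise ValueError(f"no samples in scope {scope!r}")
    ok = _presence_ok(sub_table, sub_meta, cells)
    rel = to_relative(sub_table).counts
    mean = rel.mean(axis=1)
    sd = rel.std(axis=1, ddof=1)
    if sd_rule:
        ok &= sd <= mean
    members = list(sub_table.counts.index[ok])
    total = sub_table.counts.to_numpy().sum()
    member_reads = sub_table.counts.loc[members].to_numpy().sum()
    stats = pd.DataFrame(
        {"mean_rel_abund": mean[ok], "sd_rel_abund": sd[ok]}
    )
    stats.index.name = "otu_id"
    return CoreSet(
        members=members,
        fraction_of_reads=float(member_reads / total) if total else 0.0,
        scope=scope,
        stats=stats,
    )


@dataclass
class TernaryPoint:
    otu_id: str
    bulk: float
    drilosphere: float
    rhizosphere: float
    total_abundance: int

    @property
    def coordinates(self) -> tuple[float, float, float]:
        return (self.bulk, self.drilosphere, self.rhizosphere)


def ternary_coordinates(
    table: CountTable,
    meta: SampleMetadata,
    depth_scope: str = "all",
    min_abundance: int = 5,
) -> list[TernaryPoint]:
    """Barycentric bulk/drilosphere/rhizosphere coordinates per OTU.

    Per compartment the mean relative abundance over its replicates is taken
    first, then the three compartment means are re-closed to sum 1, so
    unequal replicate counts cannot bias the coordinates.  OTUs with total
    reads below ``min_abundance`` in scope are excluded, as are OTUs absent
    from all three compartments.
    """
    if depth_scope == "all":
        samples = list(meta.table.index)
    elif depth_scope in ("topsoil", "subsoil"):
        samples = list(meta.table.index[meta.table["depth"] == depth_scope])
    else:
        raise ValueError(f"unknown depth_scope {depth_scope!r}")
    sub_meta = meta.subset(samples)
    sub = CountTable(table.counts[samples].copy())
    rel = to_relative(sub).counts
    comp_means = {}
    for comp in COMPARTMENT_LEVELS:
        cols = list(
            sub_meta.table.index[sub_meta.table["compartment"] == comp]
        )
        if not cols:
            raise ValueError(f"compartment {comp!r} absent in scope")
        comp_means[comp] = rel[cols].mean(axis=1)
    totals = sub.counts.sum(axis=1)
    points = []
    for otu in sub.counts.index:
        total = int(totals[otu])
        if total < min_abundance:
            continue
        vals = np.array([comp_means[c][otu] for c in COMPARTMENT_LEVELS])
        s = vals.sum()
        if s == 0:
            continue
        vals = vals / s
        points.append(TernaryPoint(otu, *[float(v) for v in vals], total))
    return points


@dataclass
class ClusterAttribution:
    """Per community: mean relative-abundance profile over design cells."""

    profiles: pd.DataFrame  # community rows x design-cell columns, rows sum 1
    attribution: dict[int, tuple[str, str]]  # community -> argmax cell
    ties: set[int]
    dendrogram_order: list[str]  # sample order from complete linkage


def attribute_clusters(
    partition: Partition, table: CountTable, meta: SampleMetadata
) -> ClusterAttribution:
    """Attribute each co-occurrence cluster to a depth x compartment cell.

    The community profile is the summed relative abundance of its member
    OTUs, averaged within each design cell and normalized across cells; the
    attribution is the argmax cell (lexicographic-first on exact ties, which
    are flagged).  A complete-linkage dendrogram order of samples on the
    community x sample abundance matrix is emitted alongside.
    """
    rel = to_relative(table).counts
    cells = meta.cells()
    cell_cols = {cell: meta.samples_in_cell(*cell) for cell in cells}
    rows = {}
    community_samples = {}
    for c in range(partition.k):
        members = [m for m in partition.members(c) if m in rel.index]
        if not members:
            warnings.warn(f"community {c} has no OTUs in the table; skipped",
                          stacklevel=2)
            continue
        per_sample = rel.loc[members].sum(axis=0)
        community_samples[c] = per_sample
        rows[c] = [per_sample[cols].mean() for cols in cell_cols.values()]
    profiles = pd.DataFrame(
        rows, index=[f"{d}:{c}" for d, c in cells]
    ).T
    sums = profiles.sum(axis=1)
    profiles = profiles.div(sums.where(sums > 0, 1.0), axis=0)
    attribution: dict[int, tuple[str, str]] = {}
    ties: set[int] = set()
    for c in profiles.index:
        vals = profiles.loc[c].to_numpy()
        best = int(np.argmax(vals))  # argmax takes the first on ties
        if (vals == vals[best]).sum() > 1:
            ties.add(int(c))
        attribution[int(c)] = cells[best]
    # sample dendrogram on Euclidean distances of community profiles
    mat = pd.DataFrame(community_samples).T  # communities x samples
    if mat.shape[1] > 2 and mat.shape[0] >= 1:
        order = leaves_list(complete(pdist(mat.T.to_numpy())))
        dendro = [mat.columns[i] for i in order]
    else:
        dendro = list(mat.columns)
    return ClusterAttribution(profiles, attribution, ties, dendro)


def cross_cluster_negative_table(
    network: CooccurrenceNetwork,
    partition: Partition,
    tax: TaxonomyTable | None = None,
) -> pd.DataFrame:
    """Negative correlations between clusters of co-occurring OTUs.

    For every ordered cluster pair (X, Y) the OTUs of Y are ranked by how
    many negative edges they have into X.  OTUs carrying negative edges but
    no positive ones (hence absent from the clustering) get the label
    "unclustered".  Columns: cluster_x, cluster_y, otu_id, taxon,
    n_negative_edges.
    """
    label_of = partition.as_dict()

    def cluster_of(otu: str):
        return label_of.get(otu, "unclustered")

    tally: dict[tuple, dict[str, int]] = {}
    for e in network.negative_edges():
        ca, cb = cluster_of(e.otu_a), cluster_of(e.otu_b)
        # e.otu_b in cluster cb negatively correlates into cluster ca, and v.v.
        tally.setdefault((ca, cb), {}).setdefault(e.otu_b, 0)
        tally[(ca, cb)][e.otu_b] += 1
        tally.setdefault((cb, ca), {}).setdefault(e.otu_a, 0)
        tally[(cb, ca)][e.otu_a] += 1
    rows = []
    for (cx, cy), counts in sorted(
        tally.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))
    ):
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        for otu, n in ranked:
            rows.append(
                {
                    "cluster_x": cx,
                    "cluster_y": cy,
                    "otu_id": otu,
                    "taxon": tax.label(otu) if tax is not None and
                    otu in tax.lineage.index else "",
                    "n_negative_edges": n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_x", "cluster_y", "otu_id", "taxon", "n_negative_edges"],
    )


def shared_otu_summary(table: CountTable, meta: SampleMetadata) -> pd.DataFrame:
    """Venn-cell counts of OTU presence across compartments, per depth.

    An OTU counts as present in a compartment when it has count > 0 in at
    least one replicate.  Rows: depth x compartment-subset; column n_otus.
    """
    rows = []
    depths = sorted(set(meta.table["depth"]), key=["topsoil", "subsoil"].index)
    for depth in depths:
        present = {}
        for comp in COMPARTMENT_LEVELS:
            cols = meta.samples_in_cell(depth, comp)
            present[comp] = set(
                table.counts.index[(table.counts[cols] > 0).any(axis=1)]
            )
        comps = list(COMPARTMENT_LEVELS)
        for mask in range(1, 2 ** len(comps)):
            inside = [c for i, c in enumerate(comps) if mask >> i & 1]
            outside = [c for c in comps if c not in inside]
            cell = set(table.counts.index)
            for c in inside:
                cell &= present[c]
            for c in outside:
                cell -= present[c]
            rows.append(
                {
                    "depth": depth,
                    "compartments": "&".join(inside),
                    "n_otus": len(cell),
                }
            )
    return pd.DataFrame(rows, columns=["depth", "compartments", "n_otus"])
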