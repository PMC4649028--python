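"""Synthetic OTU tables with the statistical structure the pipeline assumes.

The generator emulates the post-clustering stage of a compartment-resolved
soil amplicon study: 18 samples (2 depths x 3 compartments x 3 replicate
field plots), a few hundred OTUs, read depths near typical 454 subsampling
minima, and compositional closure via Dirichlet-multinomial sampling.

Planted structure:

* four clusters of co-occurring OTUs, each enriched ``effect_size``-fold in
  its home depth x compartment cell and tied together by a shared per-sample
  log-normal factor (this is what drives within-cluster Spearman rho);
* a set of ubiquitous low-variability core OTUs (constant expected
  abundance, no extra jitter);
* independent log-normal background OTUs;
* per-genus 16S copy numbers and qPCR totals proportional to read depth.

Everything is drawn from one seeded generator, so a design is bit-for-bit
reproducible, and the returned :class:`SyntheticTruth` records the planted
labels for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (
    RANKS,
    CopyNumberTable,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
)

DEFAULT_CLUSTER_CELLS = (
    ("topsoil", "bulk"),
    ("subsoil", "bulk"),
    ("topsoil", "drilosphere"),
    ("subsoil", "rhizosphere"),
)


@dataclass
class SyntheticDesign:
    """Study-design parameters of a generated dataset.

    Defaults mirror the emulated study: 18 samples (2 depths x 3
    compartments x 3 replicate plots), 4 planted clusters of compartment
    specialists with an 8-fold home-cell enrichment, a small set of
    ubiquitous low-variability core OTUs that hold most of the read mass, a
    long rare-background tail, and Dirichlet-multinomial counts at depths
    near typical subsampling minima (~4800 reads).

    Abundance scales are in arbitrary units; per-sample proportions are the
    closure of expected abundances, so only ratios matter.  ``dirichlet_alpha``
    is the symmetric-equivalent per-OTU concentration (the Dirichlet
    concentration vector is ``alpha * n_otus * m`` for expected proportions
    m); larger values approach plain multinomial sampling.
    """

    n_otus: int = 300
    n_clusters: int = 4
    cluster_size: int = 12
    cluster_cells: tuple = DEFAULT_CLUSTER_CELLS
    effect_size: float = 8.0
    latent_sd: float = 0.8
    member_jitter_sd: float = 0.3
    cluster_scale: float = 6.0
    n_core: int = 3
    core_scale: float = 900.0
    core_jitter_sd: float = 0.45
    background_scale: float = 0.7
    background_sd: float = 0.3
    depth_range: tuple[int, int] = (4500, 5000)
    dirichlet_alpha: float = 200.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_clusters * self.cluster_size > self.n_otus:
            raise ValueError("core + cluster OTUs exceed n_otus")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must be positive and ordered")
        if len(self.cluster_cells) < self.n_clusters:
            raise ValueError("need a home cell per cluster")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated dataset."""

    otu_roles: dict[str, str]  # otu -> "cluster<i>" | "core" | "background"
    cluster_members: dict[int, list[str]]
    core_members: list[str]
    cell_expected: pd.DataFrame  # expected relative abundance per design cell
    copy_numbers: dict[str, float]  # genus -> mean copies
    seed: int

    def cluster_labels(self, otus) -> np.ndarray:
        """Integer labels for oracle comparisons; non-cluster OTUs get -1."""
        lookup = {}
        for c, members in self.cluster_members.items():
            for m in members:
                lookup[m] = c
        return np.array([lookup.get(o, -1) for o in otus])


@dataclass
class SyntheticBundle:
    table: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    copy_numbers: CopyNumberTable
    qpcr_totals: pd.Series
    truth: SyntheticTruth


_GENERA = [f"Genus{i:02d}" for i in range(1, 11)]


def _make_metadata(n_replicates: int) -> SampleMetadata:
    rows = []
    for depth, tag in (("topsoil", "T"), ("subsoil", "S")):
        for comp, ctag in (
            ("bulk", "b"),
            ("drilosphere", "d"),
            ("rhizosphere", "r"),
        ):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tag}{ctag}{rep}",
                        "depth": depth,
                        "compartment": comp,
                        "replicate": rep,
                    }
                )
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


def _make_taxonomy(otu_ids: list[str]) -> tuple[TaxonomyTable, dict[str, float]]:
    """Round-robin genera; every 7th OTU left unclassified below family."""
    copy_numbers = {g: float(1 + i % 10) for i, g in enumerate(_GENERA)}
    rows = {}
    for i, otu in enumerate(otu_ids):
        genus = _GENERA[i % len(_GENERA)]
        phylum = f"Phylum{i % 4 + 1}"
        lineage = [
            "Bacteria",
            phylum,
            f"{phylum}_class",
            f"{phylum}_order",
            f"Family{i % 5 + 1}",
            genus,
        ]
        if i % 7 == 3:  # exercise the nearest-classifiable-level fallback
            lineage[5] = f"Family{i % 5 + 1}_unclassified"
        rows[otu] = lineage
    tax = TaxonomyTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    )
    return tax, copy_numbers


def generate_dataset(design: SyntheticDesign) -> SyntheticBundle:
    """Draw one dataset (counts, metadata, taxonomy, copies, qPCR, truth)."""
    rng = np.random.default_rng(design.seed)
    meta = _make_metadata(design.n_replicates)
    samples = meta.sample_ids
    n_samples = len(samples)
    otus = [f"Otu{i + 1:04d}" for i in range(design.n_otus)]

    roles: dict[str, str] = {}
    cluster_members: dict[int, list[str]] = {}
    idx = 0
    for c in range(design.n_clusters):
        cluster_members[c] = otus[idx : idx + design.cluster_size]
        for o in cluster_members[c]:
            roles[o] = f"cluster{c}"
        idx += design.cluster_size
    core_members = otus[idx : idx + design.n_core]
    for o in core_members:
        roles[o] = "core"
    idx += design.n_core
    for o in otus[idx:]:
        roles[o] = "background"

    # expected (unclosed) abundance per OTU and sample, in arbitrary units
    base = np.empty(design.n_otus)
    for i, o in enumerate(otus):
        role = roles[o]
        if role == "core":
            base[i] = design.core_scale * rng.lognormal(0.0, 0.25)
        elif role.startswith("cluster"):
            base[i] = design.cluster_scale * rng.lognormal(0.0, 0.4)
        else:
            base[i] = design.background_scale * rng.lognormal(0.0, 0.4)
    # scales approximate expected reads per sample at typical depths:
    # a few abundant stable core OTUs hold most of the mass, cluster
    # specialists are moderate, and the background tail sits below the
    # co-occurrence prevalence filter

    expected = np.tile(base[:, None], (1, n_samples)).astype(float)
    sample_cell = [meta.cell(s) for s in samples]
    for c, members in cluster_members.items():
        rows = [otus.index(o) for o in members]
        home = design.cluster_cells[c]
        in_home = np.array([cell == home for cell in sample_cell])
        expected[np.ix_(rows, np.flatnonzero(in_home))] *= design.effect_size
        # shared latent factor: one draw per sample, common to the cluster
        latent = rng.lognormal(0.0, design.latent_sd, n_samples)
        expected[rows] *= latent[None, :]
        # member-specific jitter keeps within-cluster correlation below 1
        expected[rows] *= rng.lognormal(
            0.0, design.member_jitter_sd, (len(rows), n_samples)
        )
    core_rows = [i for i, o in enumerate(otus) if roles[o] == "core"]
    expected[core_rows] *= rng.lognormal(
        0.0, design.core_jitter_sd, (len(core_rows), n_samples)
    )
    bg_rows = [i for i, o in enumerate(otus) if roles[o] == "background"]
    expected[bg_rows] *= rng.lognormal(
        0.0, design.background_sd, (len(bg_rows), n_samples)
    )

    depths = rng.integers(
        design.depth_range[0], design.depth_range[1] + 1, n_samples
    )
    counts = np.zeros((design.n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        m = expected[:, j] / expected[:, j].sum()
        p = rng.dirichlet(design.dirichlet_alpha * design.n_otus * m)
        counts[:, j] = rng.multinomial(depths[j], p)

    table = CountTable(pd.DataFrame(counts, index=otus, columns=samples))
    tax, genus_copies = _make_taxonomy(otus)
    cn_entries: dict[tuple[str, str], float] = {("root", "root"): 2.5}
    for g, v in genus_copies.items():
        cn_entries[("genus", g)] = v
    for i in range(1, 6):
        cn_entries[("family", f"Family{i}")] = 2.0 + 0.5 * i
    cn = CopyNumberTable(cn_entries)

    qpcr = pd.Series(
        depths * 1.0e5 * rng.lognormal(0.0, 0.1, n_samples),
        index=samples,
        name="copies_per_g",
    )

    # expected relative abundance per design cell (closure within cell)
    cells = meta.cells()
    cell_expected = {}
    for cell in cells:
        mean_abund = base.copy()
        for c, members in cluster_members.items():
            if design.cluster_cells[c] == cell:
                rows = [otus.index(o) for o in members]
                mean_abund[rows] *= design.effect_size
        cell_expected[f"{cell[0]}:{cell[1]}"] = mean_abund / mean_abund.sum()
    truth = SyntheticTruth(
        otu_roles=roles,
        cluster_members=cluster_members,
        core_members=list(core_members),
        cell_expected=pd.DataFrame(cell_expected, index=otus),
        copy_numbers=genus_copies,
        seed=design.seed,
    )
    return SyntheticBundle(table, meta, tax, cn, qpcr, truth)


def exchangeable_null_table(
    n_otus: int = 120,
    n_samples: int = 18,
    depth: int = 4800,
    dirichlet_alpha: float = 200.0,
    seed: int = 0,
) -> CountTable:
    """Dirichlet-multinomial table with no planted association.

    All OTUs share one composition vector across samples; deviations are pure
    Dirichlet-multinomial noise.  With many OTUs the closure-induced
    correlation is negligible, so this is the null for calibration checks of
    the corrected co-occurrence test.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, n_otus)
    m = base / base.sum()
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = rng.dirichlet(dirichlet_alpha * m * n_otus)
        counts[:, j] = rng.multinomial(depth, p)
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"Otu{i + 1:04d}" for i in range(n_otus)],
            columns=[f"S{j + 1:02d}" for j in range(n_samples)],
        )
    )


def dominant_closed_table(
    n_samples: int = 18,
    depth: int = 2000,
    dominant_mu: float = float(np.log(3.0)),
    dominant_sd: float = 0.7,
    minor_sd: float = 0.7,
    seed: int = 0,
) -> CountTable:
    """4-OTU closed table with one dominant, highly variable OTU.

    The four OTUs have independent absolute abundances, so any correlation in
    the closed (relative) data is a compositional artifact.  The dominant
    OTU's swings drag the minors' relative abundances down, producing the
    classic spurious negative correlations this package's corrected test is
    meant to suppress.
    """
    rng = np.random.default_rng(seed)
    abs_ab = np.empty((4, n_samples))
    abs_ab[0] = rng.lognormal(dominant_mu, dominant_sd, n_samples)
    for i in range(1, 4):
        abs_ab[i] = rng.lognormal(0.0, minor_sd, n_samples)
    counts = np.zeros((4, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depth, abs_ab[:, s] / abs_ab[:, s].sum())
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"Otu{i + 1:04d}" for i in range(4)],
            columns=[f"S{j + 1:02d}" for j in range(n_samples)],
        )
    )


@dataclass
class MicroExample:
    """Hand-sized fixture with hand-computable outcomes."""

    table: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    copy_numbers: CopyNumberTable
    expected_filter_survivors: list[str] = field(default_factory=list)
    expected_core: list[str] = field(default_factory=list)


def worked_micro_example() -> MicroExample:
    """12 OTUs x 18 samples with designed filter and core outcomes.

    Every sample sums to exactly 120 reads (two depth-specific filler OTUs
    absorb the remainder), so relative abundances are counts / 120 and the
    table rarefies cleanly to depth 100.  Exactly 7 OTUs carry >= 6 reads in
    >= 3 samples, and exactly Otu01/Otu02 satisfy the core criteria.
    """
    meta = _make_metadata(3)
    samples = meta.sample_ids
    otus = [f"Otu{i:02d}" for i in range(1, 13)]
    counts = pd.DataFrame(0, index=otus, columns=samples, dtype=np.int64)
    topsoil = [s for s in samples if s.startswith("T")]
    subsoil = [s for s in samples if s.startswith("S")]

    counts.loc["Otu01", :] = 10  # core: constant everywhere
    counts.loc["Otu02", :] = 10  # core: constant everywhere
    counts.loc["Otu03", topsoil] = 8  # passes filter; absent in subsoil
    counts.loc["Otu04", ["Tb1", "Sd2", "Sr3"]] = 30  # bursty: sd > mean
    counts.loc["Otu05", ["Tb1", "Tb2", "Tb3"]] = 6  # minimal filter pass
    counts.loc["Otu06", :] = 5  # below min_reads everywhere
    counts.loc["Otu06", ["Tb2", "Tb3"]] = 0  # and absent in 2 of 3 bulk reps
    counts.loc["Otu07", ["Td1", "Td2"]] = 6  # 6 reads but only 2 samples
    counts.loc["Otu08", ["Tr1", "Sb1", "Sd1"]] = 1
    counts.loc["Otu09", ["Tb1", "Td1", "Tr1", "Sb1", "Sd1"]] = 3
    counts.loc["Otu10", ["Sr1"]] = 1
    # depth-specific fillers bring every column to 120 reads
    for s in topsoil:
        counts.loc["Otu11", s] = 120 - counts[s].sum()
    for s in subsoil:
        counts.loc["Otu12", s] = 120 - counts[s].sum()
    assert (counts.sum(axis=0) == 120).all()

    tax, genus_copies = _make_taxonomy(otus)
    cn_entries: dict[tuple[str, str], float] = {("root", "root"): 2.5}
    for g, v in genus_copies.items():
        cn_entries[("genus", g)] = v
    for i in range(1, 6):
        cn_entries[("family", f"Family{i}")] = 2.0 + 0.5 * i
    return MicroExample(
        table=CountTable(counts),
        metadata=meta,
        taxonomy=tax,
        copy_numbers=CopyNumberTable(cn_entries),
        expected_filter_survivors=[
            "Otu01", "Otu02", "Otu03", "Otu04", "Otu05", "Otu11", "Otu12",
        ],
        expected_core=["Otu01", "Otu02"],
    )
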