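import numpy as np
import pandas as pd
import pytest

from soilnet import compartment_analysis as ca
from soilnet import preprocess as pp
from soilnet.coocc_network import CooccurrenceNetwork, EdgeRecord
from soilnet.markov_stability import Partition
from soilnet.synthetic_data import SyntheticDesign, generate_dataset
from soilnet.tables_io import CountTable
from tests.conftest import random_count_table


def brute_force_core(table, meta, sd_rule=True):
    """Literal reimplementation of the core criteria for oracle checks."""
    rel = table.counts / table.counts.sum(axis=0)
    members = []
    for otu in table.otu_ids:
        ok = True
        for depth, comp in meta.cells():
            cell_samples = meta.samples_in_cell(depth, comp)
            present = sum(table.counts.loc[otu, s] > 0 for s in cell_samples)
            if present < 2:
                ok = False
        if sd_rule:
            vals = rel.loc[otu].to_numpy()
            if vals.std(ddof=1) > vals.mean():
                ok = False
        if ok:
            members.append(otu)
    return members


class TestCoreMicrobiome:
    def test_constant_positive_otu_is_core(self, micro):
        core = ca.core_microbiome(micro.table, micro.metadata)
        assert "Otu01" in core.members  # constant 10 reads everywhere

    def test_absence_in_two_replicates_of_one_cell_excludes(self, micro):
        # Otu06 misses 2 of 3 topsoil-bulk replicates by construction
        core = ca.core_microbiome(micro.table, micro.metadata)
        assert "Otu06" not in core.members

    def test_matches_brute_force_scan(self, micro, rng):
        for _ in range(5):
            t = random_count_table(rng, n_otus=100)
            t.counts.columns = micro.metadata.sample_ids
            core = ca.core_microbiome(t, micro.metadata)
            assert core.members == brute_force_core(t, micro.metadata)

    def test_fraction_of_reads_definition(self, micro):
        core = ca.core_microbiome(micro.table, micro.metadata)
        member_reads = micro.table.counts.loc[core.members].to_numpy().sum()
        assert core.fraction_of_reads == pytest.approx(
            member_reads / micro.table.counts.to_numpy().sum()
        )

    def test_members_recheck_against_criteria(self, micro, rng):
        t = random_count_table(rng, n_otus=80)
        t.counts.columns = micro.metadata.sample_ids
        core = ca.core_microbiome(t, micro.metadata)
        oracle = set(brute_force_core(t, micro.metadata))
        for otu in t.otu_ids:
            assert (otu in oracle) == (otu in core.members)

    def test_cell_with_single_replicate_raises(self, micro):
        meta = micro.metadata.subset(
            [s for s in micro.metadata.sample_ids if s not in ("Tb1", "Tb2")]
        )
        table = CountTable(micro.table.counts[meta.sample_ids].copy())
        with pytest.raises(ValueError, match="fewer than 2"):
            ca.core_microbiome(table, meta)


class TestScopedCore:
    def test_scope_all_equals_core_microbiome(self, micro):
        assert (
            ca.scoped_core(micro.table, micro.metadata, "all").members
            == ca.core_microbiome(micro.table, micro.metadata).members
        )

    def test_topsoil_only_otu_never_all_core(self, micro):
        # Otu03 lives only in topsoil: topsoil-core candidate, never all-core
        top = ca.scoped_core(micro.table, micro.metadata, "topsoil")
        full = ca.core_microbiome(micro.table, micro.metadata)
        assert "Otu03" in top.members
        assert "Otu03" not in full.members

    def test_planted_ubiquitous_otus_recovered_exactly(self):
        design = SyntheticDesign(
            seed=4, n_clusters=0, n_core=10, core_jitter_sd=0.0,
            background_scale=0.05, background_sd=1.5,
        )
        bundle = generate_dataset(design)
        sub = pp.subsample_counts(bundle.table, "auto-min", seed=0)
        for scope in ("all", "topsoil", "subsoil"):
            core = ca.scoped_core(sub, bundle.metadata, scope)
            assert set(core.members) == set(bundle.truth.core_members)


class TestTernary:
    def test_single_compartment_otu_sits_at_tip(self, micro):
        pts = {
            p.otu_id: p
            for p in ca.ternary_coordinates(
                micro.table, micro.metadata, "topsoil", min_abundance=5
            )
        }
        # Otu05 only occurs in topsoil bulk samples
        assert pts["Otu05"].coordinates == pytest.approx((1.0, 0.0, 0.0))

    def test_uniform_otu_sits_at_center(self, micro):
        pts = {
            p.otu_id: p
            for p in ca.ternary_coordinates(
                micro.table, micro.metadata, "topsoil"
            )
        }
        assert pts["Otu01"].coordinates == pytest.approx((1 / 3,) * 3)

    def test_min_abundance_excludes(self, micro):
        pts = ca.ternary_coordinates(
            micro.table, micro.metadata, "topsoil", min_abundance=5
        )
        ids = {p.otu_id for p in pts}
        assert "Otu08" not in ids  # 1 read in topsoil < 5
        pts_all = ca.ternary_coordinates(
            micro.table, micro.metadata, "topsoil", min_abundance=1
        )
        assert "Otu08" in {p.otu_id for p in pts_all}

    def test_coordinates_sum_to_one(self, micro):
        for p in ca.ternary_coordinates(micro.table, micro.metadata, "all"):
            assert sum(p.coordinates) == pytest.approx(1.0)
            assert min(p.coordinates) >= 0

    def test_invariant_to_replicate_count_rescaling(self, micro):
        # duplicating one bulk replicate must not move the coordinates
        # (compartment means are taken before re-closure)
        table = micro.table.counts.copy()
        meta = micro.metadata.table.copy()
        table["Tb4"] = table["Tb1"]
        meta.loc["Tb4"] = ["topsoil", "bulk", 4]
        from soilnet.tables_io import SampleMetadata

        pts1 = {
            p.otu_id: p.coordinates
            for p in ca.ternary_coordinates(
                micro.table, micro.metadata, "topsoil"
            )
        }
        pts2 = {
            p.otu_id: p.coordinates
            for p in ca.ternary_coordinates(
                CountTable(table), SampleMetadata(meta), "topsoil"
            )
        }
        for otu in ("Otu01", "Otu02", "Otu03"):
            assert pts1[otu] == pytest.approx(pts2[otu], abs=1e-9)


class TestAttribution:
    def test_compartment_specific_community_attributed(self, micro):
        partition = Partition(["Otu05", "Otu03"], np.array([0, 1]))
        att = ca.attribute_clusters(partition, micro.table, micro.metadata)
        # Otu05 is exclusively topsoil bulk
        assert att.attribution[0] == ("topsoil", "bulk")

    def test_tied_profile_flagged_and_deterministic(self, micro):
        partition = Partition(["Otu01"], np.array([0]))
        att = ca.attribute_clusters(partition, micro.table, micro.metadata)
        # Otu01 constant everywhere: exact 6-way tie -> lexicographic first
        assert 0 in att.ties
        assert att.attribution[0] == ("topsoil", "bulk")

    def test_planted_clusters_attributed_to_home_cells(self):
        design = SyntheticDesign(seed=6)
        bundle = generate_dataset(design)
        sub = pp.subsample_counts(bundle.table, "auto-min", seed=1)
        nodes, labels = [], []
        for c, members in bundle.truth.cluster_members.items():
            nodes += members
            labels += [c] * len(members)
        partition = Partition(nodes, np.array(labels))
        att = ca.attribute_clusters(partition, sub, bundle.metadata)
        for c in range(design.n_clusters):
            assert att.attribution[c] == design.cluster_cells[c]

    def test_whole_table_community_has_flat_profile(self):
        # exchangeable data: the all-OTU community profile is ~uniform
        from soilnet.synthetic_data import exchangeable_null_table

        table = exchangeable_null_table(n_otus=80, seed=3)
        meta = generate_dataset(SyntheticDesign(seed=0)).metadata
        table.counts.columns = meta.sample_ids
        partition = Partition(table.otu_ids, np.zeros(80, int))
        att = ca.attribute_clusters(partition, table, meta)
        profile = att.profiles.loc[0].to_numpy()
        assert np.allclose(profile, 1 / 6, atol=0.02)

    def test_dendrogram_covers_all_samples(self, micro):
        partition = Partition(["Otu01", "Otu03"], np.array([0, 1]))
        att = ca.attribute_clusters(partition, micro.table, micro.metadata)
        assert sorted(att.dendrogram_order) == sorted(
            micro.metadata.sample_ids
        )


def random_signed_network(rng, n_nodes=15, n_edges=25):
    nodes = [f"o{i:02d}" for i in range(n_nodes)]
    edges = []
    seen = set()
    while len(edges) < n_edges:
        i, j = rng.choice(n_nodes, 2, replace=False)
        a, b = sorted((nodes[i], nodes[j]))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        sign = "negative" if rng.random() < 0.5 else "positive"
        rho = -0.8 if sign == "negative" else 0.8
        edges.append(EdgeRecord(a, b, rho, 0.01, sign))
    return CooccurrenceNetwork(nodes, edges)


class TestNegativeTable:
    def test_no_negative_edges_empty_table(self):
        net = CooccurrenceNetwork(["a", "b"], [])
        part = Partition(["a", "b"], np.array([0, 1]))
        assert ca.cross_cluster_negative_table(net, part).empty

    def test_single_edge_listed_both_directions(self):
        net = CooccurrenceNetwork(
            ["a", "b"], [EdgeRecord("a", "b", -0.7, 0.01, "negative")]
        )
        part = Partition(["a", "b"], np.array([0, 1]))
        table = ca.cross_cluster_negative_table(net, part)
        rows = {
            (r.cluster_x, r.cluster_y, r.otu_id)
            for r in table.itertuples()
        }
        assert rows == {(0, 1, "b"), (1, 0, "a")}

    def test_unclustered_label_for_nodes_without_positive_edges(self):
        net = CooccurrenceNetwork(
            ["a", "z"], [EdgeRecord("a", "z", -0.9, 0.001, "negative")]
        )
        part = Partition(["a"], np.array([0]))  # z has no positive edges
        table = ca.cross_cluster_negative_table(net, part)
        assert set(table["cluster_x"]) == {0, "unclustered"}

    def test_counts_match_brute_force_tally(self, rng):
        for _ in range(5):
            net = random_signed_network(rng)
            labels = rng.integers(0, 3, len(net.nodes))
            part = Partition(net.nodes, labels)
            table = ca.cross_cluster_negative_table(net, part)
            label_of = part.as_dict()
            for row in table.itertuples():
                count = 0
                for e in net.negative_edges():
                    pair = {e.otu_a, e.otu_b}
                    if row.otu_id in pair:
                        other = (pair - {row.otu_id}).pop()
                        if (
                            label_of.get(other, "unclustered") == row.cluster_x
                            and label_of.get(row.otu_id, "unclustered")
                            == row.cluster_y
                        ):
                            count += 1
                assert count == row.n_negative_edges


class TestSharedOtus:
    def test_ubiquitous_otu_in_triple_intersection(self, micro):
        table = ca.shared_otu_summary(micro.table, micro.metadata)
        triple = table[
            (table["compartments"] == "bulk&drilosphere&rhizosphere")
        ]
        assert (triple["n_otus"] >= 1).all()  # Otu01/Otu02 everywhere

    def test_empty_table_gives_zero_cells(self, micro):
        empty = CountTable(
            pd.DataFrame(
                np.empty((0, 18), dtype=int),
                columns=micro.metadata.sample_ids,
            )
        )
        table = ca.shared_otu_summary(empty, micro.metadata)
        assert (table["n_otus"] == 0).all()

    def test_matches_brute_force_set_algebra(self, micro, rng):
        t = random_count_table(rng, n_otus=20)
        t.counts.columns = micro.metadata.sample_ids
        table = ca.shared_otu_summary(t, micro.metadata)
        for row in table.itertuples():
            inside = set(row.compartments.split("&"))
            count = 0
            for otu in t.otu_ids:
                member = set()
                for comp in ("bulk", "drilosphere", "rhizosphere"):
                    cols = micro.metadata.samples_in_cell(row.depth, comp)
                    if (t.counts.loc[otu, cols] > 0).any():
                        member.add(comp)
                count += member == inside
            assert count == row.n_otus
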