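"""Hypergeometric uniqueness, whitelist filtering and phylogenetic debiasing."""

import math

import numpy as np
import pytest

from rgnn import (
    Cluster,
    ClusterAssignment,
    ClusterPfamEdge,
    GNNClusterNode,
    GNNDocument,
    GNNPfamNode,
    PfamAnnotationTable,
    PfamWhitelist,
    SSNDocument,
    SequenceNode,
    TaxonomyTable,
    annotate_pfam_nodes,
    apply_whitelist,
    build_enzyme_whitelist,
    compute_phylum_stat,
    compute_uniqueness,
    dedup_species_per_cluster,
    edge_uniqueness,
    eliminate_subspecies,
    hypergeom_log10_pmf,
)
from rgnn.model import IntegrityError
from rgnn.thresholds import cluster_components

from oracles import exact_hypergeom_pmf


class TestHypergeometric:
    def test_brute_force_enumeration_example(self):
        # all C(10,4)=210 draws; 5 of them take every marked item
        assert hypergeom_log10_pmf(10, 5, 4, 4) == pytest.approx(math.log10(5 / 210), abs=1e-12)
        assert edge_uniqueness(10, 5, 4, 4) == pytest.approx(-math.log10(5 / 210), abs=1e-12)

    @pytest.mark.parametrize("N, M, n, k", [(1, 1, 1, 1), (7, 7, 7, 7), (30, 30, 30, 30)])
    def test_forced_draw_has_probability_one(self, N, M, n, k):
        assert hypergeom_log10_pmf(N, M, n, k) == 0.0
        assert edge_uniqueness(N, M, n, k) == 0.0

    def test_pmf_normalizes(self):
        N, M, n = 20, 7, 9
        total = sum(
            10 ** hypergeom_log10_pmf(N, M, n, k)
            for k in range(max(0, n - (N - M)), min(n, M) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_agreement_with_exact_arithmetic(self):
        # every valid configuration up to N=25 against big-integer rationals
        for N in range(1, 26):
            for M in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n - (N - M)), min(n, M) + 1):
                        exact = float(-math.log10(exact_hypergeom_pmf(N, M, n, k)))
                        got = edge_uniqueness(N, M, n, k)
                        assert got == pytest.approx(exact, rel=1e-10, abs=1e-12)

    def test_doubling_the_configuration_raises_uniqueness(self):
        assert edge_uniqueness(20, 10, 8, 8) > edge_uniqueness(10, 5, 4, 4)

    def test_extreme_values_stay_finite_in_log_space(self):
        # a configuration whose direct probability underflows float64
        value = edge_uniqueness(40000, 4000, 4000, 4000)
        assert value > 400 and math.isfinite(value)

    @pytest.mark.parametrize(
        "args, bound",
        [
            ((10, 11, 4, 4), "0 <= M <= N"),
            ((10, 5, 11, 4), "0 <= n <= N"),
            ((10, 5, 4, 6), "k <= min"),
            ((10, 9, 4, 0), "n - k <= N - M"),
        ],
    )
    def test_domain_errors_name_the_violated_bound(self, args, bound):
        with pytest.raises(ValueError, match=bound):
            hypergeom_log10_pmf(*args)


def _gnn(cluster_sizes, edges):
    """cluster_sizes: {cid: n}; edges: {(cid, pfam): k}."""
    gnn = GNNDocument()
    for cid, n in cluster_sizes.items():
        gnn.add_cluster_node(GNNClusterNode(cid, n))
    for (cid, pfam), k in edges.items():
        if pfam not in gnn.pfam_nodes:
            gnn.add_pfam_node(GNNPfamNode(pfam))
        gnn.add_edge(ClusterPfamEdge(cid, pfam, k, k / cluster_sizes[cid]))
    return gnn


class TestComputeUniqueness:
    def test_single_forced_cluster_scores_zero(self):
        gnn = _gnn({1: 4}, {(1, "PF1"): 4})
        report = compute_uniqueness(gnn)
        assert report.edge[(1, "PF1")] == 0.0
        assert report.cluster[1] == 0.0
        assert report.pfam["PF1"] == 0.0

    def test_two_cluster_pfam_uniqueness_matches_enumeration(self):
        # N=10; PF_X held by all 4 members of cluster 1 and 1 of 6 in cluster 2
        gnn = _gnn({1: 4, 2: 6}, {(1, "PF_X"): 4, (2, "PF_X"): 1})
        report = compute_uniqueness(gnn)
        expected = -math.log10(exact_hypergeom_pmf(10, 5, 4, 4)) - math.log10(
            exact_hypergeom_pmf(10, 5, 6, 1)
        )
        assert report.pfam["PF_X"] == pytest.approx(float(expected), rel=1e-12)
        assert gnn.pfam_nodes["PF_X"].uniqueness == pytest.approx(float(expected), rel=1e-12)

    def test_cluster_value_is_sum_of_edge_values(self):
        gnn = _gnn({1: 5, 2: 5}, {(1, "PF1"): 4, (1, "PF2"): 3, (2, "PF1"): 1})
        report = compute_uniqueness(gnn)
        assert report.cluster[1] == pytest.approx(
            report.edge[(1, "PF1")] + report.edge[(1, "PF2")]
        )
        assert report.pfam["PF1"] == pytest.approx(
            report.edge[(1, "PF1")] + report.edge[(2, "PF1")]
        )
        assert all(v >= 0 for v in report.edge.values())

    def test_inconsistent_supporting_count_rejected(self):
        gnn = GNNDocument()
        gnn.add_cluster_node(GNNClusterNode(1, 2))
        gnn.add_pfam_node(GNNPfamNode("PF1"))
        gnn.edges[(1, "PF1")] = ClusterPfamEdge(1, "PF1", 5, 1.0)  # k > n, bypass add_edge
        with pytest.raises(IntegrityError, match="exceeds"):
            compute_uniqueness(gnn)

    def test_exclusive_cluster_outranks_uniformly_spread_one(self):
        # cluster 1's Pfams occur only inside cluster 1; cluster 2's spread evenly
        sizes = {1: 20, 2: 20, 3: 20, 4: 20}
        edges = {(1, f"PF1000{i}"): 18 for i in range(4)}
        for cid in sizes:
            edges[(cid, "PF20000")] = 10  # uniform background Pfam
        gnn = _gnn(sizes, edges)
        report = compute_uniqueness(gnn)
        assert report.cluster[1] > report.cluster[2]


class TestWhitelist:
    def test_filtering_keeps_only_admitted_pfams(self):
        gnn = _gnn({1: 3}, {(1, "PF00117"): 2, (1, "PF99999"): 2})
        out = apply_whitelist(gnn, PfamWhitelist({"PF00117"}))
        assert set(out.pfam_nodes) == {"PF00117"}
        assert set(out.edges) == {(1, "PF00117")}

    def test_empty_whitelist_leaves_hubs_only(self):
        gnn = _gnn({1: 3}, {(1, "PF00117"): 2})
        out = apply_whitelist(gnn, PfamWhitelist())
        assert set(out.cluster_nodes) == {1}
        assert not out.pfam_nodes and not out.edges

    def test_composite_passes_if_any_component_passes(self):
        gnn = _gnn({1: 3}, {(1, "PF04055-PF13394"): 2, (1, "PF11111-PF22222"): 2})
        out = apply_whitelist(gnn, PfamWhitelist({"PF04055"}))
        assert set(out.pfam_nodes) == {"PF04055-PF13394"}

    def test_idempotent(self):
        gnn = _gnn({1: 3}, {(1, "PF00117"): 2, (1, "PF99999"): 2})
        wl = PfamWhitelist({"PF00117"})
        once = apply_whitelist(gnn, wl)
        assert apply_whitelist(once, wl) == once

    @pytest.mark.parametrize(
        "description, included",
        [
            ("Glutamine amidotransferase class-I, EC 2.4.2.18", True),
            ("Transferase of unknown specificity (2.4.-.-)", True),
            ("7 transmembrane receptor", False),
            ("Catalytic domain of a protein kinase", True),
            ("Component of the holoENZYME", True),  # substring, case-insensitive
            ("Binds ions at pH 7.4", False),  # not a 4-field EC pattern
        ],
    )
    def test_enzyme_whitelist_rule(self, description, included):
        table = PfamAnnotationTable()
        table.add("PF00001", description)
        wl = build_enzyme_whitelist(table)
        assert ("PF00001" in wl) is included


def _taxonomy():
    tax = TaxonomyTable()
    tax.add(562, 562, "Proteobacteria")
    tax.add(83333, 562, "Proteobacteria")  # subspecies of 562
    tax.add(632, 632, "Proteobacteria")
    tax.add(1423, 1423, "Firmicutes")
    return tax


class TestSubspeciesElimination:
    def test_subspecies_accession_removed_node_survives(self):
        ssn = SSNDocument()
        ssn.add_node(SequenceNode("R", ["a1", "a2"], [562, 83333]))
        result = eliminate_subspecies(ssn, _taxonomy())
        node = result.ssn.nodes["R"]
        assert node.accessions == ["a1"] and node.seq_count == 1

    def test_node_of_only_subspecies_deleted_with_edges(self):
        ssn = SSNDocument()
        ssn.add_node(SequenceNode("S", ["a1"], [83333]))
        ssn.add_node(SequenceNode("K", ["b1"], [562]))
        ssn.add_edge("S", "K", 50)
        result = eliminate_subspecies(ssn, _taxonomy())
        assert "S" not in result.ssn.nodes and result.ssn.n_edges == 0

    def test_uncovered_taxid_kept_and_reported(self):
        ssn = SSNDocument()
        ssn.add_node(SequenceNode("U", ["a1"], [99999]))
        result = eliminate_subspecies(ssn, _taxonomy())
        assert result.ssn.nodes["U"].accessions == ["a1"]
        assert result.unknown_taxids == (99999,)

    def test_idempotent(self, small_dataset):
        once = eliminate_subspecies(small_dataset.ssn, small_dataset.taxonomy).ssn
        twice = eliminate_subspecies(once, small_dataset.taxonomy).ssn
        assert twice == once
        # all planted subspecies really are gone
        remaining = {a for node in once.nodes.values() for a in node.accessions}
        assert not remaining & small_dataset.truth.subspecies_accessions


def _clustered_ssn(node_specs):
    """node_specs: list of (node_id, [(acc, taxid), ...], linked_to_or_None)."""
    ssn = SSNDocument()
    for node_id, pairs, _ in node_specs:
        ssn.add_node(SequenceNode(node_id, [a for a, _ in pairs], [t for _, t in pairs]))
    for node_id, _, link in node_specs:
        if link is not None:
            ssn.add_edge(node_id, link, 99)
    return ssn, cluster_components(ssn)


class TestSpeciesDedup:
    def test_same_species_collapses_to_smallest_accession(self):
        ssn, assignment = _clustered_ssn([
            ("n1", [("accB", 562)], "n2"),
            ("n2", [("accA", 562), ("accC", 562)], None),
        ])
        deduped, new_ssn = dedup_species_per_cluster(assignment, ssn, _taxonomy())
        assert deduped.clusters[1].accessions == ["accA"]
        assert "n1" not in new_ssn.nodes  # emptied node disappears

    def test_distinct_species_both_kept(self):
        ssn, assignment = _clustered_ssn([
            ("n1", [("accA", 562)], "n2"),
            ("n2", [("accB", 632)], None),
        ])
        deduped, _ = dedup_species_per_cluster(assignment, ssn, _taxonomy())
        assert deduped.clusters[1].accessions == ["accA", "accB"]

    def test_rule_is_per_cluster(self):
        # same species in two clusters: one representative kept in each
        ssn, assignment = _clustered_ssn([
            ("n1", [("accA", 562), ("accB", 562)], None),
            ("n2", [("accC", 562), ("accD", 562)], None),
        ])
        deduped, _ = dedup_species_per_cluster(assignment, ssn, _taxonomy())
        kept = {cid: c.accessions for cid, c in deduped.clusters.items()}
        assert sorted(kept.values()) == [["accA"], ["accC"]]

    def test_unknown_taxids_never_removed(self):
        ssn, assignment = _clustered_ssn([
            ("n1", [("accA", 0), ("accB", 0), ("accC", 77777)], None),
        ])
        deduped, _ = dedup_species_per_cluster(assignment, ssn, _taxonomy())
        assert deduped.clusters[1].accessions == ["accA", "accB", "accC"]

    def test_idempotent_and_multiplicity_bounded(self, small_dataset):
        assignment = cluster_components(small_dataset.ssn)
        tax = small_dataset.taxonomy
        once_a, once_s = dedup_species_per_cluster(assignment, small_dataset.ssn, tax)
        twice_a, twice_s = dedup_species_per_cluster(once_a, once_s, tax)
        assert twice_s == once_s
        assert {c.id: c.accessions for c in twice_a.clusters.values()} == {
            c.id: c.accessions for c in once_a.clusters.values()
        }
        for cluster in once_a.clusters.values():
            anchors = [
                tax.anchor(t)
                for t in cluster.accession_taxids.values()
                if t in tax
            ]
            assert len(anchors) == len(set(anchors))


class TestPhylumStat:
    def test_normalized_frequencies(self):
        ssn, assignment = _clustered_ssn([
            ("n1", [("a1", 562), ("a2", 562), ("a3", 632), ("a4", 1423)], None),
        ])
        stats = compute_phylum_stat(assignment, ssn, _taxonomy())
        assert stats[1] == {"Proteobacteria": 0.75, "Firmicutes": 0.25}

    def test_single_phylum_cluster(self):
        ssn, assignment = _clustered_ssn([("n1", [("a1", 562)], None)])
        assert compute_phylum_stat(assignment, ssn, _taxonomy())[1] == {"Proteobacteria": 1.0}

    def test_unknown_taxids_excluded_from_denominator(self):
        ssn, assignment = _clustered_ssn([
            ("n1", [("a1", 1423), ("a2", 1423), ("a3", 0), ("a4", 88888)], None),
        ])
        assert compute_phylum_stat(assignment, ssn, _taxonomy())[1] == {"Firmicutes": 1.0}

    def test_all_unknown_gives_empty_map(self):
        ssn, assignment = _clustered_ssn([("n1", [("a1", 0)], None)])
        assert compute_phylum_stat(assignment, ssn, _taxonomy())[1] == {}

    def test_sums_to_one_on_synthetic_clusters(self, small_dataset):
        assignment = cluster_components(small_dataset.ssn)
        stats = compute_phylum_stat(assignment, small_dataset.ssn, small_dataset.taxonomy)
        for stat in stats.values():
            assert stat and sum(stat.values()) == pytest.approx(1.0, abs=1e-9)


class TestAnnotation:
    def test_description_and_go_terms_attached(self):
        gnn = _gnn({1: 2}, {(1, "PF00117"): 2})
        table = PfamAnnotationTable()
        table.add("PF00117", "GATase class-I", ["GO:0006541"])
        annotate_pfam_nodes(gnn, table)
        node = gnn.pfam_nodes["PF00117"]
        assert node.description == "GATase class-I"
        assert node.go_terms == ("GO:0006541",)

    def test_missing_entry_leaves_fields_empty(self):
        gnn = _gnn({1: 2}, {(1, "PF00117"): 2})
        annotate_pfam_nodes(gnn, PfamAnnotationTable())
        node = gnn.pfam_nodes["PF00117"]
        assert node.description is None and node.go_terms == ()

    def test_composite_concatenates_component_annotations(self):
        gnn = _gnn({1: 2}, {(1, "PF04055-PF13394"): 2})
        table = PfamAnnotationTable()
        table.add("PF04055", "Radical SAM", ["GO:0003824"])
        table.add("PF13394", "4Fe-4S binding", ["GO:0051536"])
        annotate_pfam_nodes(gnn, table)
        node = gnn.pfam_nodes["PF04055-PF13394"]
        assert node.description == "Radical SAM; 4Fe-4S binding"
        assert node.go_terms == ("GO:0003824", "GO:0051536")
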