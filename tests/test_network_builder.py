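import pytest

from pathweaver import (
    CollectionSpec,
    InteractionRecord,
    ParticipantRef,
    Pathway,
    PathwayCollection,
    UnifiedNetwork,
    build_network,
    canonical_interaction_key,
    connected_components,
    generate_collection,
    read_exclusion_list,
    summarize,
)
from conftest import directed, gp


class TestCanonicalKey:
    def test_same_record_from_two_pathways_merges(self):
        a = directed("I1", "P1", "A", "B")
        b = directed("IX", "P2", "A", "B")
        assert canonical_interaction_key(a) == canonical_interaction_key(b)

    def test_reversed_direction_differs(self):
        assert canonical_interaction_key(
            directed("I1", "P1", "A", "B")
        ) != canonical_interaction_key(directed("I1", "P1", "B", "A"))

    def test_interaction_type_is_part_of_key(self):
        und = InteractionRecord(
            "I1", "complex_participation", [gp("A"), gp("B")], "P1"
        )
        und2 = InteractionRecord("I2", "undirected", [gp("A"), gp("B")], "P1")
        assert canonical_interaction_key(und) != canonical_interaction_key(und2)


class TestBuildNetwork:
    def test_fixture_merges_and_counts(self, two_pathway_collection):
        net = build_network(two_pathway_collection)
        assert len(net.interaction_node_ids) == 2
        assert net.n_nodes == 5  # 2 interactions + A, B, D
        assert net.n_edges == 4
        merged = [
            net.graph.nodes[n]
            for n in net.interaction_node_ids
            if net.graph.nodes[n]["occurrence_count"] == 2
        ]
        assert len(merged) == 1
        assert merged[0]["provenance"] == {"P1", "P2"}
        assert net.report.n_records_merged_away == 1

    def test_exclusion_can_empty_a_record(self):
        coll = PathwayCollection(
            pathways=[Pathway("P1", "p")],
            interactions=[
                InteractionRecord(
                    "I1",
                    "directed",
                    [
                        gp("A", "source"),
                        ParticipantRef("chebi:ATP", "metabolite", "target"),
                    ],
                    "P1",
                )
            ],
        )
        net = build_network(coll, exclusion_list={"chebi:ATP"})
        assert net.n_nodes == 0
        assert net.report.n_records_dropped_small == 1
        assert net.report.n_participant_refs_excluded == 1

    def test_empty_collection(self):
        net = build_network(PathwayCollection())
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_exclusion_applied_before_size_rule(self):
        # a 3-participant record keeps 2 after exclusion and survives
        coll = PathwayCollection(
            pathways=[Pathway("P1", "p")],
            interactions=[
                InteractionRecord(
                    "I1",
                    "directed",
                    [
                        gp("A", "source"),
                        gp("B", "target"),
                        ParticipantRef("chebi:ATP", "metabolite", "target"),
                    ],
                    "P1",
                )
            ],
        )
        net = build_network(coll, exclusion_list={"chebi:ATP"})
        assert net.n_nodes == 3
        assert "chebi:ATP" not in net.graph

    def test_participant_with_two_roles_gives_two_edges(self):
        coll = PathwayCollection(
            pathways=[Pathway("P1", "p")],
            interactions=[
                InteractionRecord(
                    "I1",
                    "directed",
                    [gp("A", "source"), gp("A", "target"), gp("B", "target")],
                    "P1",
                )
            ],
        )
        net = build_network(coll)
        assert net.n_edges == 3  # A/source, A/target, B/target
        assert net.n_nodes == 3

    def test_within_pathway_duplicate_merges_with_single_provenance(self):
        coll = PathwayCollection(
            pathways=[Pathway("P1", "p")],
            interactions=[
                directed("I1", "P1", "A", "B"),
                directed("I2", "P1", "A", "B"),
            ],
        )
        net = build_network(coll)
        s = summarize(net)
        assert s.n_interactions_multi_occurrence == 1
        assert s.n_interactions_multi_pathway == 0

    def test_build_is_order_insensitive(self, two_pathway_collection):
        net1 = build_network(two_pathway_collection)
        shuffled = PathwayCollection(
            list(reversed(two_pathway_collection.pathways)),
            list(reversed(two_pathway_collection.interactions)),
        )
        net2 = build_network(shuffled)
        assert set(net1.graph.nodes) == set(net2.graph.nodes)
        canon = lambda g: sorted(
            (min(u, v), max(u, v), k) for u, v, k in g.edges(keys=True)
        )
        assert canon(net1.graph) == canon(net2.graph)


class TestComponentsAndSummary:
    def test_fixture_single_component(self, two_pathway_collection):
        net = build_network(two_pathway_collection)
        comps = connected_components(net)
        assert [len(c) for c in comps] == [5]

    def test_disjoint_interactions_two_components(self):
        coll = PathwayCollection(
            pathways=[Pathway("P1", "p")],
            interactions=[
                directed("I1", "P1", "A", "B"),
                directed("I2", "P1", "C", "D"),
            ],
        )
        comps = connected_components(build_network(coll))
        assert [len(c) for c in comps] == [3, 3]
        # ties broken by smallest member id
        assert min(comps[0]) < min(comps[1])

    def test_empty_network_has_no_components(self):
        assert connected_components(build_network(PathwayCollection())) == []

    def test_summary_of_fixture(self, two_pathway_collection):
        s = summarize(build_network(two_pathway_collection))
        assert s.n_interaction_nodes == 2
        assert s.n_gene_products == 3
        assert s.n_interactions_multi_occurrence == 1
        assert s.n_interactions_multi_pathway == 1
        assert sum([s.n_gene_products, s.n_metabolites, s.n_complexes,
                    s.n_interaction_nodes]) == s.n_nodes
        assert sum(s.component_sizes) == s.n_nodes


class TestInvariantsOnGeneratedCollections:
    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_bipartite_degree_exclusion_conservation(self, seed):
        spec = CollectionSpec(
            n_pathways=6,
            interactions_median=6,
            n_gene_products=80,
            n_metabolites=30,
            n_complexes=30,
            n_currency_metabolites=4,
            currency_attach_rate=0.3,
            seed=seed,
        )
        coll, truth = generate_collection(spec)
        net = build_network(coll, truth.currency_ids)
        net.validate()  # bipartiteness + degree + provenance invariants
        for cur in truth.currency_ids:
            assert cur not in net.graph
        # conservation: edges = sum of distinct (participant, role) pairs
        total = sum(
            net.graph.number_of_edges(n, v)
            for n in net.interaction_node_ids
            for v in set(net.graph[n])
        )
        assert total == net.n_edges

    def test_generator_truth_predicts_summary(self):
        spec = CollectionSpec(
            n_pathways=8, interactions_median=5, n_gene_products=60,
            n_metabolites=25, n_complexes=25, seed=99,
        )
        coll, truth = generate_collection(spec)
        net = build_network(coll, truth.currency_ids)
        assert summarize(net).as_dict() == truth.expected_summary


class TestExports:
    def test_graphml_round_trip(self, two_pathway_collection, tmp_path):
        net = build_network(two_pathway_collection)
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = UnifiedNetwork.from_graphml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert sorted(back.graph.edges(keys=True)) == sorted(net.graph.edges(keys=True))
        for n in net.interaction_node_ids:
            assert back.graph.nodes[n]["provenance"] == net.graph.nodes[n]["provenance"]
            assert (
                back.graph.nodes[n]["occurrence_count"]
                == net.graph.nodes[n]["occurrence_count"]
            )

    def test_sif_and_tables(self, two_pathway_collection, tmp_path):
        net = build_network(two_pathway_collection)
        net.write_sif(tmp_path / "net.sif")
        net.write_node_table(tmp_path / "nodes.tsv")
        net.write_edge_table(tmp_path / "edges.tsv")
        sif = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert len(sif) == net.n_edges
        hubs = {line.split("\t")[0] for line in sif}
        assert hubs <= set(net.interaction_node_ids)

    def test_exclusion_list_reader(self, tmp_path):
        p = tmp_path / "excl.txt"
        p.write_text("# currency\nchebi:ATP\nchebi:H2O  # water\n\n")
        assert read_exclusion_list(p) == {"chebi:ATP", "chebi:H2O"}
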