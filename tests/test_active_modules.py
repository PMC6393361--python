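import math

import numpy as np
import pytest

from pathweaver import (
    ActiveModule,
    CalibrationTable,
    CollectionSpec,
    GeneStatTable,
    NodeZScores,
    Pathway,
    PathwayCollection,
    PlantSpec,
    SearchParams,
    ValidationError,
    aggregate_score,
    build_network,
    calibrate,
    corrected_score,
    generate_collection,
    generate_expression,
    greedy_search,
    map_and_merge,
    module_report,
    select_modules,
    z_from_p,
)
from pathweaver.active_modules import module_overlap
from conftest import directed
from oracles import naive_greedy_best

# frozen standard-normal quantiles (reference table values)
Z_095 = 1.6448536269514722


class TestZFromP:
    def test_median_maps_to_zero(self):
        assert z_from_p(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_p_005(self):
        assert z_from_p(0.05) == pytest.approx(Z_095, abs=1e-9)

    def test_clamp_keeps_extremes_finite(self):
        assert z_from_p(0.0, clamp_epsilon=1e-12) == z_from_p(1e-12)
        assert math.isfinite(z_from_p(1.0))

    def test_monotone_decreasing(self):
        ps = np.linspace(0.01, 0.99, 25)
        zs = z_from_p(ps)
        assert np.all(np.diff(zs) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            z_from_p(1.5)


class TestAggregateScore:
    def test_four_unit_scores(self):
        assert aggregate_score([1.0] * 4) == pytest.approx(2.0)

    def test_single_node_identity(self):
        assert aggregate_score([3.3]) == pytest.approx(3.3)

    def test_symmetric_pair_cancels(self):
        assert aggregate_score([1.0, -1.0]) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_score([])

    def test_lower_p_never_lowers_aggregate(self):
        # monotone scoring: improving one member's p raises zA
        ps = [0.3, 0.5, 0.8]
        base = aggregate_score([z_from_p(p) for p in ps])
        for i in range(len(ps)):
            better = list(ps)
            better[i] = ps[i] / 2
            assert aggregate_score([z_from_p(p) for p in better]) >= base


class TestCalibration:
    def test_standard_normal_population(self):
        rng = np.random.default_rng(5)
        scores = NodeZScores({f"n{i}": float(z) for i, z in enumerate(rng.normal(size=500))})
        calib = calibrate(scores, k_max=10, n_draws=2000, seed=42)
        bound = 3.0 / math.sqrt(2000)
        for k in range(1, 11):
            assert abs(calib.mu[k]) < 3 * (1.0 / math.sqrt(2000)) + 0.1
            assert abs(calib.sigma[k] - 1.0) < 0.1
        assert abs(calib.mu[5]) < 10 * bound

    def test_degenerate_equal_scores_floor(self):
        scores = NodeZScores({f"n{i}": 2.0 for i in range(20)})
        calib = calibrate(scores, k_max=4, n_draws=200, seed=1)
        assert calib.mu[4] == pytest.approx(2.0 * math.sqrt(4))
        assert calib.sigma[4] == pytest.approx(0.0, abs=1e-12)
        # sigma floor keeps the corrected score finite
        s = corrected_score(["n0", "n1"], scores, calib)
        assert math.isfinite(s)

    def test_same_seed_reproduces_table(self):
        scores = NodeZScores({f"n{i}": float(i) / 7 for i in range(30)})
        a = calibrate(scores, k_max=5, n_draws=300, seed=9)
        b = calibrate(scores, k_max=5, n_draws=300, seed=9)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_k_max_beyond_population_rejected(self):
        scores = NodeZScores({"a": 1.0, "b": 2.0})
        with pytest.raises(ValidationError):
            calibrate(scores, k_max=3, n_draws=200, seed=0)


class TestCorrectedScore:
    def test_identity_calibration_returns_aggregate(self):
        scores = NodeZScores({"a": 1.0, "b": 3.0})
        calib = CalibrationTable.identity(5)
        assert corrected_score(["a", "b"], scores, calib) == pytest.approx(
            4.0 / math.sqrt(2)
        )

    def test_single_node_at_background_mean_scores_zero(self):
        scores = NodeZScores({"a": 1.5})
        calib = CalibrationTable.identity(2)
        calib.mu[1] = 1.5
        assert corrected_score(["a"], scores, calib) == pytest.approx(0.0)

    def test_unscored_members_contribute_nothing(self):
        scores = NodeZScores({"a": 2.0})
        calib = CalibrationTable.identity(5)
        assert corrected_score(["a", "rx:x", "chebi:m"], scores, calib) == 2.0

    def test_no_scored_members_rejected(self):
        with pytest.raises(ValidationError):
            corrected_score(["rx:x"], NodeZScores({"a": 1.0}), CalibrationTable.identity(3))


def _path_network():
    """A - I1 - B: two scored genes joined by one interaction node."""
    coll = PathwayCollection(
        pathways=[Pathway("P1", "p")],
        interactions=[directed("I1", "P1", "A", "B")],
    )
    return build_network(coll)


class TestGreedySearch:
    def test_hand_traced_path_adoption(self):
        net = _path_network()
        scores = NodeZScores({"ensembl:A": 3.0, "ensembl:B": 3.0})
        calib = CalibrationTable.identity(5)
        mods = greedy_search(net, scores, calib, SearchParams())
        top = mods[0]
        assert top.scored_k == 2
        assert top.raw_score == pytest.approx(6.0 / math.sqrt(2))
        assert len(top.member_node_ids) == 3  # A, I1, B
        assert top.pathway_contributions == {"P1": 1}

    def test_isolated_high_scorer_stays_singleton(self):
        net = _path_network()
        # B's z is negative: adopting it would lower the aggregate
        scores = NodeZScores({"ensembl:A": 4.0, "ensembl:B": -1.0})
        calib = CalibrationTable.identity(5)
        top = greedy_search(net, scores, calib, SearchParams())[0]
        assert top.member_node_ids == frozenset({"ensembl:A"})
        assert top.corrected == pytest.approx(4.0)

    def test_no_scored_nodes_is_an_error(self):
        net = _path_network()
        with pytest.raises(ValidationError):
            greedy_search(net, NodeZScores({}), CalibrationTable.identity(3), SearchParams())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_reimplementation(self, seed):
        """Optimized incremental search equals a from-scratch greedy
        restatement on small random planted networks."""
        cspec = CollectionSpec(
            n_pathways=4, interactions_median=4, n_gene_products=30,
            n_metabolites=10, n_complexes=10, n_currency_metabolites=0,
            currency_attach_rate=0.0, seed=seed,
        )
        coll, truth = generate_collection(cspec)
        net = build_network(coll)
        rng = np.random.default_rng(seed + 100)
        genes = net.nodes_of_kind("gene_product")
        picked = sorted(rng.choice(genes, size=min(8, len(genes)), replace=False))
        scores = NodeZScores({g: float(rng.normal(1.0, 1.5)) for g in picked})
        calib = calibrate(scores, k_max=len(picked), n_draws=300, seed=seed)
        params = SearchParams(max_module_scored=len(picked))
        best = greedy_search(net, scores, calib, params)[0]
        naive = naive_greedy_best(
            net.graph, scores.z, calib.mu, calib.sigma,
            radius=2 * params.search_depth, k_cap=len(picked),
        )
        assert best.corrected == pytest.approx(naive[3], abs=1e-9)
        # scored membership must agree; unscored connector choice may
        # differ between exactly tied shortest paths
        assert best.member_node_ids & scores.scored_set == (
            frozenset(naive[0]) & scores.scored_set
        )
        assert best.scored_k == naive[2]


class TestSelectModules:
    def _mod(self, members, score, seed="s"):
        return ActiveModule(
            member_node_ids=frozenset(members), scored_k=len(members),
            raw_score=score, corrected=score, seed_id=seed,
        )

    def test_identical_candidates_second_rejected(self):
        mods = [self._mod("abc", 5.0), self._mod("abc", 4.0)]
        assert select_modules(mods, SearchParams(overlap_threshold=0.99)) == [mods[0]]

    def test_disjoint_candidates_accepted_up_to_n(self):
        mods = [self._mod([c], 9.0 - i) for i, c in enumerate("abcdefg")]
        out = select_modules(mods, SearchParams(n_modules=5, overlap_threshold=0.8))
        assert out == mods[:5]

    def test_half_overlap_passes_at_08(self):
        a = self._mod("abcd", 5.0)
        b = self._mod("cdef", 4.0)
        assert select_modules([a, b], SearchParams(overlap_threshold=0.8)) == [a, b]

    def test_overlap_measures(self):
        a, b = frozenset("abcd"), frozenset("cdef")
        assert module_overlap(a, b, "min") == pytest.approx(0.5)
        assert module_overlap(a, b, "jaccard") == pytest.approx(2 / 6)


class TestModuleReport:
    def test_pathway_contributions_fan_out(self, two_pathway_collection):
        net = build_network(two_pathway_collection)
        shared = [
            n for n in net.interaction_node_ids
            if net.graph.nodes[n]["occurrence_count"] == 2
        ][0]
        mod = ActiveModule(
            member_node_ids=frozenset({"ensembl:A", shared, "ensembl:B"}),
            scored_k=2, raw_score=1.0, corrected=1.0, seed_id="ensembl:A",
        )
        table = GeneStatTable({"ensembl:A": (1.0, 0.001), "ensembl:B": (0.0, 0.9)})
        rep = module_report(mod, net, "pvalue < 0.05", table)
        assert rep.pathway_contributions == {"P1": 1, "P2": 1}
        assert rep.n_significant == 1
        assert rep.members_by_kind == {"gene_product": 2, "interaction": 1}

    def test_unmeasured_module_has_no_significant_members(self, two_pathway_collection):
        net = build_network(two_pathway_collection)
        mod = ActiveModule(
            member_node_ids=frozenset({"ensembl:D"}), scored_k=0,
            raw_score=0.0, corrected=0.0, seed_id="ensembl:D",
        )
        rep = module_report(mod, net, "pvalue < 0.05", GeneStatTable({}))
        assert rep.n_significant == 0


class TestPlantedSignal:
    def test_planted_module_outscores_random_sets(self):
        cspec = CollectionSpec(
            n_pathways=20, interactions_median=10, n_gene_products=300, seed=3
        )
        coll, truth = generate_collection(cspec)
        net = build_network(coll, truth.currency_ids)
        probes, idmap, et = generate_expression(
            net, PlantSpec(planted_size=10, seed=4)
        )
        table = map_and_merge(probes, idmap)
        from pathweaver import scores_from_table

        scores = scores_from_table(table, net.graph.nodes)
        calib = calibrate(scores, k_max=12, n_draws=500, seed=5)
        planted_s = corrected_score(et.planted_genes, scores, calib)
        rng = np.random.default_rng(6)
        pool = sorted(scores.z)
        rand_scores = [
            corrected_score(rng.choice(pool, size=10, replace=False), scores, calib)
            for _ in range(50)
        ]
        assert planted_s > max(rand_scores)
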