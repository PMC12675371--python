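import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netsurv.cohort import Cohort
from netsurv.network import (
    ClusterNode,
    NetSurvivalConfig,
    SampledGraph,
    WalkPath,
    cluster_extreme_samples,
    consensus_markers,
    extreme_set,
    fisher_enrichment_p,
    fisher_marker_enrichment,
    path_logrank_test,
    random_walk_paths,
    run_netsurvival,
    sample_interaction_graph,
)
from netsurv.preprocess import filter_low_expression_genes
from netsurv.simulate import SimConfig, generate_cohort



class TestExtremeSet:
    def test_ceiling_count(self):
        values = pd.Series(np.arange(20.0), index=[f"s{i:02d}" for i in range(20)])
        assert len(extreme_set(values, 0.10)) == 2

    def test_absolute_value_ordering(self):
        values = pd.Series([-3.0, -0.1, 0.2, 2.5], index=list("abcd"))
        assert set(extreme_set(values, 0.5)) == {"a", "d"}

    def test_all_zero_ties_break_by_id(self):
        values = pd.Series(np.zeros(10), index=[f"s{i}" for i in range(10)])
        assert extreme_set(values, 0.3) == ["s0", "s1", "s2"]


class TestClusterExtremeSamples:
    def test_gap_cut_separates_two_groups(self):
        values = pd.Series([-2.9, -3.0, -3.1, 2.8, 3.0],
                           index=list("abcde"), name="g")
        nodes = cluster_extreme_samples(values, min_cluster_size=2)
        assert len(nodes) == 2
        assert {frozenset("abc"), frozenset("de")} == {
            frozenset(n.member_samples) for n in nodes
        }

    def test_tight_interval_single_cluster(self):
        values = pd.Series([1.0, 1.01, 1.02, 1.03], index=list("abcd"), name="g")
        nodes = cluster_extreme_samples(values)
        assert len(nodes) == 1
        assert len(nodes[0].member_samples) == 4

    def test_below_min_size_returns_empty(self):
        values = pd.Series([1.0, 2.0], index=list("ab"), name="g")
        assert cluster_extreme_samples(values, min_cluster_size=3) == []

    def test_small_clusters_discarded(self):
        values = pd.Series([0.0, 0.1, 0.2, 5.0], index=list("abcd"), name="g")
        nodes = cluster_extreme_samples(values, min_cluster_size=3)
        assert len(nodes) == 1
        assert set(nodes[0].member_samples) == {"a", "b", "c"}

    def test_max_clusters_cap(self):
        # four well-separated pairs would be 4 clusters; cap at 2
        values = pd.Series([0, 0.1, 10, 10.1, 20, 20.1, 30, 30.1],
                           index=list("abcdefgh"), name="g")
        nodes = cluster_extreme_samples(values, min_cluster_size=2, max_clusters=2)
        assert len(nodes) == 2


def _clinical(n_patients, samples_per_patient=1):
    rows = []
    for p in range(n_patients):
        for s in range(samples_per_patient):
            rows.append({"sample_id": f"p{p:02d}s{s}", "patient_id": f"p{p:02d}",
                         "time": float(p + 1), "event": 1, "timepoint": "recurrent"})
    return pd.DataFrame(rows)


class TestSampleInteractionGraph:
    def test_shared_patients_make_complete_graph(self, rng):
        clin = _clinical(6)
        nodes = {
            "g1": [ClusterNode("g1", ("p00s0", "p01s0", "p02s0"), 0.0)],
            "g2": [ClusterNode("g2", ("p02s0", "p03s0"), 0.0)],
            "g3": [ClusterNode("g3", ("p03s0", "p00s0"), 0.0)],
        }
        graph = sample_interaction_graph(nodes, clin, rng)
        adj = graph.adjacency()
        assert adj.sum() == 6  # all 3 undirected edges, both directions

    def test_disjoint_members_give_edgeless_graph(self, rng):
        clin = _clinical(6)
        nodes = {
            "g1": [ClusterNode("g1", ("p00s0", "p01s0"), 0.0)],
            "g2": [ClusterNode("g2", ("p02s0", "p03s0"), 0.0)],
        }
        graph = sample_interaction_graph(nodes, clin, rng)
        assert graph.adjacency().sum() == 0

    def test_cluster_choice_is_uniform(self):
        clin = _clinical(4)
        two = [ClusterNode("g1", ("p00s0",), 0.0), ClusterNode("g1", ("p01s0",), 1.0)]
        nodes = {"g1": two, "g2": [ClusterNode("g2", ("p02s0",), 0.0)]}
        rng = np.random.default_rng(123)
        counts = 0
        n_iter = 4000
        for _ in range(n_iter):
            g = sample_interaction_graph(nodes, clin, rng)
            counts += g.nodes[0].centroid  # 1.0 iff second cluster chosen
        # binomial(4000, 1/2) concentration: 5 sigma ~ 158
        assert abs(counts - n_iter / 2) < 5 * math.sqrt(n_iter / 4)


def _graph_from_weights(weights, genes=None):
    n = weights.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    nodes = [ClusterNode(g, (f"s{i}",), 0.0) for i, g in enumerate(genes)]
    return SampledGraph(nodes=nodes, weights=np.asarray(weights, float))


class TestRandomWalks:
    def test_forced_path_on_a_line(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        rng = np.random.default_rng(0)
        paths = random_walk_paths(_graph_from_weights(w), 50, max_len=2, rng=rng)
        from_a = [p for p in paths if p[0] == 0]
        assert from_a and all(p == (0, 1) for p in from_a)

    def test_star_center_is_always_second_from_a_leaf(self):
        n = 5  # node 0 is the hub
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        rng = np.random.default_rng(1)
        paths = random_walk_paths(_graph_from_weights(w), 200, max_len=4, rng=rng)
        for p in paths:
            if p[0] != 0:
                assert p[1] == 0

    def test_triangle_symmetry(self):
        w = np.ones((3, 3)) - np.eye(3)
        rng = np.random.default_rng(2)
        paths = random_walk_paths(_graph_from_weights(w), 3000, max_len=3, rng=rng)
        from_a = [p for p in paths if p[0] == 0]
        n_ab = sum(p == (0, 1, 2) for p in from_a)
        n_ac = sum(p == (0, 2, 1) for p in from_a)
        assert n_ab + n_ac == len(from_a)
        assert abs(n_ab - n_ac) < 5 * math.sqrt(len(from_a) / 4)

    def test_walks_are_self_avoiding_and_adjacent(self, rng):
        w = (rng.random((12, 12)) < 0.4).astype(float)
        w = np.triu(w, 1)
        w = w + w.T
        graph = _graph_from_weights(w)
        for p in random_walk_paths(graph, 300, max_len=6, rng=rng):
            assert len(set(p)) == len(p)
            for a, b in zip(p, p[1:]):
                assert w[a, b] > 0

    def test_edgeless_graph_returns_empty(self, rng):
        paths = random_walk_paths(_graph_from_weights(np.zeros((4, 4))), 10, 5, rng)
        assert paths == []


class TestPathLogrank:
    def _path(self, patients):
        return WalkPath(node_indices=(0, 1), genes=("g1", "g2"),
                        patients=frozenset(patients))

    def test_whole_cohort_pool_untestable(self):
        clin = _clinical(30)
        path = self._path(clin["patient_id"].unique())
        out = path_logrank_test(path, clin, min_group=5)
        assert not out.testable

    def test_planted_short_survival_cluster_is_significant(self, rng):
        n = 60
        time = np.r_[rng.exponential(2.0, 15), rng.exponential(30.0, n - 15)]
        clin = _clinical(n)
        clin["time"] = time
        path = self._path(clin["patient_id"].to_numpy()[:15])
        out = path_logrank_test(path, clin, alpha=0.05, min_group=10)
        assert out.testable and out.significant

    def test_type_one_error_near_alpha_under_exchangeability(self):
        rng = np.random.default_rng(9)
        n, reps, alpha = 40, 1000, 0.05
        clin = _clinical(n)
        time = rng.exponential(10.0, n)
        clin["time"] = time
        patients = clin["patient_id"].to_numpy()
        hits = 0
        for _ in range(reps):
            pool = rng.choice(patients, size=15, replace=False)
            out = path_logrank_test(self._path(pool), clin, alpha=alpha, min_group=10)
            hits += out.significant
        assert 0.03 <= hits / reps <= 0.075


class TestFisherEnrichment:
    def test_hand_computed_table(self):
        # (a,b,c,d)=(3,1,1,3): one-sided p = [C(4,3)C(4,1)+C(4,4)C(4,0)]/C(8,4) = 17/70
        assert fisher_enrichment_p(3, 1, 1, 3) == pytest.approx(17 / 70)

    def test_zero_a_with_presence_gives_p_one(self):
        assert fisher_enrichment_p(0, 4, 3, 5) == pytest.approx(1.0)

    def test_matches_scipy_and_enumeration_for_all_small_margins(self):
        """Exhaustive: all 2x2 tables with total margins <= 12."""
        for n in range(1, 13):
            for row1 in range(n + 1):
                for col1 in range(n + 1):
                    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
                    for a in range(lo, hi + 1):
                        b, c = row1 - a, col1 - a
                        d = n - row1 - col1 + a
                        table = [[a, b], [c, d]]
                        expected = stats.fisher_exact(table, alternative="greater")[1]
                        mine = fisher_enrichment_p(a, b, c, d)
                        assert mine == pytest.approx(expected, abs=1e-12), table
                        # independent enumeration of the hypergeometric tail
                        tail = sum(
                            math.comb(col1, x) * math.comb(n - col1, row1 - x)
                            for x in range(a, min(row1, col1) + 1)
                        ) / math.comb(n, row1)
                        assert mine == pytest.approx(tail, abs=1e-12), table

    def test_count_conservation_and_margins(self):
        paths = [
            WalkPath((0, 1), ("g1", "g2"), frozenset("ab"), significant=True),
            WalkPath((1, 2), ("g2", "g3"), frozenset("bc"), significant=False),
            WalkPath((0, 2), ("g1", "g3"), frozenset("ac"), significant=True),
            WalkPath((2, 0), ("g3", "g1"), frozenset("ca"), significant=False,
                     testable=False),
        ]
        table = fisher_marker_enrichment(paths, ["g1", "g2", "g3", "g4"]).set_index("gene")
        # untestable path excluded from all margins
        assert (table["a"] + table["b"]).eq(2).all()
        assert (table["c"] + table["d"]).eq(1).all()
        assert table.loc["g1", ["a", "c"]].tolist() == [2, 0]
        assert table.loc["g4", "p"] == 1.0
        assert (table["q"] >= table["p"] - 1e-12).all()


class TestConsensus:
    def _fold(self, selected_genes, all_genes=("g1", "g2", "g3")):
        return pd.DataFrame(
            {"gene": all_genes,
             "q": [0.01 if g in selected_genes else 0.5 for g in all_genes],
             "selected": [g in selected_genes for g in all_genes]}
        )

    def test_membership_rules(self):
        folds = [self._fold({"g1", "g2"}), self._fold({"g1"}), self._fold({"g1", "g2"}),
                 self._fold(set()), self._fold({"g2"})]
        out = consensus_markers(folds, min_folds=3).set_index("gene")
        assert bool(out.loc["g1", "consensus"])
        assert bool(out.loc["g2", "consensus"])
        assert not out.loc["g3", "consensus"]
        two = consensus_markers(folds[:2] + [self._fold(set())] * 3, min_folds=3)
        assert not two.set_index("gene").loc["g2", "consensus"]

    def test_min_folds_one_is_union(self):
        folds = [self._fold({"g1"}), self._fold({"g2"}), self._fold(set())]
        out = consensus_markers(folds, min_folds=1)
        assert set(out.loc[out["consensus"], "gene"]) == {"g1", "g2"}


@pytest.fixture(scope="module")
def planted_run():
    config = SimConfig(n_patients=80, n_samples=88, n_genes=60, n_prognostic=3,
                       block_size=16)
    cohort, truth = generate_cohort(config, seed=21)
    cohort = Cohort(
        expression=filter_low_expression_genes(cohort.expression),
        clinical=cohort.clinical,
    )
    net_config = NetSurvivalConfig(n_graphs=150, walks_per_graph=30, k_folds=4,
                                   min_folds=3)
    result = run_netsurvival(cohort, net_config, seed=21)
    return result, truth


class TestRunNetsurvival:
    def test_planted_markers_recovered(self, planted_run):
        result, truth = planted_run
        recovered = set(result.consensus_genes) & set(truth.prognostic)
        assert len(recovered) >= 2

    def test_structural_accounting(self, planted_run):
        result, _ = planted_run
        for table, info in zip(result.per_fold, result.fold_info):
            assert (table["a"] + table["b"]).nunique() == 1
            assert (table["a"] + table["b"]).iloc[0] == info["n_significant_paths"]
            assert (
                table["a"] + table["b"] + table["c"] + table["d"]
            ).iloc[0] == info["n_testable_paths"]

    def test_smoke_single_iteration(self):
        config = SimConfig(n_patients=70, n_samples=77, n_genes=30, n_prognostic=2,
                           block_size=14)
        cohort, _ = generate_cohort(config, seed=3)
        net_config = NetSurvivalConfig(n_graphs=1, walks_per_graph=1, k_folds=3,
                                       min_folds=2)
        result = run_netsurvival(cohort, net_config, seed=3)
        assert len(result.per_fold) == 3
        assert {"gene", "a", "b", "c", "d", "p", "q", "selected"} <= set(
            result.per_fold[0].columns
        )

    def test_reproducible_from_seed(self):
        config = SimConfig(n_patients=70, n_samples=77, n_genes=30, n_prognostic=2,
                           block_size=14)
        cohort, _ = generate_cohort(config, seed=3)
        net_config = NetSurvivalConfig(n_graphs=20, walks_per_graph=10, k_folds=3,
                                       min_folds=2)
        a = run_netsurvival(cohort, net_config, seed=4)
        b = run_netsurvival(cohort, net_config, seed=4)
        pd.testing.assert_frame_equal(a.consensus, b.consensus)
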