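from math import comb

import numpy as np
import pytest

from alsflow import (
    EventLog,
    cfm_to_dot,
    edge_percentages,
    mine_cfm,
    mine_dfg,
    node_association_test,
    node_time_comparison,
    prune_cfm,
    stratify_cfm,
)
from alsflow.errors import InsufficientDataError

from conftest import make_trace, random_toy_log
from oracles import fisher_two_sided


class TestMineCFM:
    def test_toy_tree_supports_and_times(self, toy_log):
        tree = mine_cfm(toy_log, "M_0000")
        root = tree.root
        assert root.support == 2 and tree.population_size == 3
        child = root.find(("M_0000", "M_1000"))
        assert child.support == 2
        assert child.times == [100.0, 100.0]
        assert child.min_time == child.median_time == child.max_time == 100.0
        dead = root.find(("M_0000", "M_1000", "Dead"))
        m1100 = root.find(("M_0000", "M_1000", "M_1100"))
        assert dead.support == 1 and m1100.support == 1

    def test_single_trace_chain(self):
        log = EventLog.from_traces([make_trace("p", [("M_0000", 0), ("M_1000", 10), ("Dead", 20)])])
        tree = mine_cfm(log, "M_0000")
        assert [n.support for n in tree.nodes()] == [1, 1, 1]
        assert [n.activity for n in tree.nodes()] == ["M_0000", "M_1000", "Dead"]

    def test_identical_traces_merge_into_one_chain(self):
        pairs = [("M_0000", 0), ("M_1000", 10), ("Dead", 20)]
        log = EventLog.from_traces([make_trace("p1", pairs), make_trace("p2", pairs)])
        tree = mine_cfm(log, "M_0000")
        assert [n.support for n in tree.nodes()] == [2, 2, 2]

    def test_missing_root_is_an_error(self, toy_log):
        with pytest.raises(InsufficientDataError):
            mine_cfm(toy_log, "M_1111")

    def test_first_level_matches_dfg_out_edges_on_no_revisit_log(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            # traces all start at the root and never revisit an activity
            states = ["M_0000", "M_1000", "M_1100", "M_1110", "M_1111"]
            traces = []
            for i in range(int(rng.integers(2, 8))):
                length = int(rng.integers(1, 5))
                traces.append(make_trace(
                    f"p{i}", [(states[j], 10.0 * j) for j in range(length + 1)]))
            log = EventLog.from_traces(traces)
            tree = mine_cfm(log, "M_0000")
            dfg = mine_dfg(log)
            for child in tree.root.children:
                assert child.support == dfg.edges[("M_0000", child.activity)].count

    def test_support_dominates_children_and_ids_unique(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            log = random_toy_log(rng)
            acts = sorted(log.activities())
            tree = mine_cfm(log, acts[0])
            ids = [n.node_id for n in tree.nodes()]
            assert len(ids) == len(set(ids))
            for node in tree.nodes():
                assert node.support >= sum(c.support for c in node.children)
                assert len(node.times) == node.support


class TestPruneAndPercentages:
    def test_node_below_threshold_removed(self, toy_log):
        tree = mine_cfm(toy_log, "M_0000")
        pruned = prune_cfm(tree, 2)
        assert pruned.root.find(("M_0000", "M_1000")) is not None
        assert pruned.root.find(("M_0000", "M_1000", "Dead")) is None

    def test_min_support_one_is_identity(self, toy_log):
        tree = mine_cfm(toy_log, "M_0000")
        pruned = prune_cfm(tree, 1)
        assert [n.path for n in pruned.nodes()] == [n.path for n in tree.nodes()]

    def test_chain_pruning_keeps_prefix(self):
        log = EventLog.from_traces(
            [make_trace(f"p{i}", [("M_0000", 0), ("M_1000", 10), ("Dead", 20)][:k + 1])
             for i, k in enumerate([2, 1, 1, 0, 0])]
        )
        tree = mine_cfm(log, "M_0000")  # supports 5 -> 3 -> 1
        pruned = prune_cfm(tree, 3)
        assert [n.support for n in pruned.nodes()] == [5, 3]

    def test_parent_supports_unchanged_by_pruning(self, toy_log):
        tree = prune_cfm(mine_cfm(toy_log, "M_0000"), 2)
        assert tree.root.support == 2

    def test_toy_edge_percentages(self, toy_log):
        tree = mine_cfm(toy_log, "M_0000")
        child = tree.root.find(("M_0000", "M_1000"))
        p_parent, p_pop = edge_percentages(tree)[child.node_id]
        assert p_parent == 1.0
        assert p_pop == pytest.approx(2 / 3, abs=1e-3)

    def test_children_percentages_sum_at_most_one_after_pruning(self):
        rng = np.random.default_rng(41)
        log = random_toy_log(rng, max_traces=10, max_events=6)
        acts = sorted(log.activities())
        tree = prune_cfm(mine_cfm(log, acts[0]), 2)
        pct = edge_percentages(tree)
        for node in tree.nodes():
            total = sum(pct[c.node_id][0] for c in node.children)
            assert total <= 1.0 + 1e-12


class TestAssociationTest:
    def test_identical_proportions_give_p_one(self):
        for cutoff in (5.0, float("inf")):
            out = node_association_test(5, 5, 5, 5, expected_cutoff=cutoff)
            assert out.p_value == pytest.approx(1.0)

    def test_perfect_separation_exact_p(self):
        out = node_association_test(10, 0, 0, 10, expected_cutoff=float("inf"))
        assert out.test == "fisher"
        assert out.p_value == pytest.approx(2 / comb(20, 10))

    def test_switch_rule_picks_chi2_when_expected_counts_allow(self):
        # margins 20/20 and 12/28 -> smallest expected cell is 6
        out = node_association_test(10, 10, 2, 18)
        assert out.test == "chi2"
        forced = node_association_test(10, 10, 2, 18, expected_cutoff=float("inf"))
        assert forced.test == "fisher"
        assert forced.p_value == pytest.approx(fisher_two_sided(10, 10, 2, 18), rel=1e-8)

    def test_small_counts_select_fisher(self):
        out = node_association_test(3, 1, 1, 3)
        assert out.test == "fisher"

    def test_all_zero_table_is_undefined(self):
        with pytest.raises(InsufficientDataError):
            node_association_test(0, 0, 0, 0)

    def test_fisher_agrees_with_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher

        from alsflow.cfm import fisher_exact_two_sided

        rng = np.random.default_rng(19)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_two_sided(a, b, c, d)
            reference = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(reference, rel=1e-10, abs=1e-12)


class TestNodeTimeComparison:
    def test_identical_samples(self):
        stat, p = node_time_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(4.5)  # U = n1*n2/2
        assert p == pytest.approx(1.0)

    def test_fully_separated_samples_smallest_exact_p(self):
        _, p = node_time_comparison([1.0, 2.0, 3.0], [100.0, 200.0, 300.0])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_empty_sample_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            node_time_comparison([], [1.0])


class TestStratifiedCFM:
    def duplicated_log(self):
        pairs = [("M_0000", 0), ("M_1000", 50), ("Censored", 100)]
        traces = [make_trace(f"a{i}", pairs, onset_site="Spinal") for i in range(5)]
        traces += [make_trace(f"b{i}", pairs, onset_site="Bulbar") for i in range(5)]
        return EventLog.from_traces(traces)

    def test_identical_strata_give_ratio_one_and_p_one(self):
        strat = stratify_cfm(self.duplicated_log(), "M_0000", "onset_site",
                             ["Spinal", "Bulbar"])
        for ns in strat.stats.values():
            assert ns.ratio == pytest.approx(1.0)
            assert ns.p_value == pytest.approx(1.0)
            assert not ns.significant

    def test_disjoint_pathways_get_exact_fisher_p(self):
        traces = [make_trace(f"a{i}", [("M_0000", 0), ("M_1000", 50), ("Censored", 100)],
                             group="x") for i in range(6)]
        traces += [make_trace(f"b{i}", [("M_0000", 0), ("Censored", 100)], group="y")
                   for i in range(6)]
        strat = stratify_cfm(EventLog.from_traces(traces), "M_0000", "group", ["x", "y"])
        node = strat.tree.root.find(("M_0000", "M_1000"))
        ns = strat.stats[node.node_id]
        assert ns.test == "fisher"
        assert ns.p_value == pytest.approx(fisher_two_sided(6, 0, 0, 6), rel=1e-8)
        assert ns.significant

    def test_per_stratum_supports_sum_to_combined(self):
        strat = stratify_cfm(self.duplicated_log(), "M_0000", "onset_site",
                             ["Spinal", "Bulbar"])
        for node in strat.tree.nodes():
            ns = strat.stats[node.node_id]
            assert ns.support_a + ns.support_b == node.support

    def test_degenerate_stratum_skips_tests(self):
        traces = [make_trace(f"a{i}", [("M_0000", 0), ("Censored", 10)], group="x")
                  for i in range(3)]
        traces += [make_trace("b0", [("M_1000", 0), ("Censored", 10)], group="y")]
        with pytest.warns(UserWarning, match="node tests skipped"):
            strat = stratify_cfm(EventLog.from_traces(traces), "M_0000", "group", ["x", "y"])
        assert all(ns.p_value is None for ns in strat.stats.values())


class TestDot:
    def test_median_bins_color_nodes(self, toy_log):
        dot = cfm_to_dot(mine_cfm(toy_log, "M_0000"))
        # node at median 100 days falls in the first bin, 200-day nodes in the second
        assert "#deebf7" in dot and "#9ecae1" in dot

    def test_significant_node_is_yellow(self):
        traces = [make_trace(f"a{i}", [("M_0000", 0), ("M_1000", 50), ("Censored", 100)],
                             group="x") for i in range(6)]
        traces += [make_trace(f"b{i}", [("M_0000", 0), ("Censored", 100)], group="y")
                   for i in range(6)]
        strat = stratify_cfm(EventLog.from_traces(traces), "M_0000", "group", ["x", "y"])
        assert "fillcolor=\"yellow\"" in cfm_to_dot(strat)

    def test_leaf_only_tree_renders_single_node(self):
        log = EventLog.from_traces([make_trace("p", [("M_0000", 0)])])
        dot = cfm_to_dot(mine_cfm(log, "M_0000"))
        assert dot.count("label=") == 1 and "->" not in dot

    def test_dot_is_byte_deterministic(self, toy_log):
        a = cfm_to_dot(mine_cfm(toy_log, "M_0000"))
        b = cfm_to_dot(mine_cfm(toy_log, "M_0000"))
        assert a == b
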