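"""Locality statistic, scan maximum, permutation null, secondary clusters."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import chi2_contingency

from pathscan import (
    Cohort,
    PathwayGraph,
    Window,
    dedupe_windows,
    enumerate_windows,
    locality_statistic,
    permutation_test,
    scan,
    secondary_clusters,
    truncated_distances,
)

from conftest import random_pathway_graph


def random_cohort(genes, n_cases, n_controls, p_affect, rng):
    ids, phenos, affected = [], [], []
    genes = np.array(genes)
    for k, (n, ph) in enumerate(((n_cases, "case"), (n_controls, "control"))):
        for i in range(n):
            ids.append(f"{ph}{i}")
            phenos.append(ph)
            affected.append(frozenset(genes[rng.random(len(genes)) < p_affect]))
    return Cohort(ids, phenos, affected)


class TestLocalityStatistic:
    def test_equal_proportions_zero(self):
        assert locality_statistic(3, 3, 10, 10) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        expected = 0.3 / math.sqrt(0.25 * 0.75 * 0.2)
        assert locality_statistic(4, 1, 10, 10) == pytest.approx(expected)

    @pytest.mark.parametrize("sx,sy,n1,n0", [
        (4, 1, 10, 10), (1, 5, 12, 9), (7, 2, 20, 15), (3, 3, 8, 14),
    ])
    def test_squared_equals_pooled_chi2(self, sx, sy, n1, n0):
        T = locality_statistic(sx, sy, n1, n0)
        table = [[sx, sy], [n1 - sx, n0 - sy]]
        chi2 = chi2_contingency(table, correction=False).statistic
        assert T * T == pytest.approx(chi2, abs=1e-10)

    def test_sign_matches_proportion_difference(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n1, n0 = rng.integers(5, 40, 2)
            sx = int(rng.integers(1, n1 + 1))
            sy = int(rng.integers(0, n0 + 1))
            if sx + sy == n1 + n0:
                continue
            T = locality_statistic(sx, sy, int(n1), int(n0))
            assert np.sign(T) == np.sign(sx / n1 - sy / n0)

    def test_undefined_cases_raise(self):
        with pytest.raises(ValueError):
            locality_statistic(0, 1, 10, 10)  # sum_x < 1
        with pytest.raises(ValueError):
            locality_statistic(1, 0, 0, 10)  # n1 = 0
        with pytest.raises(ValueError):
            locality_statistic(10, 10, 10, 10)  # pooled proportion = 1


def brute_force_scan_max(cohort, graph, R):
    """Independent oracle: enumerate all (R+1)N windows with networkx and take
    the max pooled-z over member sets with case count > 0."""
    n1, n0 = cohort.n1, cohort.n0
    case = list(cohort.case_mask)
    best = None
    for center in graph.genes:
        reach = nx.single_source_shortest_path_length(
            graph.to_networkx(), center, cutoff=R)
        for r in range(R + 1):
            members = {g for g, d in reach.items() if d <= r}
            sx = sum(len(s & members) for s, c in zip(cohort.affected, case) if c)
            sy = sum(len(s & members) for s, c in zip(cohort.affected, case) if not c)
            if sx < 1 or n1 == 0 or n0 == 0:
                continue
            pooled = (sx + sy) / (n1 + n0)
            if not 0 < pooled < 1:
                continue
            T = (sx / n1 - sy / n0) / math.sqrt(
                pooled * (1 - pooled) * (1 / n1 + 1 / n0))
            if best is None or T > best:
                best = T
    return best


class TestScan:
    def test_single_window_is_most_likely(self):
        w = Window("A", 0, frozenset({"A"}))
        cohort = Cohort(["c1", "k1"], ["case", "control"],
                        [frozenset({"A"}), frozenset({"B"})])
        res = scan(cohort, [w])
        assert res.most_likely.window == w
        assert res.scan_T == pytest.approx(res.most_likely.T)

    def test_case_only_cluster_window_wins(self):
        g = PathwayGraph(edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        d = truncated_distances(g, 2)
        windows = dedupe_windows(enumerate_windows(g, d, 2))
        cohort = Cohort(
            [f"c{i}" for i in range(4)] + [f"k{i}" for i in range(4)],
            ["case"] * 4 + ["control"] * 4,
            [frozenset({"A", "B"})] * 4 + [frozenset({"E"})] * 4)
        res = scan(cohort, windows)
        assert {"A", "B"} <= res.most_likely.window.members
        assert "E" not in res.most_likely.window.members

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_pathway_graph(int(rng.integers(8, 25)), 0.15, seed=seed)
        cohort = random_cohort(g.genes, 6, 6, 0.15, rng)
        d = truncated_distances(g, 3)
        windows = enumerate_windows(g, d, 3)
        res = scan(cohort, windows)
        oracle = brute_force_scan_max(cohort, g, 3)
        if oracle is None:
            assert res.scan_T is None
        else:
            assert res.scan_T == pytest.approx(oracle, abs=1e-10)
            # dedup cannot change the maximum
            res_dedup = scan(cohort, dedupe_windows(windows))
            assert res_dedup.scan_T == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_subject_reordering(self, rng):
        g = random_pathway_graph(15, 0.2, seed=1)
        cohort = random_cohort(g.genes, 5, 5, 0.2, rng)
        d = truncated_distances(g, 2)
        windows = dedupe_windows(enumerate_windows(g, d, 2))
        res = scan(cohort, windows)
        order = rng.permutation(cohort.n_subjects)
        shuffled = Cohort([cohort.subject_ids[i] for i in order],
                          [cohort.phenotypes[i] for i in order],
                          [cohort.affected[i] for i in order])
        assert scan(shuffled, windows).scan_T == pytest.approx(res.scan_T)

    def test_tie_break_prefers_smaller_window_then_center(self):
        # Two disjoint singleton case-hits produce identical T; window list
        # also contains a larger superset window with the same counts.
        wa = Window("A", 0, frozenset({"A"}))
        wb = Window("B", 0, frozenset({"B"}))
        wbig = Window("B", 1, frozenset({"B", "Q"}))
        cohort = Cohort(["c", "k"], ["case", "control"],
                        [frozenset({"A", "B"}), frozenset({"Z"})])
        res = scan(cohort, [wbig, wb, wa])
        assert res.most_likely.window == wa

    def test_no_case_signal_gives_p_one(self):
        w = Window("A", 0, frozenset({"A"}))
        cohort = Cohort(["c", "k"], ["case", "control"],
                        [frozenset(), frozenset({"A"})])
        res = scan(cohort, [w])
        assert res.scan_T is None and res.p_value == 1.0

    def test_adding_case_gene_in_most_likely_window_never_lowers_scan(self):
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 40:
            g = random_pathway_graph(int(rng.integers(6, 14)), 0.25,
                                     seed=int(rng.integers(10_000)))
            cohort = random_cohort(g.genes, 4, 4, 0.3, rng)
            d = truncated_distances(g, 2)
            windows = dedupe_windows(enumerate_windows(g, d, 2))
            res = scan(cohort, windows)
            if res.scan_T is None:
                continue
            ml = res.most_likely.window.members
            case_idx = [i for i, c in enumerate(cohort.case_mask) if c]
            i = int(rng.choice(case_idx))
            candidates = sorted(ml - cohort.affected[i])
            if not candidates:
                continue
            new = list(cohort.affected)
            new[i] = cohort.affected[i] | {candidates[0]}
            res2 = scan(Cohort(cohort.subject_ids, cohort.phenotypes, new),
                        windows)
            assert res2.scan_T >= res.scan_T - 1e-12
            checked += 1


class TestPermutationTest:
    def test_p_value_formula_and_determinism(self, rng):
        g = random_pathway_graph(20, 0.15, seed=2)
        cohort = random_cohort(g.genes, 8, 8, 0.15, rng)
        d = truncated_distances(g, 2)
        windows = dedupe_windows(enumerate_windows(g, d, 2))
        r1 = permutation_test(cohort, windows, B=99, seed=5)
        r2 = permutation_test(cohort, windows, B=99, seed=5)
        assert np.array_equal(r1.null_T, r2.null_T)
        assert r1.p_value == r2.p_value
        expected = (1 + np.sum(r1.null_T >= r1.scan_T)) / 100
        assert r1.p_value == pytest.approx(expected)
        assert 0 < r1.p_value <= 1

    def test_extreme_observed_attains_minimum_p(self):
        # every affected gene sits in cases inside one tight window: the
        # observed scan maximum should beat (almost) all permuted maxima
        g = PathwayGraph(edges=[("A", "B"), ("C", "D"), ("D", "E")])
        d = truncated_distances(g, 2)
        windows = dedupe_windows(enumerate_windows(g, d, 2))
        cohort = Cohort(
            [f"c{i}" for i in range(10)] + [f"k{i}" for i in range(10)],
            ["case"] * 10 + ["control"] * 10,
            [frozenset({"A", "B"})] * 10 + [frozenset({"E"})] * 10)
        res = permutation_test(cohort, windows, B=199, seed=3)
        assert res.p_value <= 0.05


class TestSecondaryClusters:
    def _two_cluster_setup(self):
        # two disconnected 4-gene communities carrying case-only signal, plus
        # a 12-gene background path carrying the controls' affected genes
        g = nx.disjoint_union_all(
            [nx.complete_graph(4), nx.complete_graph(4), nx.path_graph(12)])
        graph = PathwayGraph.from_networkx(
            nx.relabel_nodes(g, {i: f"G{i:02d}" for i in g.nodes()}))
        left = frozenset({"G00", "G01", "G02", "G03"})
        right = frozenset({"G04", "G05", "G06", "G07"})
        background = [f"G{i:02d}" for i in range(8, 20)]
        affected_cases = [frozenset(left)] * 6 + [frozenset(right)] * 6
        affected_ctrls = [
            frozenset(background[i % 12] for i in (j, j + 3, j + 6))
            for j in range(12)]
        cohort = Cohort(
            [f"c{i}" for i in range(12)] + [f"k{i}" for i in range(12)],
            ["case"] * 12 + ["control"] * 12,
            affected_cases + affected_ctrls)
        d = truncated_distances(graph, 2)
        windows = dedupe_windows(enumerate_windows(graph, d, 2))
        return cohort, windows, left, right

    def test_two_planted_clusters_recovered(self):
        cohort, windows, left, right = self._two_cluster_setup()
        res = permutation_test(cohort, windows, B=999, seed=8)
        sec = secondary_clusters(res, alpha=0.05)
        assert res.p_value < 0.05
        detected = {res.most_likely.window.members} | {lr.window.members
                                                       for lr, _ in sec}
        assert left in detected and right in detected

    def test_secondary_windows_disjoint_from_most_likely(self):
        cohort, windows, *_ = self._two_cluster_setup()
        res = permutation_test(cohort, windows, B=999, seed=8)
        sec = secondary_clusters(res, alpha=0.05)
        ml = res.most_likely.window.members
        kept = [ml] + [lr.window.members for lr, _ in sec]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert a.isdisjoint(b)

    def test_not_significant_gives_empty_list(self, rng):
        g = random_pathway_graph(15, 0.2, seed=9)
        cohort = random_cohort(g.genes, 5, 5, 0.2, rng)
        d = truncated_distances(g, 2)
        windows = dedupe_windows(enumerate_windows(g, d, 2))
        res = permutation_test(cohort, windows, B=99, seed=10)
        if res.p_value >= 0.05:  # overwhelmingly likely for null data
            assert secondary_clusters(res, alpha=0.05) == []

    def test_requires_permutation_first(self):
        w = Window("A", 0, frozenset({"A"}))
        cohort = Cohort(["c", "k"], ["case", "control"],
                        [frozenset({"A"}), frozenset()])
        res = scan(cohort, [w])
        with pytest.raises(ValueError, match="permutation"):
            secondary_clusters(res)
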