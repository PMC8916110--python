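"""Network-based statistic: edge models, components, permutation inference."""

import numpy as np
import pytest
from scipy import stats

from fcaging.connectome import ConnectomeStack
from fcaging.nbs import (
    T_SENTINEL,
    EdgeStats,
    NBSConfig,
    component_edge_mask,
    edge_statistics,
    nbs_test,
    node_degree_table,
    suprathreshold_components,
)


def _stats_from_tmap(tvals: dict[tuple[int, int], float], n: int) -> EdgeStats:
    iu, ju = np.triu_indices(n, 1)
    t = np.zeros(iu.size)
    for k, (i, j) in enumerate(zip(iu, ju)):
        t[k] = tvals.get((int(i), int(j)), 0.0)
    return EdgeStats(t=t, i=iu, j=ju, n=20, df=18)


def _dfs_components(edges: list[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Brute-force oracle: connected components by explicit depth-first search."""
    adj: dict[int, set[int]] = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen: set[int] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        nodes, stack_ = set(), [start]
        while stack_:
            u = stack_.pop()
            if u in nodes:
                continue
            nodes.add(u)
            stack_.extend(adj[u] - nodes)
        seen |= nodes
        comps.append({(min(i, j), max(i, j)) for i, j in edges if i in nodes})
    return comps


class TestEdgeStatistics:
    def test_null_t_distribution(self, rng):
        n, n_rois = 60, 15
        data = rng.normal(0.4, 0.1, size=(n, n_rois, n_rois))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        data[:, np.arange(n_rois), np.arange(n_rois)] = 0
        x = rng.normal(60, 8, n)
        st_ = edge_statistics(data, x)
        assert st_.df == n - 2
        assert stats.kstest(st_.t, stats.t(st_.df).cdf).pvalue > 0.01

    def test_perfect_fit_edge_capped(self, rng):
        n, n_rois = 20, 4
        data = rng.normal(0.4, 0.05, size=(n, n_rois, n_rois))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        x = np.linspace(40, 70, n)
        data[:, 0, 1] = data[:, 1, 0] = 0.01 * x  # exact linear edge
        st_ = edge_statistics(data, x)
        assert st_.t[0] == T_SENTINEL

    def test_constant_edge_excluded(self, rng):
        n, n_rois = 20, 4
        data = rng.normal(0.4, 0.05, size=(n, n_rois, n_rois))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        data[:, 0, 1] = data[:, 1, 0] = 0.5
        st_ = edge_statistics(data, np.linspace(40, 70, n))
        assert 0 in st_.excluded
        assert np.isnan(st_.t[0])

    def test_joint_relabeling_invariance(self, rng):
        n, n_rois = 30, 6
        data = rng.normal(0.4, 0.1, size=(n, n_rois, n_rois))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        x = rng.normal(60, 8, n)
        perm = rng.permutation(n)
        t1 = edge_statistics(data, x).t
        t2 = edge_statistics(data[perm], x[perm]).t
        assert np.allclose(t1, t2, atol=1e-10)

    def test_constant_predictor_rejected(self, rng):
        data = rng.random((10, 4, 4))
        data = (data + np.transpose(data, (0, 2, 1))) / 2
        with pytest.raises(ValueError, match="constant"):
            edge_statistics(data, np.ones(10))


class TestComponents:
    def test_empty_when_nothing_suprathreshold(self):
        st_ = _stats_from_tmap({}, 6)
        assert suprathreshold_components(st_, 3.2, "positive") == []

    def test_two_disjoint_triangles(self):
        tv = {e: 5.0 for e in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]}
        comps = suprathreshold_components(_stats_from_tmap(tv, 6), 3.2, "positive")
        assert [c.size for c in comps] == [3, 3]
        assert {frozenset(c.nodes) for c in comps} == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_path_degrees(self):
        tv = {(0, 1): -4.0, (1, 2): -4.0}
        comps = suprathreshold_components(_stats_from_tmap(tv, 4), 3.2, "negative")
        assert len(comps) == 1
        assert comps[0].size == 2
        assert comps[0].degrees == {0: 1, 1: 2, 2: 1}

    def test_direction_separates_signs(self):
        tv = {(0, 1): 5.0, (2, 3): -5.0}
        st_ = _stats_from_tmap(tv, 4)
        pos = suprathreshold_components(st_, 3.2, "positive")
        neg = suprathreshold_components(st_, 3.2, "negative")
        assert [(c.size, set(c.nodes)) for c in pos] == [(1, {0, 1})]
        assert [(c.size, set(c.nodes)) for c in neg] == [(1, {2, 3})]

    def test_agrees_with_dfs_oracle_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            iu, ju = np.triu_indices(n, 1)
            present = rng.random(iu.size) < 0.15
            edges = [(int(i), int(j)) for i, j in zip(iu[present], ju[present])]
            tv = {e: 5.0 for e in edges}
            comps = suprathreshold_components(_stats_from_tmap(tv, n), 3.2, "positive")
            oracle = _dfs_components(edges)
            got = [{(i, j) for i, j, _ in c.edges} for c in comps]
            assert sorted(map(sorted, got)) == sorted(map(sorted, oracle))

    def test_threshold_monotonicity(self, rng):
        iu, ju = np.triu_indices(12, 1)
        tv = {
            (int(i), int(j)): float(v)
            for i, j, v in zip(iu, ju, rng.normal(0, 3, iu.size))
        }
        st_ = _stats_from_tmap(tv, 12)
        sizes = []
        for thr in (1.0, 2.0, 3.0, 4.0):
            comps = suprathreshold_components(st_, thr, "positive")
            sizes.append(max((c.size for c in comps), default=0))
        assert sizes == sorted(sizes, reverse=True)


class TestNbsTest:
    def test_planted_component_detected(self, small_cohort, small_stack):
        stack, truth = small_stack
        comps = nbs_test(
            stack,
            small_cohort["age"].to_numpy(float),
            NBSConfig(n_permutations=300, seed=0),
        )
        assert comps, "no components found despite a planted effect"
        best = comps[0]
        assert best.fwe_p < 0.05
        found = {(i, j) for i, j, _ in best.edges}
        truth_edges = set(truth.planted_edges)
        jacc = len(found & truth_edges) / len(found | truth_edges)
        assert jacc >= 0.8

    def test_observed_larger_than_all_nulls_gives_zero_p(self, small_cohort, small_stack):
        stack, _ = small_stack
        comps = nbs_test(
            stack,
            small_cohort["age"].to_numpy(float),
            NBSConfig(n_permutations=50, seed=1),
        )
        assert comps[0].fwe_p == 0.0
        assert (comps[0].null_max_sizes < comps[0].size).all()

    def test_add_one_correction_variant(self, small_cohort, small_stack):
        stack, _ = small_stack
        comps = nbs_test(
            stack,
            small_cohort["age"].to_numpy(float),
            NBSConfig(n_permutations=50, seed=1, add_one_correction=True),
        )
        assert comps[0].fwe_p == pytest.approx(1 / 51)

    def test_deterministic_given_seed(self, small_cohort, small_stack):
        stack, _ = small_stack
        age = small_cohort["age"].to_numpy(float)
        cfg = NBSConfig(n_permutations=100, seed=7)
        c1 = nbs_test(stack, age, cfg)
        c2 = nbs_test(stack, age, cfg)
        assert np.array_equal(c1[0].null_max_sizes, c2[0].null_max_sizes)
        assert c1[0].fwe_p == c2[0].fwe_p

    def test_covariate_adjusted_mode_runs(self, small_cohort, small_stack):
        stack, _ = small_stack
        covs = small_cohort[["sex", "education"]].to_numpy(float)
        comps = nbs_test(
            stack,
            small_cohort["age"].to_numpy(float),
            NBSConfig(n_permutations=50, seed=2, include_covariates=True),
            covariates=covs,
        )
        assert comps and comps[0].fwe_p < 0.05

    def test_invalid_permutation_count(self, small_cohort, small_stack):
        with pytest.raises(ValueError, match="n_permutations"):
            NBSConfig(n_permutations=0)


class TestComponentUtilities:
    def test_star_graph_degrees(self):
        tv = {(0, k): 4.0 for k in range(1, 5)}
        comps = suprathreshold_components(_stats_from_tmap(tv, 5), 3.2, "positive")
        table = node_degree_table(comps[0])
        assert table.iloc[0].tolist() == [0, 4]
        assert (table["degree"].iloc[1:] == 1).all()

    def test_edge_mask_round_trip(self):
        tv = {(0, 1): 4.0, (1, 2): 4.0, (0, 2): 4.0}
        comps = suprathreshold_components(_stats_from_tmap(tv, 3), 3.2, "positive")
        assert set(component_edge_mask(comps[0])) == {(0, 1), (1, 2), (0, 2)}

    def test_subnetwork_fc_via_mask(self, small_stack):
        stack, truth = small_stack
        from fcaging.connectome import subnetwork_fc

        mi = [e for e in truth.planted_edges][:3]
        vals = subnetwork_fc(stack, mi)
        manual = np.mean(
            [stack.data[:, i, j] for i, j in mi], axis=0
        )
        assert np.allclose(vals, manual)
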