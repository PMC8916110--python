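"""Connectivity-matrix construction, thresholding and summary statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcaging.connectome import (
    ConnectivityMatrix,
    ConnectomeStack,
    Parcellation,
    correlation_matrix,
    group_difference_map,
    mean_connectivity,
    network_means,
    proportional_threshold,
    psmd,
    subnetwork_fc,
    tmt_ratio,
)


def _hand_pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac * bc).sum() / np.sqrt((ac**2).sum() * (bc**2).sum()))


class TestCorrelationMatrix:
    def test_identical_series_give_unit_correlation(self):
        ts = np.vstack([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        m = correlation_matrix(ts)
        assert m.weights[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_sign_handling(self):
        ts = np.vstack([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert correlation_matrix(ts, "absolute").weights[0, 1] == pytest.approx(1.0)
        assert correlation_matrix(ts, "signed").weights[0, 1] == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        ts = np.array(
            [
                [0.2, 1.4, -0.3, 0.9, 2.1],
                [1.1, 0.3, 0.8, -0.5, 0.4],
                [-0.7, 0.6, 1.9, 0.1, -1.2],
            ]
        )
        m = correlation_matrix(ts, "signed")
        for i in range(3):
            for j in range(i + 1, 3):
                assert m.weights[i, j] == pytest.approx(
                    _hand_pearson(ts[i], ts[j]), abs=1e-12
                )

    def test_constant_series_error_names_roi(self):
        ts = np.vstack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            correlation_matrix(ts)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            correlation_matrix(np.ones((4, 2)))

    @given(st.integers(0, 10_000))
    def test_symmetry_zero_diagonal_and_range(self, seed):
        g = np.random.default_rng(seed)
        ts = g.standard_normal((6, 20))
        m = correlation_matrix(ts)
        assert np.array_equal(m.weights, m.weights.T)
        assert np.all(np.diag(m.weights) == 0)
        assert m.weights.min() >= 0 and m.weights.max() <= 1


class TestProportionalThreshold:
    def _toy(self):
        w = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        return ConnectivityMatrix(w)

    def test_full_proportion_is_identity(self):
        m = self._toy()
        out = proportional_threshold(m, 1.0)
        assert np.array_equal(out.weights, m.weights)

    def test_half_proportion_keeps_three_strongest(self):
        out = proportional_threshold(self._toy(), 0.5)
        iu, ju = np.triu_indices(4, 1)
        kept = sorted(out.weights[iu, ju][out.weights[iu, ju] != 0])
        assert kept == pytest.approx([0.7, 0.8, 0.9])

    def test_tie_break_retains_exact_count(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        out = proportional_threshold(ConnectivityMatrix(w), 0.5)
        iu, ju = np.triu_indices(4, 1)
        assert int((out.weights[iu, ju] != 0).sum()) == 3
        # deterministic tie-break: lowest (i, j) pairs first
        assert out.weights[0, 1] != 0 and out.weights[0, 2] != 0 and out.weights[0, 3] != 0

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_proportion(self, bad):
        with pytest.raises(ValueError):
            proportional_threshold(self._toy(), bad)

    def test_signed_mode_ranks_by_magnitude(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.9
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.1
        out = proportional_threshold(ConnectivityMatrix(w, mode="signed"), 1 / 3)
        assert out.weights[0, 1] == -0.9 and out.weights[0, 2] == 0

    @given(st.integers(0, 10_000))
    def test_retained_count_and_nesting(self, seed):
        g = np.random.default_rng(seed)
        n = 9
        w = g.random((n, n))
        w = np.triu(w, 1)
        w = w + w.T
        m = ConnectivityMatrix(w)
        e = n * (n - 1) // 2
        iu, ju = np.triu_indices(n, 1)
        prev: set | None = None
        for p in (0.7, 0.5, 0.3, 0.1):
            out = proportional_threshold(m, p)
            kept = {(i, j) for i, j in zip(iu, ju) if out.weights[i, j] != 0}
            assert len(kept) == int(np.floor(p * e + 0.5))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestMeanConnectivity:
    def test_constant_edges(self):
        w = np.full((4, 4), 0.6)
        np.fill_diagonal(w, 0.0)
        assert mean_connectivity(ConnectivityMatrix(w)) == pytest.approx(0.6)

    def test_excluded_edges_leave_denominator(self):
        w = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7}.items():
            w[i, j] = w[j, i] = v
        m = ConnectivityMatrix(w, retained_proportion=0.5)
        assert mean_connectivity(m) == pytest.approx(0.8)

    def test_edge_mask_restriction(self):
        w = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 0.9, (2, 3): 0.1}.items():
            w[i, j] = w[j, i] = v
        m = ConnectivityMatrix(w)
        assert mean_connectivity(m, edge_mask=[(2, 3)]) == pytest.approx(0.1)

    def test_empty_retained_set_errors(self):
        w = np.zeros((3, 3))
        m = ConnectivityMatrix(w, retained_proportion=0.5)
        with pytest.raises(ValueError, match="retained"):
            mean_connectivity(m)


class TestNetworkMeans:
    def _block_parc(self):
        return Parcellation(
            roi_names=tuple(f"r{i}" for i in range(4)),
            networks=("A", "A", "B", "B"),
        )

    def test_two_network_block_toy(self):
        w = np.full((4, 4), 0.2)
        w[0, 1] = w[1, 0] = 0.6
        w[2, 3] = w[3, 2] = 0.6
        np.fill_diagonal(w, 0.0)
        s = network_means(ConnectivityMatrix(w), self._block_parc())
        assert s.within_mean == pytest.approx(0.6)
        assert s.between_mean == pytest.approx(0.2)
        assert s.per_network_mean["A"] == pytest.approx(0.6)

    def test_constant_matrix_equalizes_all_fields(self):
        w = np.full((4, 4), 0.4)
        np.fill_diagonal(w, 0.0)
        s = network_means(ConnectivityMatrix(w), self._block_parc())
        for v in (s.within_mean, s.between_mean, s.global_mean):
            assert v == pytest.approx(0.4)

    def test_single_roi_network_flagged_undefined(self):
        parc = Parcellation(("r0", "r1", "r2"), ("A", "A", "B"))
        w = np.full((3, 3), 0.3)
        np.fill_diagonal(w, 0.0)
        s = network_means(ConnectivityMatrix(w), parc)
        assert "B" in s.undefined_networks
        assert np.isnan(s.per_network_mean["B"])
        assert s.global_mean == pytest.approx(0.3)


class TestGroupDifference:
    def _stack(self, mats):
        return ConnectomeStack(
            np.array(mats), tuple(f"s{i}" for i in range(len(mats)))
        )

    def test_identical_groups_zero_map(self):
        m = np.full((3, 3), 0.4)
        np.fill_diagonal(m, 0.0)
        stack = self._stack([m, m])
        assert np.allclose(group_difference_map(stack, ["young", "old"]), 0.0)

    def test_planted_delta_recovered(self):
        m = np.full((3, 3), 0.4)
        np.fill_diagonal(m, 0.0)
        m2 = m.copy()
        m2[0, 1] = m2[1, 0] = 0.4 + 0.25
        diff = group_difference_map(self._stack([m, m2]), ["young", "old"])
        assert diff[0, 1] == pytest.approx(-0.25)

    def test_empty_group_errors(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError, match="non-empty"):
            group_difference_map(self._stack([m]), ["young"])


class TestPsmd:
    def test_constant_vector(self):
        assert psmd(np.full(10, 3e-4)) == pytest.approx(0.0)

    def test_uniform_grid(self):
        vals = np.arange(101) * 1e-5  # 0.000 .. 0.001
        assert psmd(vals) == pytest.approx(0.0009)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            psmd(np.array([1e-4, np.nan, 3e-4]))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            psmd(np.array([1e-4]))

    @given(st.integers(0, 10_000))
    def test_translation_and_scale_equivariance(self, seed):
        g = np.random.default_rng(seed)
        x = g.random(50)
        base = psmd(x)
        assert psmd(x + 7.5) == pytest.approx(base, abs=1e-12)
        assert psmd(3.0 * x) == pytest.approx(3.0 * base, rel=1e-10)


class TestTmtRatio:
    def test_cohort_median_ratio(self):
        assert tmt_ratio(79.0, 36.0) == pytest.approx(79 / 36)

    def test_equal_times(self):
        assert tmt_ratio(40.0, 40.0) == pytest.approx(1.0)

    def test_nonpositive_input(self):
        with pytest.raises(ValueError):
            tmt_ratio(50.0, 0.0)


def test_subnetwork_fc_constant_stack():
    w = np.full((4, 4), 0.5)
    np.fill_diagonal(w, 0.0)
    stack = ConnectomeStack(np.stack([w, w, w]), ("a", "b", "c"))
    fc = subnetwork_fc(stack, [(0, 1), (1, 2), (0, 2)])
    assert np.allclose(fc, 0.5)
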