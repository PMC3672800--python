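"""Structure learning with FDR control and DBN strength estimation."""

import numpy as np
import pytest
from scipy import stats

from rigidnet import simulate
from rigidnet.network import (
    DirectedNetwork,
    Edge,
    InsufficientDataError,
    ci_test,
    dbn_strengths,
    edge_universe_size,
    lagged_design,
    pcfdr_learn,
)
from rigidnet.simulate import NetworkSimSpec


class TestLaggedDesign:
    def test_single_run_row_count(self):
        x = np.random.default_rng(0).normal(size=(100, 3))
        past, present = lagged_design(x)
        assert past.shape == (99, 3) and present.shape == (99, 3)
        assert np.array_equal(past, x[:-1]) and np.array_equal(present, x[1:])

    def test_run_boundary_excluded(self):
        rng = np.random.default_rng(1)
        runs = [rng.normal(size=(50, 2)), rng.normal(size=(50, 2))]
        past, _ = lagged_design(runs)
        assert past.shape[0] == 98  # 2 x 49, never 99

    def test_run_order_does_not_change_row_multiset(self):
        rng = np.random.default_rng(2)
        runs = [rng.normal(size=(30, 2)), rng.normal(size=(40, 2))]
        p1, q1 = lagged_design(runs)
        p2, q2 = lagged_design(runs[::-1])
        rows1 = {tuple(np.r_[a, b]) for a, b in zip(p1, q1)}
        rows2 = {tuple(np.r_[a, b]) for a, b in zip(p2, q2)}
        assert rows1 == rows2

    def test_short_run_rejected(self):
        with pytest.raises(InsufficientDataError):
            lagged_design(np.zeros((2, 2)))


class TestCITest:
    def test_strong_parent_detected(self):
        W = np.zeros((2, 2))
        W[1, 0] = 0.8
        x = simulate.simulate_roi_timeseries(
            NetworkSimSpec(n_rois=2, coeff_matrix=W, n_timepoints=500, seed=0)
        )
        p = ci_test(x[:-1, 0], x[1:, 1])
        assert p < 1e-6

    def test_null_p_values_uniform(self):
        """Independent series: the p-value distribution is uniform on [0, 1]."""
        rng = np.random.default_rng(3)
        pvals = [
            ci_test(rng.normal(size=200), rng.normal(size=200)) for _ in range(800)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_chain_blocked_by_conditioning(self):
        """i -> k -> j: conditioning on k removes the i-j dependence."""
        W = np.zeros((3, 3))
        W[1, 0] = 0.7  # i -> k
        W[2, 1] = 0.7  # k -> j
        hits = 0
        reps = 40
        for seed in range(reps):
            x = simulate.simulate_roi_timeseries(
                NetworkSimSpec(n_rois=3, coeff_matrix=W, n_timepoints=2000, seed=seed)
            )
            p = ci_test(x[:-1, 0], x[1:, 2], x[:-1, 1][:, None])
            hits += p > 0.05
        assert hits >= 0.9 * reps

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            ci_test(np.zeros(4), np.zeros(4), np.zeros((4, 2)))


class TestPCfdr:
    def test_single_roi_empty_network(self):
        x = np.random.default_rng(4).normal(size=(100, 1))
        net = pcfdr_learn(x)
        assert net.edges == ()

    def test_single_edge_recovered(self):
        """3 ROIs with one true connection: the learner returns exactly it in
        nearly all replicates."""
        W = np.zeros((3, 3))
        W[1, 0] = 0.8
        exact = 0
        reps = 40
        for rep in range(reps):
            runs = [
                simulate.simulate_roi_timeseries(
                    NetworkSimSpec(
                        n_rois=3, coeff_matrix=W, n_timepoints=250, seed=rep * 100 + s
                    )
                )
                for s in range(20)
            ]
            net = pcfdr_learn(runs, q=0.05)
            found = {(e.source, e.target) for e in net.edges}
            exact += found == {("roi000", "roi001")}
        assert exact >= 0.9 * reps

    def test_oracle_equivalence_at_large_samples(self):
        """With generous conditioning, n -> large and a stringent FDR level,
        the learned edge set equals the support of the coefficient matrix.

        The stringent level matters: at q the procedure deliberately admits
        about a fraction q of false discoveries, so exact support recovery is
        only expected as q becomes small while power saturates.
        """
        exact = 0
        reps = 40
        for rep in range(reps):
            W = simulate.sparse_var_matrix(5, 0.2, 0.5, seed=rep)
            truth = {
                (f"roi{i:03d}", f"roi{j:03d}")
                for i in range(5)
                for j in range(5)
                if i != j and W[j, i] != 0
            }
            x = simulate.simulate_roi_timeseries(
                NetworkSimSpec(n_rois=5, coeff_matrix=W, n_timepoints=10000, seed=rep)
            )
            net = pcfdr_learn(x, q=0.01, max_cond_size=3)
            found = {(e.source, e.target) for e in net.edges}
            exact += found == truth
        assert exact >= 0.95 * reps

    def test_power_increases_with_coefficient_and_samples(self):
        """Detection rate of a single edge is non-decreasing in effect size
        and in timepoint count."""
        def detection_rate(coeff, T, reps=25):
            W = np.zeros((3, 3))
            W[1, 0] = coeff
            hits = 0
            for rep in range(reps):
                x = simulate.simulate_roi_timeseries(
                    NetworkSimSpec(n_rois=3, coeff_matrix=W, n_timepoints=T, seed=rep)
                )
                net = pcfdr_learn(x, q=0.05)
                hits += ("roi000", "roi001") in {(e.source, e.target) for e in net.edges}
            return hits / reps

        weak_small = detection_rate(0.08, 60)
        weak_large = detection_rate(0.08, 2000)
        strong_small = detection_rate(0.5, 60)
        assert weak_large >= weak_small
        assert strong_small >= weak_small

    def test_self_loops_never_reported(self):
        rng = np.random.default_rng(5)
        W = np.diag([0.6, 0.5, 0.4])
        runs = [
            simulate.simulate_roi_timeseries(
                NetworkSimSpec(n_rois=3, coeff_matrix=W, n_timepoints=300, seed=s)
            )
            for s in range(10)
        ]
        net = pcfdr_learn(runs)
        assert all(e.source != e.target for e in net.edges)

    def test_edge_universe_size(self):
        assert edge_universe_size(52) == 2652
        assert edge_universe_size(1) == 0


class TestDBNStrengths:
    def make_network(self, W, names=None):
        R = W.shape[0]
        names = names or tuple(f"roi{j:03d}" for j in range(R))
        edges = tuple(
            Edge(names[i], names[j], 0.0)
            for i in range(R)
            for j in range(R)
            if i != j and W[j, i] != 0
        )
        return DirectedNetwork(roi_names=names, edges=edges)

    def test_noise_free_exact_recovery(self):
        """A deterministic linear system yields its exact coefficients.

        The coefficient matrix mixes two circulant shifts so every target has
        two parents and a single slowly-decaying trajectory (spectral radius
        0.8) keeps the regression well conditioned.
        """
        R = 5
        W = np.zeros((R, R))
        for i in range(R):
            W[(i + 1) % R, i] += 0.5
            W[(i + 2) % R, i] += 0.3
        net = self.make_network(W)
        rng = np.random.default_rng(0)
        x = np.empty((40, R))
        x[0] = rng.normal(size=R)
        for t in range(1, 40):
            x[t] = W @ x[t - 1]
        sv = dbn_strengths(x, net)
        for e, val in zip(net.edges, sv.values):
            i = net.roi_names.index(e.source)
            j = net.roi_names.index(e.target)
            assert val == pytest.approx(W[j, i], abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        W = simulate.sparse_var_matrix(5, 0.2, 0.4, seed=7)
        net = self.make_network(W)
        x = simulate.simulate_roi_timeseries(
            NetworkSimSpec(n_rois=5, coeff_matrix=W, n_timepoints=400, seed=8)
        )
        sv = dbn_strengths(x, net)
        past, present = x[:-1], x[1:]
        for j in range(5):
            parents = [i for i in range(5) if W[j, i] != 0]
            if not parents:
                continue
            A = np.column_stack([np.ones(len(past)), past[:, parents]])
            coef = np.linalg.solve(A.T @ A, A.T @ present[:, j])
            for pi, i in enumerate(parents):
                lab = f"roi{i:03d}->roi{j:03d}"
                k = sv.edge_labels.index(lab)
                assert sv.values[k] == pytest.approx(coef[pi + 1], abs=1e-10)

    def test_null_edge_strength_near_zero(self):
        W = np.zeros((3, 3))
        W[1, 0] = 0.6
        net = DirectedNetwork(
            roi_names=("roi000", "roi001", "roi002"),
            edges=(Edge("roi000", "roi001", 0.0), Edge("roi002", "roi001", 0.0)),
        )
        x = simulate.simulate_roi_timeseries(
            NetworkSimSpec(n_rois=3, coeff_matrix=W, n_timepoints=2000, seed=9)
        )
        sv = dbn_strengths(x, net)
        k = sv.edge_labels.index("roi002->roi001")
        se = 1.0 / np.sqrt(2000)  # rough standard error of a null coefficient
        assert abs(sv.values[k]) < 3 * se

    def test_estimate_spread_scales_with_innovation(self):
        """Doubling innovation noise leaves strengths unbiased; spread of the
        estimates stays comparable (noise enters numerator and denominator)."""
        W = np.zeros((2, 2))
        W[1, 0] = 0.5
        net = self.make_network(W)
        for sd in (1.0, 2.0):
            vals = []
            for seed in range(40):
                x = simulate.simulate_roi_timeseries(
                    NetworkSimSpec(
                        n_rois=2,
                        coeff_matrix=W,
                        innovation_sd=sd,
                        n_timepoints=300,
                        seed=seed,
                    )
                )
                sv = dbn_strengths(x, net)
                vals.append(sv.values[0])
            assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_more_parents_than_samples_rejected(self):
        W = np.ones((5, 5)) * 0.1
        np.fill_diagonal(W, 0.0)
        net = self.make_network(W)
        with pytest.raises(InsufficientDataError):
            dbn_strengths(np.random.default_rng(0).normal(size=(4, 5)), net)


class TestNetworkContainer:
    def test_json_round_trip(self):
        net = DirectedNetwork(
            roi_names=("a", "b", "c"),
            edges=(Edge("a", "b", 0.001), Edge("c", "a", 0.02)),
            fdr_level=0.05,
        )
        back = DirectedNetwork.from_json(net.to_json())
        assert back == net

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DirectedNetwork(roi_names=("a", "b"), edges=(Edge("a", "a", 0.0),))
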