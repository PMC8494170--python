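"""M-SEM engine: initialisation, Gibbs steps, M step, alignment, full loop."""

import numpy as np
import pytest

from tdlbm import (BasisSpec, BlockPartition, CurveMatrix, LBMTheta,
                   MSEMControl, RandomEffectConfig, align_labels,
                   complete_data_loglik, init_partitions, m_step,
                   marginalization_step, run_msem, se_step)
from tdlbm.engine import _sample_categorical, average_thetas
from tdlbm.synthetic import cari, scenario_table1, simulate_dataset


def _tiny_data(n=6, d=4, T=8, seed=0):
    rng = np.random.default_rng(seed)
    return CurveMatrix(rng.normal(size=(n, d, T)), np.linspace(0, 1, T))


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

class TestInitPartitions:
    def test_single_cluster(self):
        data = _tiny_data()
        p = init_partitions(data, 1, 1, "random", seed=0)
        assert np.all(p.z == 0) and np.all(p.w == 0)

    def test_random_reproducible(self):
        data = _tiny_data()
        p1 = init_partitions(data, 3, 2, "random", seed=5)
        p2 = init_partitions(data, 3, 2, "random", seed=5)
        assert p1 == p2

    def test_kmeans_separates_exact_copies(self):
        T = 6
        a = np.sin(np.linspace(0, 3, T))
        b = np.cos(np.linspace(0, 3, T)) + 4
        rows = np.stack([a, a, b, b])          # 4 rows, 2 profiles
        vals = np.repeat(rows[:, None, :], 3, axis=1)
        data = CurveMatrix(vals, np.linspace(0, 1, T))
        p = init_partitions(data, 2, 1, "kmeans", seed=0)
        assert p.z[0] == p.z[1] and p.z[2] == p.z[3]
        assert p.z[0] != p.z[2]

    def test_out_of_range_k(self):
        data = _tiny_data()
        with pytest.raises(ValueError):
            init_partitions(data, 7, 1, "random", seed=0)


# ---------------------------------------------------------------------------
# SE step
# ---------------------------------------------------------------------------

def _uniform_theta(K, L, spec, config):
    from tdlbm.sim_model import zero_block_theta
    grid = [[zero_block_theta(spec, config) for _ in range(L)]
            for _ in range(K)]
    return LBMTheta(np.full(K, 1 / K), np.full(L, 1 / L), grid)


class TestSEStep:
    def test_single_cluster_unchanged(self, plain_spec):
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(1, 1, plain_spec, cfg)
        table = np.zeros((5, 3, 1, 1))
        part = BlockPartition(np.zeros(5, int), np.zeros(3, int), 1, 1)
        out, zp, wp = se_step(table, theta, part, 2,
                              np.random.default_rng(0), return_probs=True)
        assert np.all(out.z == 0) and np.all(out.w == 0)
        np.testing.assert_allclose(zp, 1.0)

    def test_dominated_multinomial(self, plain_spec):
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(2, 1, plain_spec, cfg)
        table = np.zeros((4, 3, 2, 1))
        table[:, :, 1, :] = 1000.0  # cluster 2 dominates every row
        part = BlockPartition(np.zeros(4, int), np.zeros(3, int), 2, 1)
        out = se_step(table, theta, part, 1, np.random.default_rng(0))
        assert np.all(out.z == 1)

    def test_conditional_probs_normalised(self, plain_spec):
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(3, 2, plain_spec, cfg)
        rng = np.random.default_rng(1)
        table = rng.normal(size=(6, 5, 3, 2))
        part = BlockPartition(rng.integers(0, 3, 6), rng.integers(0, 2, 5),
                              3, 2)
        _, zp, wp = se_step(table, theta, part, 3, rng, return_probs=True)
        np.testing.assert_allclose(zp.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(wp.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(zp >= 0) and np.all(wp >= 0)

    def test_degenerate_row_uniform_fallback(self):
        logits = np.full((2, 3), -np.inf)
        logits[1] = [0.0, 0.0, 0.0]
        with pytest.warns(RuntimeWarning):
            labels, p = _sample_categorical(logits, np.random.default_rng(0))
        np.testing.assert_allclose(p[0], 1 / 3)


# ---------------------------------------------------------------------------
# M step and complete-data log-likelihood
# ---------------------------------------------------------------------------

class TestMStep:
    def test_proportions_are_frequencies(self, plain_spec):
        data = _tiny_data(n=8, d=4)
        cfg = RandomEffectConfig.from_name("FFF")
        z = np.array([0, 0, 1, 1, 1, 1, 1, 1])
        w = np.array([0, 1, 1, 1])
        theta = m_step(data, BlockPartition(z, w, 2, 2), None, cfg,
                       plain_spec, MSEMControl())
        np.testing.assert_allclose(theta.pi, [0.25, 0.75])
        np.testing.assert_allclose(theta.rho, [0.25, 0.75])

    def test_empty_block_carries_over(self, plain_spec):
        data = _tiny_data(n=6, d=4)
        cfg = RandomEffectConfig.from_name("FFF")
        part0 = BlockPartition(np.array([0, 0, 0, 1, 1, 1]),
                               np.array([0, 0, 1, 1]), 2, 2)
        prev = m_step(data, part0, None, cfg, plain_spec, MSEMControl())
        # all rows now in cluster 0: blocks (1, l) are empty
        part1 = BlockPartition(np.zeros(6, int), np.array([0, 0, 1, 1]), 2, 2)
        theta = m_step(data, part1, prev, cfg, plain_spec, MSEMControl())
        np.testing.assert_array_equal(theta.theta[1][0].beta,
                                      prev.theta[1][0].beta)
        assert theta.pi[1] == pytest.approx(1 / 60 / (1 / 60 + 1))


class TestCompleteDataLoglik:
    def test_single_block_equals_table_sum(self, plain_spec):
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(1, 1, plain_spec, cfg)
        rng = np.random.default_rng(2)
        table = rng.normal(size=(4, 3, 1, 1))
        part = BlockPartition(np.zeros(4, int), np.zeros(3, int), 1, 1)
        assert complete_data_loglik(table, part, theta) == pytest.approx(
            table.sum())

    def test_matches_hand_sum_on_2x2(self, plain_spec):
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(2, 2, plain_spec, cfg)
        theta.pi[:] = [0.3, 0.7]
        theta.rho[:] = [0.4, 0.6]
        table = np.arange(2 * 2 * 2 * 2, dtype=float).reshape(2, 2, 2, 2)
        part = BlockPartition(np.array([0, 1]), np.array([1, 0]), 2, 2)
        hand = (np.log(0.3) + np.log(0.7) + np.log(0.4) + np.log(0.6)
                + table[0, 0, 0, 1] + table[0, 1, 0, 0]
                + table[1, 0, 1, 1] + table[1, 1, 1, 0])
        assert complete_data_loglik(table, part, theta) == pytest.approx(hand)

    def test_relabeling_invariance(self, plain_spec):
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(2, 2, plain_spec, cfg)
        theta.pi[:] = [0.3, 0.7]
        rng = np.random.default_rng(3)
        table = rng.normal(size=(5, 4, 2, 2))
        z = rng.integers(0, 2, 5)
        w = rng.integers(0, 2, 4)
        v0 = complete_data_loglik(table, BlockPartition(z, w, 2, 2), theta)
        # swap row-cluster labels everywhere
        theta2 = _uniform_theta(2, 2, plain_spec, cfg)
        theta2.pi[:] = [0.7, 0.3]
        v1 = complete_data_loglik(table[:, :, ::-1, :],
                                  BlockPartition(1 - z, w, 2, 2), theta2)
        assert v0 == pytest.approx(v1)


# ---------------------------------------------------------------------------
# label alignment and averaging
# ---------------------------------------------------------------------------

class TestAlignLabels:
    def _theta(self, K, L, spec):
        cfg = RandomEffectConfig.from_name("FFF")
        th = _uniform_theta(K, L, spec, cfg)
        th.pi[:] = np.linspace(1, K, K) / np.linspace(1, K, K).sum()
        for k in range(K):
            for l in range(L):
                th.theta[k][l].beta[:] = 10 * k + l
        return th

    def test_identity(self, plain_spec):
        part = BlockPartition(np.array([0, 1, 0]), np.array([0, 1]), 2, 2)
        th = self._theta(2, 2, plain_spec)
        out_p, out_t = align_labels(part, part, th)
        assert out_p == part
        np.testing.assert_allclose(out_t.pi, th.pi)

    def test_swap_recovered(self, plain_spec):
        ref = BlockPartition(np.array([0, 0, 1, 1]), np.array([0, 1]), 2, 2)
        swapped = BlockPartition(1 - ref.z, ref.w, 2, 2)
        th = self._theta(2, 2, plain_spec)
        out_p, out_t = align_labels(ref, swapped, th)
        assert out_p == ref
        # theta grid permuted consistently: block (0, l) now carries the
        # parameters originally at (1, l)
        assert out_t.theta[0][0].beta[0] == 10.0
        np.testing.assert_allclose(out_t.pi, th.pi[::-1])

    def test_aligned_average_of_swapped_copies(self, plain_spec):
        ref = BlockPartition(np.array([0, 0, 1]), np.array([0, 1]), 2, 2)
        th = self._theta(2, 2, plain_spec)
        swapped_part = BlockPartition(1 - ref.z, ref.w, 2, 2)
        th_swapped = self._theta(2, 2, plain_spec)
        th_swapped.pi[:] = th.pi[::-1]
        for k in range(2):
            for l in range(2):
                th_swapped.theta[k][l].beta[:] = 10 * (1 - k) + l
        _, aligned = align_labels(ref, swapped_part, th_swapped)
        avg = average_thetas([th, aligned])
        np.testing.assert_allclose(avg.pi, th.pi)
        assert avg.theta[1][0].beta[0] == 10.0


# ---------------------------------------------------------------------------
# full loop
# ---------------------------------------------------------------------------

class TestRunMSEM:
    def test_degenerate_single_block(self, plain_spec):
        data = _tiny_data(n=5, d=3)
        cfg = RandomEffectConfig.from_name("FFF")
        ctrl = MSEMControl(n_iterations=6, burn_in=2, seed=0)
        res = run_msem(data, 1, 1, cfg, plain_spec, ctrl)
        assert np.all(res.partition.z == 0) and np.all(res.partition.w == 0)
        assert res.llc_trace.size == res.n_iterations_run

    def test_constant_trace_converges_after_three_postburn_iters(self,
                                                                 plain_spec):
        # FFF on fixed data: no MC noise, K=L=1 partition frozen, so the
        # trace is constant and the stopping rule fires immediately
        data = _tiny_data(n=5, d=3)
        cfg = RandomEffectConfig.from_name("FFF")
        ctrl = MSEMControl(n_iterations=50, burn_in=4, seed=0, delta=1e-3)
        res = run_msem(data, 1, 1, cfg, plain_spec, ctrl)
        assert res.converged
        assert res.n_iterations_run == 4 + 3

    def test_seed_determinism(self):
        sc = scenario_table1(n=24, d=9)
        sim = simulate_dataset(sc, np.random.default_rng(11))
        from tdlbm import TimeDependentLBM
        kw = dict(n_row_clusters=2, n_col_clusters=2, random_effects="TFT",
                  n_iterations=8, burn_in=3, n_interior_knots=8,
                  n_mc_score=50, random_state=123)
        e1 = TimeDependentLBM(**kw).fit(sim.data)
        e2 = TimeDependentLBM(**kw).fit(sim.data)
        np.testing.assert_array_equal(e1.row_labels_, e2.row_labels_)
        np.testing.assert_array_equal(e1.column_labels_, e2.column_labels_)
        np.testing.assert_allclose(e1.llc_trace_, e2.llc_trace_)
        assert e1.result_.llc_hat == e2.result_.llc_hat

    def test_sampled_partitions_valid(self, plain_spec):
        data = _tiny_data(n=8, d=5, seed=4)
        cfg = RandomEffectConfig.from_name("FFF")
        ctrl = MSEMControl(n_iterations=6, burn_in=2, seed=3,
                           init_method="random")
        res = run_msem(data, 3, 2, cfg, plain_spec, ctrl)
        for p in res.partition_samples:
            assert p.z.min() >= 0 and p.z.max() < 3
            assert p.w.min() >= 0 and p.w.max() < 2
            assert p.z.size == 8 and p.w.size == 5


class TestMarginalizationStep:
    def test_fff_table_is_deterministic_and_exact(self, plain_spec):
        data = _tiny_data(n=3, d=2, seed=5)
        cfg = RandomEffectConfig.from_name("FFF")
        theta = _uniform_theta(1, 1, plain_spec, cfg)
        t1 = marginalization_step(data, theta, 10, np.random.default_rng(0),
                                  plain_spec)
        t2 = marginalization_step(data, theta, 50, np.random.default_rng(9),
                                  plain_spec)
        np.testing.assert_allclose(t1, t2)  # no MC variability
        from tdlbm import conditional_logdensity
        want = conditional_logdensity(data.cell(1, 1), (0, 0, 0),
                                      theta.theta[0][0], plain_spec)
        assert t1[1, 1, 0, 0] == pytest.approx(want, rel=1e-10)

    def test_all_entries_finite(self, padded_spec):
        data = _tiny_data(n=4, d=3, seed=6)
        cfg = RandomEffectConfig.from_name("TFT")
        from tests.conftest import make_theta
        grid = [[make_theta(padded_spec, "TFT", seed=k * 2 + l)
                 for l in range(2)] for k in range(2)]
        theta = LBMTheta(np.array([0.5, 0.5]), np.array([0.5, 0.5]), grid)
        table = marginalization_step(data, theta, 20,
                                     np.random.default_rng(1), padded_spec)
        assert np.all(np.isfinite(table))
        assert table.shape == (4, 3, 2, 2)
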