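import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ginifano import (
    Partition,
    WeightParams,
    connectivity,
    consensus_matrix,
    choose_k_final,
    derive_params,
    final_cluster,
    gini_cell_weight,
    pair_weights,
)
from ginifano.consensus import cell_weights
from tests.conftest import random_partition


class TestConnectivity:
    def test_shared_cluster_definition(self):
        p = Partition(np.array([1, 1, 2]))
        np.testing.assert_array_equal(
            connectivity(p), [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        )

    def test_single_cluster_all_ones(self):
        p = Partition(np.ones(5, dtype=int))
        np.testing.assert_array_equal(connectivity(p), np.ones((5, 5)))

    def test_singletons_identity(self):
        p = Partition(np.arange(1, 6))
        np.testing.assert_array_equal(connectivity(p), np.eye(5))

    def test_noise_connects_only_to_itself(self):
        p = Partition(np.array([1, 0, 0, 1]))
        m = connectivity(p)
        assert m[1, 2] == 0 and m[1, 1] == 1 and m[0, 3] == 1


class TestWeightParams:
    def test_logistic_midpoint(self):
        params = derive_params(mu=0.05, s=0.01, f=0.1)
        assert gini_cell_weight(params.mu_prime, params) == pytest.approx(0.5)

    def test_one_scale_above_midpoint(self):
        params = derive_params(mu=0.05, s=0.01, f=0.1)
        x = params.mu_prime + params.s_prime
        assert gini_cell_weight(x, params) == pytest.approx(1 - 1 / (1 + np.e**-1), abs=1e-12)

    def test_saturates_to_one_for_tiny_clusters(self):
        params = WeightParams(mu_prime=0.5, s_prime=0.01, f_prime=0.1)
        assert gini_cell_weight(1e-6, params) == pytest.approx(1.0, abs=1e-6)

    def test_strictly_decreasing(self):
        params = derive_params()
        xs = np.linspace(1e-4, 1.0, 200)
        w = gini_cell_weight(xs, params)
        assert (np.diff(w) < 0).all()

    def test_f_prime_from_f(self):
        assert derive_params(f=0.25).f_prime == pytest.approx(1 / 3)

    def test_round_trip(self, rng):
        for _ in range(200):
            mu = rng.uniform(0.01, 0.5)
            s = rng.uniform(1e-3, 0.2)
            f = rng.uniform(1e-3, 0.499)
            p = derive_params(mu, s, f)
            assert p.mu == pytest.approx(mu, abs=1e-12)
            assert p.s == pytest.approx(s, abs=1e-12)
            assert p.f == pytest.approx(f, abs=1e-12)
            # forward relation holds exactly
            fwd = 1 - 1 / (1 + np.exp(-(p.mu - p.mu_prime) / p.s_prime))
            assert fwd == pytest.approx(p.f_prime, abs=1e-12)

    def test_invalid_f_rejected(self):
        for f in (-0.1, 0.0, 0.5, 0.9, 1.0, 1.5):
            with pytest.raises(ValueError):
                derive_params(f=f)


class TestPairWeights:
    def test_max_rule_and_normalization(self):
        wg, wf = pair_weights(1.0, 0.0, 1.0)
        assert (wg, wf) == (0.5, 0.5)

    def test_pure_fano_limit(self):
        wg, wf = pair_weights(0.0, 0.0, 0.7)
        assert (wg, wf) == (0.0, 1.0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            pair_weights(0.0, 0.0, 0.0)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(1e-6, 1e3)
    )
    @settings(max_examples=500, deadline=None)
    def test_sum_to_one_nonnegative(self, wi, wj, fp):
        wg, wf = pair_weights(wi, wj, fp)
        assert wg + wf == pytest.approx(1.0, abs=1e-12)
        assert wg >= 0 and wf >= 0

    def test_sum_to_one_bulk(self, rng):
        # dense random sweep mirroring the matrix implementation
        w = rng.random(10**4)
        params = derive_params()
        pair = np.maximum(w, rng.random(10**4))
        wg = pair / (pair + params.f_prime)
        np.testing.assert_allclose(wg + (1 - wg), 1.0, atol=1e-15)


class TestConsensusMatrix:
    def _random_setup(self, rng, n=15):
        pg = random_partition(rng, n, 4)
        pf = random_partition(rng, n, 3)
        params = derive_params()
        w = cell_weights(pg, params)
        return pg, pf, params, w

    def test_identical_partitions_fixed_point(self, rng):
        p = random_partition(rng, 12, 3)
        params = derive_params()
        m = connectivity(p)
        mbar = consensus_matrix(m, m, cell_weights(p, params), params)
        np.testing.assert_allclose(mbar, m, atol=1e-12)

    def test_half_weights_give_half_entry(self):
        # one cell pair clustered together only by the Gini partition, with
        # weights forced to (0.5, 0.5) via w~ = f'
        params = WeightParams(mu_prime=0.5, s_prime=0.1, f_prime=1.0)
        pg = Partition(np.array([1, 1]))
        pf = Partition(np.array([1, 2]))
        mbar = consensus_matrix(
            connectivity(pg), connectivity(pf), np.array([1.0, 1.0]), params
        )
        assert mbar[0, 1] == pytest.approx(0.5)

    def test_entrywise_oracle(self, rng):
        pg, pf, params, w = self._random_setup(rng)
        mg, mf = connectivity(pg), connectivity(pf)
        mbar = consensus_matrix(mg, mf, w, params)
        for i in range(pg.n):
            for j in range(pg.n):
                if i == j:
                    assert mbar[i, j] == 1.0
                    continue
                wg, wf = pair_weights(w[i], w[j], params.f_prime)
                assert mbar[i, j] == pytest.approx(wg * mg[i, j] + wf * mf[i, j], abs=1e-12)

    def test_convexity_bounds(self, rng):
        for _ in range(20):
            pg, pf, params, w = self._random_setup(rng)
            mg, mf = connectivity(pg), connectivity(pf)
            mbar = consensus_matrix(mg, mf, w, params)
            lo, hi = np.minimum(mg, mf), np.maximum(mg, mf)
            assert (mbar >= lo - 1e-12).all() and (mbar <= hi + 1e-12).all()

    def test_dimension_mismatch(self, rng):
        pg, pf, params, w = self._random_setup(rng)
        with pytest.raises(ValueError, match="mismatch"):
            consensus_matrix(connectivity(pg), np.eye(4), w, params)


class TestFinalCluster:
    def test_block_diagonal_recovered(self):
        mbar = np.zeros((7, 7))
        mbar[:4, :4] = 1.0
        mbar[4:, 4:] = 1.0
        part = final_cluster(mbar, 2, seed=0)
        assert part.labels[0] == part.labels[3]
        assert part.labels[4] == part.labels[6]
        assert part.labels[0] != part.labels[4]

    def test_matches_exhaustive_bipartition(self, rng):
        n = 8
        pg = random_partition(rng, n, 3)
        pf = random_partition(rng, n, 2)
        params = derive_params()
        mbar = consensus_matrix(
            connectivity(pg), connectivity(pf), cell_weights(pg, params), params
        )
        part = final_cluster(mbar, 2, n_restarts=20, seed=3)
        labels = part.labels

        def connectivity_cost(assign):
            u = (np.asarray(assign)[:, None] == np.asarray(assign)[None, :]).astype(float)
            return ((mbar - u) ** 2).sum()

        best = min(
            connectivity_cost(a)
            for a in itertools.product([0, 1], repeat=n)
            if len(set(a)) == 2
        )
        assert connectivity_cost(labels) == pytest.approx(best, rel=1e-9)

    def test_k_equals_n_closed_form(self, rng):
        # a generic association matrix with distinct rows: every cell becomes
        # its own cluster and the cost reduces to the off-diagonal mass
        n = 6
        a = rng.random((n, n))
        mbar = (a + a.T) / 2
        np.fill_diagonal(mbar, 1.0)
        part = final_cluster(mbar, n, seed=0)
        assert part.k == n
        u = np.eye(n)
        assert ((mbar - u) ** 2).sum() == pytest.approx(
            (mbar[~np.eye(n, dtype=bool)] ** 2).sum()
        )

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            final_cluster(np.eye(3), 4, seed=0)


class TestDegenerateLimits:
    def test_pure_gini_limit(self, rng):
        pg = random_partition(rng, 20, 4)
        pf = random_partition(rng, 20, 2)
        params = WeightParams(mu_prime=100.0, s_prime=1.0, f_prime=1e-12)
        w = cell_weights(pg, params)  # logistic saturated at 1 for every cell
        mbar = consensus_matrix(connectivity(pg), connectivity(pf), w, params)
        np.testing.assert_allclose(mbar, connectivity(pg), atol=1e-9)
        part = final_cluster(mbar, pg.k, n_restarts=20, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(part.labels, pg.labels) == 1.0

    def test_pure_fano_limit(self, rng):
        pg = random_partition(rng, 20, 4)
        pf = random_partition(rng, 20, 2)
        params = WeightParams(mu_prime=0.05, s_prime=0.01, f_prime=1e6)
        mbar = consensus_matrix(
            connectivity(pg), connectivity(pf), cell_weights(pg, params), params
        )
        np.testing.assert_allclose(mbar, connectivity(pf), atol=1e-5)
        part = final_cluster(mbar, pf.k, n_restarts=20, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(part.labels, pf.labels) == 1.0


class TestChooseKFinal:
    def _partition_with_proportions(self, props, n=10000):
        sizes = [max(1, round(p * n)) for p in props]
        labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
        return Partition(labels)

    def test_rule_arithmetic(self):
        pg = self._partition_with_proportions([0.97, 0.003, 0.002, 0.0013, 0.001])
        pf = self._partition_with_proportions([0.6, 0.4])
        params = derive_params(mu=0.05, s=0.01, f=0.1)
        assert choose_k_final(pg, pf, params) == 6

    def test_no_rare_candidates(self):
        pg = self._partition_with_proportions([0.5, 0.5])
        pf = self._partition_with_proportions([0.6, 0.4])
        params = derive_params(mu=0.05, s=0.01, f=0.1)
        assert choose_k_final(pg, pf, params) == 2
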