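import numpy as np
import pytest

from spatialnb.esda import (
    getis_ord_gstar,
    local_morans_i,
    mean_center_and_standard_distance,
    morans_i,
    morans_i_permutation,
)
from spatialnb.weights import WeightMatrix, queen_contiguity, row_standardize

from conftest import random_weight_matrix


def moran_oracle(y, w):
    """Brute-force double-loop evaluation of the Moran's I definition."""
    n = len(y)
    ybar = y.mean()
    num = sum(
        w[i, j] * (y[i] - ybar) * (y[j] - ybar) for i in range(n) for j in range(n)
    )
    den = sum((y[i] - ybar) ** 2 for i in range(n))
    return n / w.sum() * num / den


def gstar_oracle(y, w_star):
    """Brute-force Gi* with explicit per-unit loops (self-weight already set)."""
    n = len(y)
    ybar = y.mean()
    s = np.sqrt(sum(v**2 for v in y) / n - ybar**2)
    out = []
    for i in range(n):
        wsum = sum(w_star[i, j] for j in range(n))
        w2 = sum(w_star[i, j] ** 2 for j in range(n))
        num = sum(w_star[i, j] * y[j] for j in range(n)) - ybar * wsum
        den = s * np.sqrt((n * w2 - wsum**2) / (n - 1))
        out.append(num / den)
    return np.array(out)


class TestGlobalMoran:
    def test_expected_value_at_n_305(self):
        # the null expectation -1/(n-1) at the survey's 305 clusters
        rng = np.random.default_rng(0)
        wm = random_weight_matrix(rng, 305)
        res = morans_i(rng.poisson(10, 305).astype(float), wm)
        assert round(res.expected, 4) == -0.0033

    def test_two_node_antithetic_pair_gives_minus_one(self):
        wm = queen_contiguity(edge_list=[(1, 2)])
        res = morans_i(np.array([-1.0, 1.0]), wm)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(5, 25)
            wm = random_weight_matrix(rng, n)
            y = rng.normal(size=n)
            res = morans_i(y, wm)
            assert res.statistic == pytest.approx(moran_oracle(y, wm.w), abs=1e-12)

    def test_constant_y_and_too_few_points_rejected(self, ring5):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(5), ring5)
        with pytest.raises(ValueError, match="at least"):
            morans_i(np.array([1.0]), WeightMatrix(np.zeros((1, 1)), "queen"))

    def test_checkerboard_negative_two_blocks_positive(self):
        # bipartite 2x3 grid checkerboard -> negative autocorrelation
        edges = [(1, 2), (2, 3), (4, 5), (5, 6), (1, 4), (2, 5), (3, 6)]
        wm = queen_contiguity(edge_list=edges)
        checker = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert morans_i(checker, wm).statistic < 0
        # two homogeneous blocks joined by one edge -> positive
        edges2 = [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)]
        wm2 = queen_contiguity(edge_list=edges2)
        blocks = np.array([5.0, 5.2, 4.9, 1.0, 1.1, 0.8])
        assert morans_i(blocks, wm2).statistic > 0


class TestPermutationInference:
    def test_p_is_one_when_observed_below_all_permutations(self):
        # a strong checkerboard gives the most negative I achievable, so
        # every permutation is >= it and the one-sided (clustering) p -> 1
        edges = [(i, i + 1) for i in range(1, 20)]
        wm = queen_contiguity(edge_list=edges)
        y = np.array([(-1.0) ** i for i in range(20)])
        res = morans_i_permutation(y, wm, n_perm=99, seed=1)
        assert res.p_value > 0.9

    def test_seed_determinism(self, ring5):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        a = morans_i_permutation(y, ring5, n_perm=199, seed=9)
        b = morans_i_permutation(y, ring5, n_perm=199, seed=9)
        assert a.p_value == b.p_value
        assert a.statistic == b.statistic

    def test_type_one_error_calibration(self):
        # i.i.d. y: rejection rate at alpha = 0.05 should be ~5%
        rng = np.random.default_rng(2024)
        wm = random_weight_matrix(np.random.default_rng(5), 30)
        rej = 0
        reps = 1000
        for rep in range(reps):
            y = rng.standard_normal(30)
            res = morans_i_permutation(y, wm, n_perm=99, seed=rep)
            rej += res.p_value <= 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_normal_and_permutation_p_agree_for_large_n(self):
        rng = np.random.default_rng(8)
        wm = random_weight_matrix(rng, 120)
        y = rng.standard_normal(120)
        p_norm = morans_i(y, wm, two_sided=False).p_value
        p_perm = morans_i_permutation(y, wm, n_perm=999, seed=0).p_value
        assert abs(p_norm - p_perm) < 0.02

    def test_requires_enough_permutations(self, ring5):
        with pytest.raises(ValueError, match="99"):
            morans_i_permutation(np.arange(5.0), ring5, n_perm=10)


class TestLocalMoran:
    def test_constant_y_rejected(self, ring5):
        with pytest.raises(ValueError, match="constant"):
            local_morans_i(np.full(5, 2.0), ring5)

    def test_isolated_mass_pair_only_nonzero_on_binary_graph(self):
        # mass concentrated on an adjacent pair: with binary weights only
        # those two units see a nonzero spatial lag contribution
        edges = [(1, 2), (3, 4), (5, 6)]
        wm = queen_contiguity(edge_list=edges)
        y = np.array([10.0, 10.0, 1.0, 1.0, 1.0, 1.0])
        out = local_morans_i(y, wm, n_perm=99, seed=0)
        z = (y - y.mean()) / y.std()
        lag = wm.w @ z
        np.testing.assert_allclose(out["local_i"].to_numpy(), z * lag, atol=1e-12)
        assert abs(out["local_i"].iloc[0]) > 0
        assert out["local_i"].iloc[0] == out["local_i"].iloc[1]

    def test_sum_relates_to_global_statistic(self):
        # sum of local statistics is proportional to global I; verify the
        # exact relation numerically against the brute-force global value
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(6, 20))
            wm = random_weight_matrix(rng, n)
            y = rng.normal(size=n)
            local = local_morans_i(y, wm, n_perm=99, seed=0)["local_i"].sum()
            i_global = moran_oracle(y, wm.w)
            # local_i uses population sd: sum(local) = I * S0 * (n-1)/n... the
            # cleanest invariant: sum z_i * lag_i == I * S0 * mean(z^2)
            z = (y - y.mean()) / y.std()
            assert local == pytest.approx(i_global * wm.w.sum() * np.mean(z**2), rel=1e-10)

    def test_cold_spot_labeling(self):
        # a clearly low cluster surrounded by low values gets 'cold'
        edges = [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)]
        wm = queen_contiguity(edge_list=edges)
        y = np.array([0.1, 0.2, 0.1, 9.0, 9.5, 9.2])
        out = local_morans_i(y, wm, n_perm=199, seed=3, alpha=0.2)
        assert (out["label"].iloc[:3] != "hot").all()
        assert "cold" in set(out["label"].iloc[:3])


class TestGetisOrdGstar:
    def test_constant_y_rejected(self, ring5):
        with pytest.raises(ValueError, match="constant"):
            getis_ord_gstar(np.full(5, 3.0), ring5)

    def test_high_value_cluster_scores_hottest(self):
        # Gi* ranks a unit by the concentration of high values in its
        # neighborhood (self included): members of the high block must
        # score positive and above every low-block unit
        edges = [(1, 2), (2, 3), (1, 3), (3, 4), (4, 5), (5, 6), (4, 6)]
        wm = queen_contiguity(edge_list=edges)
        y = np.array([48.0, 52.0, 50.0, 5.0, 4.0, 6.0])
        g = getis_ord_gstar(y, wm)["g_star"]
        assert g.iloc[:2].min() > 0
        assert g.iloc[:2].min() > g.iloc[4:].max()

    def test_neighbor_of_single_large_value_scores_high(self):
        # one large value at the star center: each leaf's neighborhood is
        # {center, self}, dominated by the spike, so leaves outscore
        # far-away units (direct evaluation of the starred statistic)
        edges = [(1, 2), (1, 3), (1, 4), (1, 5), (6, 7)]
        wm = queen_contiguity(edge_list=edges)
        y = np.array([50.0, 10.0, 11.0, 9.0, 10.0, 10.5, 9.5])
        g = getis_ord_gstar(y, wm)["g_star"]
        assert g.iloc[1:5].min() > 0
        assert g.iloc[1:5].min() > max(g.iloc[0], g.iloc[5], g.iloc[6])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(5, 20))
            wm = random_weight_matrix(rng, n)
            y = rng.uniform(1, 20, size=n)
            g = getis_ord_gstar(y, wm)["g_star"].to_numpy()
            w_star = wm.w.copy()
            np.fill_diagonal(w_star, 1.0)
            np.testing.assert_allclose(g, gstar_oracle(y, w_star), atol=1e-12)

    def test_degenerate_denominator_flagged(self):
        # 2 units: with self-weight each row is all ones -> inner term 0
        wm = queen_contiguity(edge_list=[(1, 2)])
        out = getis_ord_gstar(np.array([1.0, 2.0]), wm)
        assert not out["defined"].any()
        assert out["g_star"].isna().all()


class TestMeanCenter:
    def test_single_point(self):
        center, sd = mean_center_and_standard_distance(np.array([[2.0, 3.0]]))
        np.testing.assert_allclose(center, [2.0, 3.0])
        assert sd == 0.0

    def test_two_points(self):
        center, sd = mean_center_and_standard_distance(np.array([[0.0, 0.0], [2.0, 0.0]]))
        np.testing.assert_allclose(center, [1.0, 0.0])
        assert sd == pytest.approx(1.0)

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(size=(9, 2))
        c1, s1 = mean_center_and_standard_distance(pts)
        c2, s2 = mean_center_and_standard_distance(pts, weights=np.full(9, 3.0))
        np.testing.assert_allclose(c1, c2)
        assert s1 == pytest.approx(s2)
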