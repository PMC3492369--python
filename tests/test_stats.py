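"""The five topology statistics against exact-arithmetic oracles and the
published worked examples."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from ctdnet import (
    CHEM_GENE,
    GENE_DISEASE,
    PoolWeights,
    ScoreInputs,
    bonferroni_correct,
    c_xy,
    c_xy_tail,
    enumerate_cd_inferences,
    geometric_mean_degree,
    log_choose,
    make_fixture,
    opinion_pool,
    p1_score,
    p2_score,
    s_score,
    score_inference,
    score_table,
    w_score,
)
from ctdnet.network import TripartiteNetwork
from conftest import (
    oracle_c_xy,
    oracle_p1,
    oracle_p2,
    random_network,
    random_sparse_inputs,
)


class TestLogChoose:
    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(st.integers(0, 1200), st.data())
    def test_matches_exact_big_integer_logarithm(self, n, data):
        r = data.draw(st.integers(0, n))
        exact = math.comb(n, r)
        assert log_choose(n, r) == pytest.approx(math.log(exact), rel=1e-9, abs=1e-9)

    def test_small_identities(self):
        assert log_choose(5, 2) == pytest.approx(math.log(10), rel=1e-12)
        assert log_choose(17, 0) == 0.0
        assert log_choose(1000, 400) == pytest.approx(
            math.log(math.comb(1000, 400)), rel=1e-9
        )

    @pytest.mark.parametrize("n,r", [(3, 4), (-1, 0), (2, -1)])
    def test_invalid_arguments_raise(self, n, r):
        with pytest.raises(ValueError):
            log_choose(n, r)


class TestCxy:
    def test_zero_overlap_tail_is_certain(self):
        assert c_xy_tail(10, 10, 0, 100) == 0.0

    def test_tiny_exact_case(self):
        # N=4, n_x=n_y=2, m=2: C(2,2)C(2,0)/C(4,2) = 1/6
        inputs = ScoreInputs(n_x=2, n_y=2, m=2, N=4)
        assert c_xy(inputs) == pytest.approx(math.log10(6), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_survival_function(self, seed):
        rng = np.random.default_rng(seed)
        n_x, n_y, m, N = random_sparse_inputs(rng)
        expected = -math.log10(hypergeom.sf(m - 1, N, n_x, n_y))
        assert c_xy(ScoreInputs(n_x, n_y, m, N)) == pytest.approx(expected, rel=1e-6)

    def test_dense_network_lower_limit(self):
        # endpoints cover most of the network: overlap below n_x+n_y-N is
        # impossible, and the tail must still be a valid probability
        value = c_xy(ScoreInputs(n_x=5, n_y=5, m=4, N=6))
        exact = oracle_c_xy(5, 5, 4, 6)
        assert value == pytest.approx(exact, rel=1e-9)

    def test_hub_penalty_in_endpoint_degree(self):
        base = dict(n_y=20, m=3, N=5000)
        low = c_xy(ScoreInputs(n_x=10, **base))
        high = c_xy(ScoreInputs(n_x=100, **base))
        assert high < low


class TestP1P2Oracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_p1_matches_exact_rational_evaluation(self, seed):
        rng = np.random.default_rng(100 + seed)
        N = int(rng.integers(20, 500))
        n_x = int(rng.integers(2, N // 2))
        n_y = int(rng.integers(2, N // 2))
        m = int(rng.integers(1, min(n_x, n_y, 10) + 1))
        got = p1_score(ScoreInputs(n_x, n_y, m, N))
        assert got == pytest.approx(max(0.0, oracle_p1(n_x, n_y, m, N)), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_p2_matches_exact_rational_evaluation(self, seed):
        rng = np.random.default_rng(200 + seed)
        N = int(rng.integers(50, 500))
        m = int(rng.integers(1, 6))
        degs = tuple(int(rng.integers(2, N // 2)) for _ in range(m))
        inputs = ScoreInputs(n_x=N // 2, n_y=N // 2, m=m, N=N, gene_degrees=degs)
        assert p2_score(inputs) == pytest.approx(oracle_p2(degs, N), rel=1e-9)

    def test_p1_dominates_c_xy(self):
        # the point probability is inside the tail, and p1's natural-log
        # scale only widens the gap
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_x, n_y, m, N = random_sparse_inputs(rng)
            inputs = ScoreInputs(n_x, n_y, m, N)
            assert p1_score(inputs) >= c_xy(inputs)

    def test_p2_additive_over_disjoint_gene_subsets(self):
        N = 10_000
        a = (12, 57, 101)
        b = (8, 300)
        pa = p2_score(ScoreInputs(600, 600, len(a), N, a))
        pb = p2_score(ScoreInputs(600, 600, len(b), N, b))
        pab = p2_score(ScoreInputs(600, 600, len(a + b), N, a + b))
        assert pa + pb == pytest.approx(pab, rel=1e-12)

    def test_p2_requires_gene_degrees_of_at_least_two(self):
        with pytest.raises(ValueError, match="both endpoints"):
            ScoreInputs(10, 10, 2, 100, gene_degrees=(5, 1))


class TestOpinionPool:
    def test_published_equal_weight_example(self):
        assert s_score(17.30, 40.32) == pytest.approx(28.81, abs=5e-3)

    def test_zero_inputs_pool_to_zero(self):
        assert opinion_pool(0.0, 0.0, PoolWeights(0.3, 0.9)) == 0.0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_equal_weights_are_the_arithmetic_mean(self, a, b):
        assert s_score(a, b) == pytest.approx((a + b) / 2, rel=1e-12, abs=1e-12)

    def test_idempotent_on_equal_inputs(self):
        assert s_score(3.7, 3.7) == pytest.approx(3.7, rel=1e-12)

    def test_mean_of_printed_table_row(self):
        # the published cell prints 22.04 from unrounded inputs; the
        # arithmetic identity on the printed inputs gives 22.115
        assert s_score(17.21, 27.02) == pytest.approx(22.115, abs=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            PoolWeights(-0.1, 0.5)


class TestWScore:
    def test_published_m9_example(self):
        assert w_score(17.30, 40.32, m=9) == pytest.approx(17.31, abs=0.02)

    def test_published_m5_example(self):
        assert w_score(17.21, 27.02, m=5) == pytest.approx(17.10, abs=0.01)

    def test_weights_solved_from_published_rows_match_schedule(self):
        # two m=5 rows pin the weights as a 2x2 linear system; the
        # implemented schedule must reproduce both W cells within print
        # rounding
        a = np.array([[17.21, 27.02], [2.97, 28.15]])
        b = np.array([17.10, 3.20])
        w1, w2 = np.linalg.solve(a, b)
        weights = PoolWeights.m_weighted(5)
        assert opinion_pool(17.21, 27.02, weights) == pytest.approx(17.10, abs=0.02)
        assert opinion_pool(2.97, 28.15, weights) == pytest.approx(3.20, abs=0.02)
        assert weights.w1 == pytest.approx(w1, abs=5e-3)
        assert weights.w2 == pytest.approx(w2, abs=5e-3)

    def test_weight_on_p1_grows_with_m(self):
        w1s = [PoolWeights.m_weighted(m).w1 for m in range(1, 30)]
        assert all(b > a for a, b in zip(w1s, w1s[1:]))
        assert w1s[-1] == pytest.approx(1.0, abs=1e-6)

    def test_m_below_one_rejected(self):
        with pytest.raises(ValueError):
            w_score(1.0, 1.0, m=0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "score,n,expected",
        [(10, 100, 8.0), (1, 100, 0.0), (3.30103, 2, 3.0)],
    )
    def test_log_scale_correction(self, score, n, expected):
        assert bonferroni_correct(score, n) == pytest.approx(expected, abs=1e-5)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(0, 500), st.integers(1, 10**6))
    def test_never_exceeds_raw_score(self, score, n):
        corrected = bonferroni_correct(score, n)
        assert 0.0 <= corrected <= score
        if n == 1:
            assert corrected == score

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_correct(1.0, 0)


class TestGeometricMean:
    def test_small_exact_case(self):
        assert geometric_mean_degree([4, 9]) == pytest.approx(6.0, rel=1e-12)

    def test_published_gene_set_example(self):
        fx = make_fixture("fig2_pair")
        degs = fx.score_inputs["malathion"].gene_degrees
        assert geometric_mean_degree(degs) == pytest.approx(125.8, abs=0.05)

    def test_empty_or_zero_degrees_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_degree([])
        with pytest.raises(ValueError):
            geometric_mean_degree([3, 0])


class TestScoreInference:
    def test_toy_single_gene_inference_is_finite_and_consistent(self, toy_net):
        net = TripartiteNetwork()
        net.add_edge(CHEM_GENE, "X", "g1")
        net.add_edge(GENE_DISEASE, "g1", "Y")
        (inf,) = enumerate_cd_inferences(net)
        vec = score_inference(net, inf)
        for value in (vec.c_xy, vec.p1, vec.p2, vec.s_xya, vec.w_xya):
            assert np.isfinite(value) and value >= 0
        assert vec.s_xya == pytest.approx((vec.p1 + vec.p2) / 2, rel=1e-12)

    def test_table_matches_component_calls(self):
        net = random_network(seed=1)
        infs = enumerate_cd_inferences(net)
        table = score_table(net, infs)
        for i in range(0, len(infs), max(1, len(infs) // 17)):
            vec = score_inference(net, infs[i], n_tests=len(infs))
            row = table.iloc[i]
            assert row["c_xy"] == pytest.approx(vec.c_xy, rel=1e-12, abs=1e-12)
            assert row["p1"] == pytest.approx(vec.p1, rel=1e-12)
            assert row["p2"] == pytest.approx(vec.p2, rel=1e-12)
            assert row["w_xya"] == pytest.approx(vec.w_xya, rel=1e-12)
            assert row["w_bonferroni"] == pytest.approx(vec.w_bonferroni, rel=1e-12)

    def test_hub_gene_lowers_p2_and_w(self):
        # same network, two inferences differing in one connector: the
        # hub-containing gene set must score strictly lower on p2 and W
        net = TripartiteNetwork()
        for i in range(40):  # hub gene with many chemical partners
            net.add_edge(CHEM_GENE, f"filler{i}", "hub_gene")
        net.add_edge(CHEM_GENE, "A", "quiet_gene")
        net.add_edge(CHEM_GENE, "A", "shared_gene")
        net.add_edge(CHEM_GENE, "B", "hub_gene")
        net.add_edge(CHEM_GENE, "B", "shared_gene")
        net.add_edge(GENE_DISEASE, "quiet_gene", "Y")
        net.add_edge(GENE_DISEASE, "hub_gene", "Y")
        net.add_edge(GENE_DISEASE, "shared_gene", "Y")
        infs = {i.source.id: i for i in enumerate_cd_inferences(net)}
        vec_quiet = score_inference(net, infs["A"])
        vec_hub = score_inference(net, infs["B"])
        assert vec_hub.p2 < vec_quiet.p2
        assert vec_hub.w_xya < vec_quiet.w_xya

    def test_error_carries_inference_identity(self, toy_net):
        (inf,) = enumerate_cd_inferences(toy_net)
        with pytest.raises(ValueError, match="X - Y"):
            score_inference(toy_net, inf, n_override=2)  # N not above the degrees


class TestMonotonicityProperties:
    def test_more_shared_genes_more_surprising(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_x, n_y, m, N = random_sparse_inputs(rng)
            if m >= min(n_x, n_y):
                continue
            a = ScoreInputs(n_x, n_y, m, N)
            b = ScoreInputs(n_x, n_y, m + 1, N)
            assert c_xy(b) >= c_xy(a) - 1e-9
            assert p1_score(b) >= p1_score(a) - 1e-9

    def test_p2_strictly_decreasing_in_any_gene_degree(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            N = int(rng.integers(500, 40_000))
            m = int(rng.integers(1, 6))
            degs = [int(rng.integers(2, N // 10)) for _ in range(m)]
            j = int(rng.integers(0, m))
            bumped = list(degs)
            bumped[j] += int(rng.integers(1, 50))
            base = ScoreInputs(N // 3, N // 3, m, N, tuple(degs))
            more = ScoreInputs(N // 3, N // 3, m, N, tuple(bumped))
            assert p2_score(more) < p2_score(base)


class TestScoreInputsValidation:
    def test_m_exceeding_min_degree_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ScoreInputs(n_x=3, n_y=2, m=3, N=100)

    def test_n_not_above_degrees_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ScoreInputs(n_x=50, n_y=5, m=2, N=50)

    def test_gene_degree_count_must_match_m(self):
        with pytest.raises(ValueError):
            ScoreInputs(10, 10, 3, 1000, gene_degrees=(5, 5))
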