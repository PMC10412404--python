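"""Driver statistics against independent oracles and hand-worked examples."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import aledriver as ad
from aledriver.ranking import ea_ks, ea_sum_test, frequency_test, gene_rng


def ks_dplus_brute(obs, bg):
    """Brute-force sup_x [F_bg(x) - F_obs(x)] over all pooled points."""
    best = 0.0
    for x in set(obs) | set(bg):
        f_bg = sum(1 for v in bg if v <= x) / len(bg)
        f_obs = sum(1 for v in obs if v <= x) / len(obs)
        best = max(best, f_bg - f_obs)
    return best


def binom_tail_brute(k, n, p):
    """Exact upper-tail P(X >= k) by term-wise summation with math.comb."""
    return math.fsum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
                     for j in range(k, n + 1))


class TestEaKs:
    def test_complete_separation(self):
        d, p = ea_ks([100.0], [0.0])
        assert d == 1.0 and p < 1.0

    def test_identical_samples(self):
        d, p = ea_ks([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert d == 0.0 and p == 1.0

    def test_small_example_matches_brute_force(self):
        obs, bg = [90.0, 95.0], [10.0, 20.0, 30.0, 40.0]
        d, _ = ea_ks(obs, bg)
        assert d == pytest.approx(ks_dplus_brute(obs, bg), abs=1e-15)
        assert d == 1.0  # bg entirely below obs

    def test_shift_toward_low_ea_gives_zero_dplus(self):
        d, p = ea_ks([1.0, 2.0], [50.0, 60.0, 70.0])
        assert d == 0.0 and p == 1.0

    @pytest.mark.parametrize("case", range(25))
    def test_random_cases_match_brute_force_and_scipy(self, case):
        rng = np.random.default_rng(1000 + case)
        obs = rng.choice(np.round(rng.uniform(0, 100, 40), 1),
                         size=rng.integers(1, 30))
        bg = rng.choice(np.round(rng.uniform(0, 100, 40), 1),
                        size=rng.integers(2, 60))
        d, p = ea_ks(obs, bg)
        assert d == pytest.approx(ks_dplus_brute(list(obs), list(bg)),
                                  abs=1e-12)
        ref = stats.ks_2samp(bg, obs, alternative="greater", method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=30),
           st.lists(st.integers(0, 100), min_size=1, max_size=30))
    def test_dplus_bounds_oracle_and_shift_monotonicity(self, obs, bg):
        """0 <= D+ <= 1, matches brute force, and raising the observed EAs
        (a shift toward impact) never decreases D+."""
        d, p = ea_ks(np.array(obs, float), np.array(bg, float))
        assert 0.0 <= d <= 1.0 and 0.0 < p <= 1.0
        assert d == pytest.approx(ks_dplus_brute(obs, bg), abs=1e-12)
        d_up, _ = ea_ks(np.array(obs, float) + 1000.0, np.array(bg, float))
        assert d_up >= d - 1e-12

    def test_asymptotic_p_formula(self):
        obs, bg = [80.0, 90.0, 95.0], [10.0, 50.0, 60.0, 70.0, 75.0]
        d, p = ea_ks(obs, bg)
        m, n = len(bg), len(obs)
        assert p == pytest.approx(math.exp(-2 * d * d * m * n / (m + n)))


class TestEaSum:
    def test_unreachable_sum_gives_minimal_p(self):
        rng = np.random.default_rng(0)
        s, p = ea_sum_test([100.0, 100.0], [10.0, 20.0], n_mc=500, rng=rng)
        assert s == 200.0
        assert p == pytest.approx(1 / 501)

    def test_two_point_pool_is_bernoulli(self):
        """obs {50} vs pool {0,100}: P(draw >= 50) = 1/2 exactly."""
        n_mc = 4000
        rng = np.random.default_rng(42)
        _, p = ea_sum_test([50.0], [0.0, 100.0], n_mc=n_mc, rng=rng)
        sigma = math.sqrt(n_mc * 0.25) / n_mc
        assert abs(p - 0.5) < 3 * sigma + 1 / n_mc

    def test_deterministic_under_gene_rng(self):
        args = ([30.0, 60.0], np.arange(100.0), 1000)
        p1 = ea_sum_test(*args, rng=gene_rng(7, "geneA"))[1]
        p2 = ea_sum_test(*args, rng=gene_rng(7, "geneA"))[1]
        assert p1 == p2

    def test_monotone_in_added_max_ea_exact_two_point_pool(self):
        """Adding an EA=100 mutation never increases p (exact null on a
        two-point pool {a, 100}: the null sum is a scaled Binomial)."""
        def exact_p(obs_sum, n, a):
            # P(sum of n draws from {a,100} >= obs_sum), draws iid fair
            total = 0.0
            for k in range(n + 1):  # k draws of 100
                if k * 100 + (n - k) * a >= obs_sum - 1e-9:
                    total += math.comb(n, k) * 0.5 ** n
            return total
        for a in (0.0, 10.0, 40.0):
            for n in range(1, 8):
                for obs_sum in np.linspace(n * a, n * 100, 7):
                    assert (exact_p(obs_sum + 100, n + 1, a)
                            <= exact_p(obs_sum, n, a) + 1e-12)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            ea_sum_test([10.0], [], 100, np.random.default_rng(0))


class TestFrequency:
    def test_zero_count_gives_one(self):
        assert frequency_test(0, 300, 50, 30000) == 1.0

    def test_gene_covering_whole_genome(self):
        assert frequency_test(7, 30000, 10, 30000) == pytest.approx(1.0)

    def test_hand_example_tail_sum(self):
        # L_g/L_tot = 0.1, N = 10, n_g = 5
        expected = binom_tail_brute(5, 10, 0.1)
        assert frequency_test(5, 100, 10, 1000) == pytest.approx(expected,
                                                                 rel=1e-12)

    @pytest.mark.parametrize("case", range(20))
    def test_random_cases_match_term_summation(self, case):
        rng = np.random.default_rng(500 + case)
        n_total = int(rng.integers(1, 500))
        length, total = int(rng.integers(30, 2000)), 30000
        k = int(rng.integers(0, min(n_total, 40) + 1))
        p = frequency_test(k, length, n_total, total)
        assert p == pytest.approx(binom_tail_brute(k, n_total, length / total),
                                  rel=1e-9)


class TestRanking:
    @pytest.fixture()
    def frame(self):
        return pd.DataFrame({
            "locus_tag": ["g1", "g2", "g3", "g4"],
            "n_mut": [5, 4, 3, 2],
            "sum_ea": [400.0, 300.0, 200.0, 100.0],
            "p_ks": [0.01, 0.02, 0.03, 0.04],
            "p_sum": [0.02, 0.02, 0.02, 0.02],
            "p_freq": [0.5, 0.5, 0.5, 0.5],
            "tested_ks": True, "tested_sum": True, "tested_freq": True,
        })

    def test_rank_by_ascending_p(self, frame):
        ad.rank_genes(frame, "ks")
        assert frame.rank_ks.tolist() == [1, 2, 3, 4]

    def test_bh_step_up_hand_computed(self, frame):
        # p = (.01,.02,.03,.04) over 4 genes -> q all .04
        ad.rank_genes(frame, "ks")
        assert frame.q_ks.tolist() == pytest.approx([0.04] * 4)

    def test_tie_break_by_sum_ea_then_tag(self, frame):
        ad.rank_genes(frame, "sum")
        assert frame.rank_sum.tolist() == [1, 2, 3, 4]

    def test_tie_break_by_count_for_frequency(self, frame):
        frame.loc[:, "n_mut"] = [1, 9, 9, 1]
        ad.rank_genes(frame, "freq")
        assert frame.rank_freq.tolist() == [3, 1, 2, 4]


class TestPipeline:
    def test_results_shape_and_invariants(self, small_bundle):
        genome, table, bg = (small_bundle[k] for k in ("genome", "table",
                                                       "bg"))
        fx = small_bundle["fixture"]
        effects = []
        for strain, path in fx.vcf_paths.items():
            effects += ad.annotate(ad.read_vcf(path, strain), genome, table)
        res = ad.rank_drivers(genome, effects, bg,
                              ad.RankingConfig(n_mc=500, seed=1))
        n = len(genome.genes)
        assert len(res) == n
        for m in ("ks", "sum", "freq"):
            assert sorted(res[f"rank_{m}"]) == list(range(1, n + 1))
            assert ((res[f"p_{m}"] > 0) & (res[f"p_{m}"] <= 1)).all()
            tested = res[res[f"tested_{m}"]]
            # q monotone non-decreasing in p order
            q = tested.sort_values(f"p_{m}")[f"q_{m}"].to_numpy()
            assert (np.diff(q) >= -1e-12).all()
        assert ((res.sum_ea == 0) == (res.n_missense_scored == 0)).all()
        assert (res.sum_ea >= 0).all()

    def test_gene_results_independent_of_input_order(self, small_bundle):
        genome, table, bg = (small_bundle[k] for k in ("genome", "table",
                                                       "bg"))
        fx = small_bundle["fixture"]
        effects = []
        for strain, path in fx.vcf_paths.items():
            effects += ad.annotate(ad.read_vcf(path, strain), genome, table)
        cfg = ad.RankingConfig(n_mc=500, seed=4)
        a = ad.rank_drivers(genome, effects, bg, cfg)
        b = ad.rank_drivers(genome, list(reversed(effects)), bg, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_seeded_driver_gene_found(self, small_bundle):
        genome, table, bg = (small_bundle[k] for k in ("genome", "table",
                                                       "bg"))
        fx = small_bundle["fixture"]
        effects = ad.effects_from_substitutions(
            ad.read_substitutions(fx.substitutions_path), genome, table)
        res = ad.rank_drivers(genome, effects, bg,
                              ad.RankingConfig(n_mc=2000, seed=2))
        row = res[res.locus_tag == "ALE_0005"].iloc[0]
        assert row.rank_sum <= 2 and row.rank_ks <= 2
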