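import numpy as np
import pandas as pd
import pytest

from ydna.core import make_sample_table
from ydna.popstats import (
    amova,
    diversity,
    matrix_extremes,
    mds,
    mean_pairwise_differences,
    pairwise_differences,
    pairwise_phist,
    segregating_sites,
    tajimas_d,
    tajimas_d_from_summary,
    tajimas_d_pvalue,
)
from ydna.published import pairwise_phist_matrix
from ydna.simulate import simulate_growth_coalescent, simulate_structured_regions

from conftest import mk_matrix


# --- independent oracle: Tajima's D from the published constants, written
# without reference to the implementation ------------------------------------

def oracle_tajimas_d(calls: np.ndarray) -> float:
    n, m = calls.shape
    seg = [j for j in range(m) if 0 < calls[:, j].sum() < n]
    s = len(seg)
    if s == 0:
        return float("nan")
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((calls[i] != calls[j]).sum())
            pairs += 1
    k_hat = total / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


class TestDiversity:
    def test_two_haplotypes_three_differences(self):
        calls = np.zeros((2, 3), dtype=np.int8)
        calls[1] = 1
        d = diversity(mk_matrix(calls), l_retained=100)
        assert d.s == 3
        assert d.mpd == pytest.approx(3.0)
        assert d.pi == pytest.approx(0.03)

    def test_identical_haplotypes_zero_diversity(self):
        d = diversity(mk_matrix([[1, 0]] * 4), l_retained=100)
        assert (d.s, d.mpd, d.pi) == (0, 0.0, 0.0)

    def test_printed_mpd_implies_printed_pi(self):
        # Andalusia: MPD 62.78 over 8.9 Mb -> pi x 1000 = 0.0071 (2 s.f.)
        assert 62.78 / 8.9e6 * 1000 == pytest.approx(0.0071, abs=5e-5)

    def test_pi_times_length_equals_mpd_identity(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            m, _ = simulate_growth_coalescent(8, 6.0, 0.0, seed=seed)
            if m.n_snps == 0:
                continue
            d = diversity(m, l_retained=12_345)
            assert d.pi * 12_345 == pytest.approx(d.mpd, abs=1e-12)
        del rng


class TestTajimasD:
    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            m = int(rng.integers(2, 25))
            calls = (rng.random((n, m)) < rng.uniform(0.05, 0.6)).astype(np.int8)
            expected = oracle_tajimas_d(calls)
            if np.isnan(expected):
                continue
            got = tajimas_d(mk_matrix(calls))
            assert got == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked > 500

    def test_zero_when_mpd_equals_watterson_theta(self):
        n, s = 10, 16
        a1 = sum(1.0 / i for i in range(1, n))
        assert tajimas_d_from_summary(n, s, s / a1) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert np.isnan(tajimas_d_from_summary(10, 0, 0.0))

    def test_strong_growth_simulations_strongly_negative(self):
        d_vals = []
        for s in range(300):
            m, _ = simulate_growth_coalescent(30, 500.0, 200.0, seed=s)
            if m.n_snps:
                d_vals.append(tajimas_d(m))
        assert np.mean(d_vals) < -1.5


class TestTajimaPvalue:
    def test_unreachably_positive_d_gives_p_near_one(self):
        # two balanced clusters -> strongly positive D
        calls = np.zeros((10, 20), dtype=np.int8)
        calls[5:, :] = 1
        m = mk_matrix(calls)
        assert tajimas_d(m) > 2
        p = tajimas_d_pvalue(m, n_sims=2000, seed=0)
        assert p > 0.99

    def test_same_seed_identical_p(self):
        m, _ = simulate_growth_coalescent(10, 5.0, 0.0, seed=3)
        p1 = tajimas_d_pvalue(m, n_sims=500, seed=9)
        p2 = tajimas_d_pvalue(m, n_sims=500, seed=9)
        assert p1 == p2

    def test_null_calibration_uniform(self):
        """Under neutral constant-size data the p-value is ~Uniform(0,1)."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(200):
            m, _ = simulate_growth_coalescent(10, 5.0, 0.0, seed=seed + 10_000)
            if m.n_snps < 1:
                continue
            pvals.append(tajimas_d_pvalue(m, n_sims=500, seed=seed))
        stat, p = kstest(pvals, "uniform")
        assert p > 0.001


# --- AMOVA oracle: direct sums-of-squared-distances decomposition ------------

def oracle_amova(calls: np.ndarray, labels: list[str]):
    n = len(labels)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = (calls[i] != calls[j]).sum()
    groups = sorted(set(labels))
    k = len(groups)
    ssd_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssd_within = 0.0
    sizes = []
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        sizes.append(len(idx))
        ssd_within += sum(
            d2[a, b] for ai, a in enumerate(idx) for b in idx[ai + 1:]
        ) / len(idx)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n - k)
    n_prime = (n - sum(s**2 for s in sizes) / n) / (k - 1)
    sigma_a = (ssd_among / (k - 1) - sigma_w) / n_prime
    return sigma_a, sigma_w


class TestAmova:
    def test_identical_regions_give_phist_at_most_zero(self):
        calls = np.tile(np.eye(4, 12, dtype=np.int8), (2, 1))
        m = mk_matrix(calls)
        labels = ["A"] * 4 + ["B"] * 4
        res = amova(m, labels, n_permutations=0)
        assert res.phi_st <= 0.0 + 1e-12

    def test_fixed_differences_give_phist_one(self):
        calls = np.zeros((6, 10), dtype=np.int8)
        calls[3:, :] = 1
        res = amova(mk_matrix(calls), ["A"] * 3 + ["B"] * 3, n_permutations=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_three_region_toy_matches_brute_force_oracle(self):
        calls = np.array(
            [
                [1, 0, 0, 0, 1, 0],
                [1, 1, 0, 0, 0, 0],
                [1, 0, 1, 0, 0, 0],
                [0, 0, 0, 1, 1, 0],
                [0, 1, 0, 1, 0, 0],
                [0, 0, 0, 1, 0, 1],
                [0, 0, 1, 0, 1, 1],
                [0, 1, 1, 0, 0, 1],
                [0, 0, 1, 1, 0, 1],
            ],
            dtype=np.int8,
        )
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = amova(mk_matrix(calls), labels, n_permutations=0)
        sa, sw = oracle_amova(calls, labels)
        assert res.sigma2_among == pytest.approx(sa, abs=1e-9)
        assert res.sigma2_within == pytest.approx(sw, abs=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_invariant_to_region_relabeling_and_within_permutation(self):
        rng = np.random.default_rng(5)
        calls = (rng.random((12, 30)) < 0.3).astype(np.int8)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        m = mk_matrix(calls)
        res1 = amova(m, labels, n_permutations=0)
        relabel = {"A": "X", "B": "Y", "C": "Z"}
        res2 = amova(m, [relabel[l] for l in labels], n_permutations=0)
        assert res1.phi_st == pytest.approx(res2.phi_st)
        # permute samples within regions
        perm = np.concatenate(
            [rng.permutation(range(4)), 4 + rng.permutation(range(4)), 8 + rng.permutation(range(4))]
        )
        res3 = amova(m.subset_samples(perm), labels, n_permutations=0)
        assert res1.phi_st == pytest.approx(res3.phi_st)

    def test_small_group_excluded(self):
        calls = np.zeros((5, 4), dtype=np.int8)
        calls[0:2, 0] = 1
        calls[2:4, 1] = 1
        res = amova(mk_matrix(calls), ["A", "A", "B", "B", "C"], n_permutations=0)
        assert res.df_among == 1  # C (n=1) dropped


class TestPairwisePhist:
    def test_random_split_of_one_region_near_zero(self):
        rng = np.random.default_rng(7)
        calls = (rng.random((16, 60)) < 0.25).astype(np.int8)
        phist = pairwise_phist(mk_matrix(calls), ["A"] * 8 + ["B"] * 8)
        assert abs(phist.loc["A", "B"]) < 0.05

    def test_fixed_pair_is_one(self):
        calls = np.zeros((6, 8), dtype=np.int8)
        calls[3:, :] = 1
        phist = pairwise_phist(mk_matrix(calls), ["A"] * 3 + ["B"] * 3)
        assert phist.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetry_and_zero_diagonal(self, rate):
        m, meta, _ = simulate_structured_regions(6, 3, 1000, 3000, rate, seed=1)
        phist = pairwise_phist(m, list(meta["region"]))
        assert np.allclose(phist, phist.T)
        assert np.allclose(np.diag(phist), 0.0)

    def test_planted_phist_recovered_on_average(self, rate):
        """Two-level star with divergence 500 / within 5000 years: the mean
        estimate must track the AMOVA-oracle expectation (~ T_d/(T_d+T_w))."""
        target = 500 / 5500
        vals = []
        for seed in range(60):
            m, meta, _ = simulate_structured_regions(
                25, 4, 500, 5000, rate, seed=seed
            )
            res = amova(m, list(meta["region"]), n_permutations=0)
            vals.append(res.phi_st)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        # finite-sample AMOVA expectation is slightly below the infinite-n
        # ratio; require agreement within 3 SE of the simulated mean
        assert abs(np.mean(vals) - target) < max(3 * se, 0.01)


class TestMds:
    def test_exact_planar_distances_zero_stress(self):
        pts = np.array([[0, 0], [2, 0], [0, 1], [3, 4]], float)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        df = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        res = mds(df, k=2)
        assert res.stress_pct < 1e-8
        assert np.allclose(res.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_equilateral_triangle_zero_stress(self):
        d = np.ones((3, 3)) - np.eye(3)
        df = pd.DataFrame(d, index=list("abc"), columns=list("abc"))
        assert mds(df, k=2).stress_pct < 1e-8

    def test_published_phist_matrix_stress_near_one_percent(self):
        res = mds(pairwise_phist_matrix(), k=2)
        assert res.stress_pct == pytest.approx(1.1, abs=0.5)

    def test_k_must_be_smaller_than_matrix(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            mds(d, k=3)


class TestMatrixExtremes:
    def test_published_matrix_max_is_basque_catalonia(self):
        ext = matrix_extremes(pairwise_phist_matrix())
        assert ext["max"] == pytest.approx(0.03741)
        assert set(ext["max_pairs"][0]) == {"Basque Country", "Catalonia"}

    def test_all_equal_matrix_reports_all_pairs_tied(self):
        d = pd.DataFrame(
            0.5 * (np.ones((3, 3)) - np.eye(3)), index=list("abc"), columns=list("abc")
        )
        ext = matrix_extremes(d)
        assert len(ext["max_pairs"]) == 3
        assert ext["max"] == ext["min"]

    def test_two_by_two_single_pair_is_both(self):
        d = pd.DataFrame(
            [[0.0, 0.2], [0.2, 0.0]], index=["x", "y"], columns=["x", "y"]
        )
        ext = matrix_extremes(d)
        assert ext["max_pairs"] == ext["min_pairs"] == [("x", "y")]


def test_segregating_sites_and_mpd_consistency():
    rng = np.random.default_rng(11)
    calls = (rng.random((7, 40)) < 0.3).astype(np.int8)
    m = mk_matrix(calls)
    d = pairwise_differences(m)
    iu = np.triu_indices(7, 1)
    assert mean_pairwise_differences(m) == pytest.approx(d[iu].mean())
    assert segregating_sites(m) == sum(
        1 for j in range(40) if 0 < calls[:, j].sum() < 7
    )
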