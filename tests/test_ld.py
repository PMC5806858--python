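"""EM haplotype frequencies, r², windowed scan, binning, decay regression."""

import numpy as np
import pandas as pd
import pytest

from chickld.genotype_io import MISSING
from chickld.ld import (
    BinnedLD,
    HaplotypeFrequencies,
    bin_ld_by_distance,
    composite_r2,
    decay_regression,
    em_haplotype_frequencies,
    em_log_likelihood,
    ld_profile_correlation,
    ld_r2,
    pairwise_ld_scan,
    two_locus_counts,
)

from conftest import make_dataset, random_dataset


def grid_search_max_loglik(counts: np.ndarray, step: float = 0.01) -> float:
    """Best multinomial log-likelihood over the haplotype-frequency simplex
    discretised at ``step`` — a brute-force oracle independent of the EM."""
    k = int(round(1 / step))
    vals = np.arange(k + 1) / k
    i, j, l = np.meshgrid(np.arange(k + 1), np.arange(k + 1), np.arange(k + 1), indexing="ij")
    keep = (i + j + l) <= k
    p11, p12, p21 = vals[i[keep]], vals[j[keep]], vals[l[keep]]
    p22 = 1.0 - p11 - p12 - p21
    g = {
        (2, 2): p11**2,
        (2, 1): 2 * p11 * p12,
        (2, 0): p12**2,
        (1, 2): 2 * p11 * p21,
        (1, 1): 2 * p11 * p22 + 2 * p12 * p21,
        (1, 0): 2 * p12 * p22,
        (0, 2): p21**2,
        (0, 1): 2 * p21 * p22,
        (0, 0): p22**2,
    }
    ll = np.zeros(p11.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for (ga, gb), prob in g.items():
            n = counts[ga, gb]
            if n > 0:
                ll = ll + n * np.log(prob)
    ll[np.isnan(ll)] = -np.inf
    return float(ll.max())


def random_table(rng: np.random.Generator, n: int = 50) -> np.ndarray:
    """Genotype-pair table sampled from random haplotype frequencies."""
    p = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
    haps = rng.choice(4, size=(n, 2), p=p)
    ga = (haps < 2).sum(axis=1)  # haplotypes 0,1 carry A1
    gb = ((haps == 0) | (haps == 2)).sum(axis=1)  # haplotypes 0,2 carry B1
    t = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(ga, gb):
        t[a, b] += 1
    return t


class TestEM:
    def test_no_double_heterozygotes_closed_form(self):
        """Without the (1,1) class all haplotypes are determinate."""
        t = np.zeros((3, 3), dtype=int)
        t[2, 2] = 3  # 6 × A1B1
        t[0, 0] = 2  # 4 × A2B2
        t[2, 0] = 1  # 2 × A1B2
        h = em_haplotype_frequencies(t)
        assert h.n_iter == 0
        assert h.as_array() == pytest.approx([6 / 12, 2 / 12, 0, 4 / 12])

    def test_perfect_coupling(self):
        t = np.zeros((3, 3), dtype=int)
        t[2, 2] = 5
        t[0, 0] = 5
        h = em_haplotype_frequencies(t)
        assert h.p11 == pytest.approx(0.5)
        assert h.p22 == pytest.approx(0.5)
        assert h.d == pytest.approx(0.25)
        assert ld_r2(h) == pytest.approx(1.0)

    def test_likelihood_beats_grid_oracle(self):
        """EM fixed point is the MLE: log-likelihood ≥ a 101³ grid search."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            t = random_table(rng)
            h = em_haplotype_frequencies(t)
            assert em_log_likelihood(t, h.as_array()) >= grid_search_max_loglik(t) - 1e-6

    def test_log_likelihood_nondecreasing_across_iterations(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            t = random_table(rng)
            if t[1, 1] == 0:
                continue
            # re-run the E/M steps manually, tracking the likelihood
            h = em_haplotype_frequencies(t, max_iter=0)
            prev = em_log_likelihood(t, h.as_array())
            for it in range(1, 30):
                h = em_haplotype_frequencies(t, max_iter=it)
                cur = em_log_likelihood(t, h.as_array())
                assert cur >= prev - 1e-10
                prev = cur

    def test_marginals_reproduce_allele_frequencies(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n=40)
        h = em_haplotype_frequencies(t)
        n_called = t.sum()
        freq_a1 = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * n_called)
        freq_b1 = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n_called)
        assert h.freq_a1 == pytest.approx(freq_a1, abs=1e-7)
        assert h.freq_b1 == pytest.approx(freq_b1, abs=1e-7)
        assert h.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_double_heterozygote_table_stays_at_equilibrium(self):
        t = np.zeros((3, 3), dtype=int)
        t[1, 1] = 10
        h = em_haplotype_frequencies(t)
        assert ld_r2(h) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        t = np.zeros((3, 3), dtype=int)
        t[1, 1] = 1
        with pytest.raises(ValueError):
            em_haplotype_frequencies(t)


class TestR2:
    def test_equilibrium_zero(self):
        assert ld_r2(HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)) == pytest.approx(0.0)

    def test_complete_association(self):
        assert ld_r2(HaplotypeFrequencies(0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        """D = 0.4·0.4 − 0.1·0.1 = 0.15; r² = 0.0225/0.0625 = 0.36."""
        h = HaplotypeFrequencies(0.4, 0.1, 0.1, 0.4)
        assert h.d == pytest.approx(0.15)
        assert ld_r2(h) == pytest.approx(0.36)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld_r2(HaplotypeFrequencies(0.5, 0.5, 0.0, 0.0)))

    def test_invariant_under_allele_relabeling_and_locus_swap(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(30, 2, seed=12)
        a, b = ds.calls[:, 0], ds.calls[:, 1]
        base = ld_r2(em_haplotype_frequencies(two_locus_counts(a, b)))
        flip_a = ld_r2(em_haplotype_frequencies(two_locus_counts(2 - a, b)))
        flip_b = ld_r2(em_haplotype_frequencies(two_locus_counts(a, 2 - b)))
        swapped = ld_r2(em_haplotype_frequencies(two_locus_counts(b, a)))
        assert flip_a == pytest.approx(base, abs=1e-9)
        assert flip_b == pytest.approx(base, abs=1e-9)
        assert swapped == pytest.approx(base, abs=1e-9)

    def test_em_equals_direct_count_on_phased_equivalent_data(self):
        """With no double heterozygotes, EM r² equals haplotype-count r²."""
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, size=(40, 2))  # hap alleles at loci A,B
        # build diploids from haplotype pairs avoiding double hets
        a = haps[0::2, 0] + haps[1::2, 0]
        b = haps[0::2, 1] + haps[1::2, 1]
        dh = (a == 1) & (b == 1)
        a, b = a[~dh].astype(np.int8), b[~dh].astype(np.int8)
        t = two_locus_counts(a, b)
        h = em_haplotype_frequencies(t)
        assert h.n_iter == 0  # no latent data: closed form
        # direct haplotype-count oracle from the determinate classes
        c11 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
        c12 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
        c21 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
        c22 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
        tot = c11 + c12 + c21 + c22
        assert h.as_array() == pytest.approx(np.array([c11, c12, c21, c22]) / tot)


class TestPairwiseScan:
    def test_single_variant_empty(self):
        ds = make_dataset(np.array([[1], [2]]))
        assert len(pairwise_ld_scan(ds)) == 0

    def test_distance_window_arithmetic(self):
        ds = make_dataset(
            np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (1, 3)),
            bps=[1, 500_000, 2_000_000],
        )
        pairs = pairwise_ld_scan(ds, max_dist_bp=1_000_000)
        got = {(r.i, r.j) for r in pairs.itertuples()}
        assert got == {(0, 1)}  # (0,2) is 2 Mb apart; (1,2) is 1.5 Mb
        ds2 = make_dataset(
            np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (1, 3)),
            bps=[1, 500_000, 1_400_000],
        )
        got2 = {(r.i, r.j) for r in pairwise_ld_scan(ds2, max_dist_bp=1_000_000).itertuples()}
        assert got2 == {(0, 1), (1, 2)}

    def test_matches_brute_force_oracle(self):
        ds = random_dataset(25, 80, seed=21, missing_rate=0.05, n_chromosomes=2)
        pairs = pairwise_ld_scan(ds, max_dist_bp=5_000)
        # brute force: every same-chromosome pair, scalar EM
        expected = {}
        chroms = ds.variants["chrom"].to_numpy()
        bps = ds.variants["bp"].to_numpy()
        for i in range(ds.n_variants):
            for j in range(i + 1, ds.n_variants):
                if chroms[i] != chroms[j] or abs(int(bps[j]) - int(bps[i])) > 5_000:
                    continue
                t = two_locus_counts(ds.calls[:, i], ds.calls[:, j])
                expected[(i, j)] = ld_r2(em_haplotype_frequencies(t))
        got = {(r.i, r.j): r.r2 for r in pairs.itertuples()}
        assert set(got) == set(expected)
        for key, r2 in expected.items():
            if np.isnan(r2):
                assert np.isnan(got[key])
            else:
                assert got[key] == pytest.approx(r2, abs=1e-6)

    def test_each_pair_exactly_once(self):
        ds = random_dataset(10, 40, seed=5)
        pairs = pairwise_ld_scan(ds, max_dist_bp=10**9)
        assert len(pairs) == len(set(zip(pairs["i"], pairs["j"])))
        assert (pairs["j"] > pairs["i"]).all()


class TestBinning:
    def test_single_distance_all_windows_equal(self):
        pairs = pd.DataFrame({"dist_bp": [10_000] * 5, "r2": [0.2, 0.4, 0.6, 0.3, 0.5]})
        b = bin_ld_by_distance(pairs)
        means = b.table["mean_r2"]
        assert means.nunique() == 1
        assert means.iloc[0] == pytest.approx(0.4)

    def test_two_point_cumulative_means(self):
        pairs = pd.DataFrame({"dist_bp": [10_000, 600_000], "r2": [0.4, 0.1]})
        b = bin_ld_by_distance(pairs, mode="cumulative")
        t = b.table.set_index("window_kb")["mean_r2"]
        assert t[20.0] == pytest.approx(0.4)
        assert t[1000.0] == pytest.approx(0.25)

    def test_disjoint_mode(self):
        pairs = pd.DataFrame({"dist_bp": [10_000, 600_000], "r2": [0.4, 0.1]})
        b = bin_ld_by_distance(pairs, mode="disjoint")
        t = b.table.set_index("window_kb")["mean_r2"]
        assert t[20.0] == pytest.approx(0.4)
        assert t[1000.0] == pytest.approx(0.1)
        assert np.isnan(t[100.0])  # empty window → missing

    def test_first_window_identical_under_both_modes(self):
        rng = np.random.default_rng(6)
        pairs = pd.DataFrame(
            {"dist_bp": rng.integers(1, 10**6, 500), "r2": rng.random(500)}
        )
        cum = bin_ld_by_distance(pairs, mode="cumulative").table.iloc[0]["mean_r2"]
        dis = bin_ld_by_distance(pairs, mode="disjoint").table.iloc[0]["mean_r2"]
        assert cum == pytest.approx(dis)

    def test_average_is_unweighted_window_mean(self):
        pairs = pd.DataFrame({"dist_bp": [10_000, 600_000], "r2": [0.4, 0.1]})
        b = bin_ld_by_distance(pairs)
        assert b.average == pytest.approx(np.nanmean(b.table["mean_r2"]))


class TestDecayRegression:
    def test_perfectly_linear(self):
        pairs = pd.DataFrame({"dist_bp": [0, 100, 200, 300], "r2": [0.8, 0.6, 0.4, 0.2]})
        fit = decay_regression(pairs)
        assert fit.slope == pytest.approx(-0.002)
        assert fit.intercept == pytest.approx(0.8)

    def test_constant_r2_zero_slope(self):
        pairs = pd.DataFrame({"dist_bp": [0, 100, 200], "r2": [0.3, 0.3, 0.3]})
        assert decay_regression(pairs).slope == pytest.approx(0.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 10**6, 200).astype(float)
        y = rng.random(200)
        pairs = pd.DataFrame({"dist_bp": x, "r2": y})
        fit = decay_regression(pairs)
        # closed-form OLS
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_degenerate_design_rejected(self):
        pairs = pd.DataFrame({"dist_bp": [5, 5], "r2": [0.1, 0.2]})
        with pytest.raises(ValueError):
            decay_regression(pairs)


class TestProfileCorrelation:
    def test_identical_profiles(self):
        p = np.array([0.5, 0.4, 0.3, 0.2])
        assert ld_profile_correlation(p, p) == pytest.approx(1.0)

    def test_reversed_affine_profile(self):
        p = np.array([0.5, 0.4, 0.3, 0.2])
        assert ld_profile_correlation(p, -2 * p + 1) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        a, b = rng.random(8), rng.random(8)
        expected = (((a - a.mean()) * (b - b.mean())).sum()
                    / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()))
        assert ld_profile_correlation(a, b) == pytest.approx(expected)

    def test_zero_variance_undefined(self):
        assert np.isnan(ld_profile_correlation(np.ones(4), np.arange(4.0)))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ld_profile_correlation(np.ones(4), np.ones(5))


def test_composite_r2_close_to_em_under_hwe():
    ds = random_dataset(200, 2, seed=30)
    em = ld_r2(em_haplotype_frequencies(two_locus_counts(ds.calls[:, 0], ds.calls[:, 1])))
    comp = composite_r2(ds.calls[:, 0], ds.calls[:, 1])
    assert comp == pytest.approx(em, abs=0.05)
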