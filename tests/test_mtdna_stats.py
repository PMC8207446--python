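import itertools
import math

import numpy as np
import pytest

from phylopop.io_formats import Alignment, PopulationMap
from phylopop import mtdna_stats as mt


def _aln(seqs, prefix="s"):
    ids = tuple(f"{prefix}{i}" for i in range(len(seqs)))
    return Alignment(ids, tuple(seqs)), ids


class TestCollapseHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        aln, ids = _aln(["ACGT"] * 4)
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        ht = mt.collapse_haplotypes(aln, pm)
        assert ht.n_haplotypes == 1
        assert ht.variable_sites == ()
        assert ht.counts.sum() == 4

    def test_two_haplotypes_hand_enumeration(self):
        aln, ids = _aln(["AAA", "AAT", "AAT"])
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        ht = mt.collapse_haplotypes(aln, pm)
        assert ht.n_haplotypes == 2
        assert ht.variable_sites == (3,)
        assert sorted(ht.counts[0].tolist()) == [1, 2]

    def test_per_population_counts(self, toy_alignment, toy_popmap):
        ht = mt.collapse_haplotypes(toy_alignment, toy_popmap)
        assert ht.n_haplotypes == 2
        assert ht.counts.tolist() == [[2, 0], [0, 2]]

    def test_high_missing_sample_excluded(self):
        aln, ids = _aln(["ACGTACGTAC", "ACGTACGTAC", "NNNNNNACGT"])
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        ht = mt.collapse_haplotypes(aln, pm, max_missing_frac=0.1)
        assert len(ht.sample_ids) == 2


class TestDiversity:
    def test_monomorphic(self):
        aln, ids = _aln(["ACGT"] * 5)
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        s = mt.diversity_summary(aln, pm).per_population["P"]
        assert s.h == pytest.approx(0.0)
        assert s.pi == pytest.approx(0.0)
        assert s.S == 0

    def test_two_samples_one_difference(self):
        # h = (n/(n-1))(1 - sum p^2) = 2 * (1 - 0.5) = 1; pi = 1/10 per site
        aln, ids = _aln(["AAAAAAAAAA", "AAAAAAAAAT"])
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        s = mt.diversity_summary(aln, pm).per_population["P"]
        assert s.h == pytest.approx(1.0)
        assert s.pi == pytest.approx(0.1)

    def test_haplotype_diversity_hand_formula(self):
        # counts (2,1): n=3, sum p^2 = 5/9, h = 1.5 * 4/9 = 2/3
        h, sd = mt.haplotype_diversity([2, 1])
        assert h == pytest.approx(2.0 / 3.0)
        assert sd > 0

    def test_single_sample_population_flagged(self):
        aln, _ = _aln(["ACGT", "ACGT", "AGGT"], prefix="x")
        pm = PopulationMap.from_pairs([("x0", "P"), ("x1", "P"), ("x2", "Q")])
        s = mt.diversity_summary(aln, pm)
        assert math.isnan(s.per_population["Q"].h)

    def test_pi_pairwise_equals_site_formula(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(8, 40))
        n, L = codes.shape
        pi_pair = mt.mean_pairwise_differences(codes, per_site=True)
        # oracle: per-site heterozygosity sum over distinct pairs
        tot = 0.0
        for j in range(L):
            counts = np.bincount(codes[:, j], minlength=4)
            tot += (n * n - np.sum(counts**2)) / 2.0
        pi_site = tot / (n * (n - 1) / 2) / L
        assert pi_pair == pytest.approx(pi_site, abs=1e-12)

    def test_invariance_under_reordering(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, size=(6, 30))
        perm = rng.permutation(6)
        colperm = rng.permutation(30)
        a = mt.mean_pairwise_differences(codes)
        b = mt.mean_pairwise_differences(codes[perm][:, colperm])
        assert a == pytest.approx(b, abs=1e-12)


def _tajima_d_oracle(S, pi, n):
    """Independent implementation straight from the published constants."""
    if S == 0:
        return 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return (pi - S / a1) / math.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))


class TestNeutrality:
    def test_monomorphic_d_zero(self):
        aln, ids = _aln(["ACGT"] * 6)
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        s = mt.neutrality_tests(aln, pm, n_sim=50, rng_seed=1).per_population["P"]
        assert s.tajima_d == 0.0
        assert s.tajima_d_p == 1.0
        assert s.fu_fs == 0.0

    @pytest.mark.parametrize("S,pi,n", [(5, 3.2, 10), (12, 6.0, 25), (1, 0.4, 4)])
    def test_tajima_d_matches_oracle(self, S, pi, n):
        assert mt.tajima_d(S, pi, n) == pytest.approx(_tajima_d_oracle(S, pi, n), abs=1e-12)

    def test_ewens_distribution_matches_polynomial_oracle(self):
        # |s(n,k)| are the coefficients of theta(theta+1)...(theta+n-1)
        n, theta = 6, 1.7
        poly = np.array([1.0])
        for i in range(n):
            poly = np.convolve(poly, [1.0, float(i)])  # multiply by (theta + i)
        coeffs = poly[::-1]  # coeffs[k] is the theta^k coefficient
        rising = math.prod(theta + i for i in range(n))
        expected = np.array([coeffs[k] * theta**k / rising for k in range(1, n + 1)])
        got = mt.ewens_k_distribution(n, theta)
        assert np.allclose(got, expected, atol=1e-12)

    def test_fu_fs_sign_convention(self):
        # many haplotypes for modest theta -> S' small -> Fs negative
        assert mt.fu_fs(k_obs=8, theta=1.0, n=10) < 0
        # few haplotypes for large theta -> Fs positive
        assert mt.fu_fs(k_obs=2, theta=8.0, n=10) > 0

    def test_neutral_mean_d_near_zero(self):
        rng = np.random.default_rng(42)
        d, _ = mt._simulate_neutral_replicates(10, 5.0, 500, rng)
        assert -0.3 < d.mean() < 0.3

    def test_pvalues_reproducible(self):
        aln, ids = _aln(["AAAAAAAA", "AAAAAAAT", "AAAAATAT", "ATAAATAT", "AAAAAAAA"])
        pm = PopulationMap.from_pairs([(i, "P") for i in ids])
        a = mt.neutrality_tests(aln, pm, n_sim=200, rng_seed=9).per_population["P"]
        b = mt.neutrality_tests(aln, pm, n_sim=200, rng_seed=9).per_population["P"]
        assert a.tajima_d_p == b.tajima_d_p
        assert a.fu_fs_p == b.fu_fs_p


def _tamura_gamma_oracle(P, Q, gc, a):
    """Second implementation typed directly from the published formula."""
    h = 2 * gc * (1 - gc)
    c1 = 1 - P / h - Q
    c2 = 1 - 2 * Q
    return a * (h * (c1 ** (-1 / a) - 1) + 0.5 * (1 - h) * (c2 ** (-1 / a) - 1))


class TestTamura:
    def test_identical_pair_zero(self):
        aln, _ = _aln(["ACGTACGT", "ACGTACGT"])
        d = mt.tamura_gamma_distance(aln, 0.5)
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_matches_independent_formula(self):
        # L=100, GC fraction 0.5 in both sequences, one transition + one transversion
        s1 = "AG" * 25 + "CT" * 25
        s2 = "GG" + "AG" * 24 + "CA" + "CT" * 24  # A->G transition, T->A transversion
        aln, _ = _aln([s1, s2])
        codes = aln.to_codes()
        both = (codes[0] >= 0) & (codes[1] >= 0)
        assert both.sum() == 100
        got = mt.tamura_gamma_distance(aln, 0.5).matrix[0, 1]
        gc = (np.isin(codes[0], [1, 2]).mean() + np.isin(codes[1], [1, 2]).mean()) / 2
        expected = _tamura_gamma_oracle(P=0.01, Q=0.01, gc=gc, a=0.5)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_gamma_limit_equals_plain_tamura(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 4, size=400)
        mutant = base.copy()
        sites = rng.choice(400, size=30, replace=False)
        mutant[sites] = (mutant[sites] + rng.integers(1, 4, size=30)) % 4
        aln = Alignment(
            ("x", "y"),
            tuple("".join("ACGT"[c] for c in row) for row in (base, mutant)),
        )
        big = mt.tamura_gamma_distance(aln, 1e6).matrix[0, 1]
        plain = mt.tamura_gamma_distance(aln, None).matrix[0, 1]
        assert big == pytest.approx(plain, abs=1e-6)

    def test_saturated_pair_nan(self):
        aln, _ = _aln(["ACAC", "CACA"])  # all transversions: Q = 1
        with pytest.warns(UserWarning, match="saturated"):
            d = mt.tamura_gamma_distance(aln, 0.5)
        assert math.isnan(d.matrix[0, 1])


class TestAmova:
    def test_fixed_populations_phist_one(self):
        # 6 + 6 samples fixed for different haplotypes: PhiST = 1 and only an
        # exact relabeling of the split (2 / C(12,6) of permutations) ties it
        seqs = ["AAAAAAAAAA"] * 6 + ["AAAAAAAATT"] * 6
        ids = tuple(f"s{i}" for i in range(12))
        aln = Alignment(ids, tuple(seqs))
        pm = PopulationMap.from_pairs(
            [(i, "A" if k < 6 else "B") for k, i in enumerate(ids)]
        )
        dist = mt.pairwise_difference_distance(aln)
        res = mt.amova_phist(aln, pm, dist, n_perm=200, rng_seed=0)
        assert res.overall == pytest.approx(1.0)
        assert res.overall_p <= 5.0 / 201

    def test_duplicated_dataset_invariant(self, toy_alignment, toy_popmap):
        dist = mt.pairwise_difference_distance(toy_alignment)
        base = mt.amova_phist(toy_alignment, toy_popmap, dist, n_perm=20, rng_seed=0)
        doubled = Alignment(
            toy_alignment.sample_ids + tuple(s + "_c" for s in toy_alignment.sample_ids),
            toy_alignment.sequences * 2,
        )
        pm2 = PopulationMap.from_pairs(
            [(s, toy_popmap.assignments[s.removesuffix("_c")]) for s in doubled.sample_ids]
        )
        dist2 = mt.pairwise_difference_distance(doubled)
        res2 = mt.amova_phist(doubled, pm2, dist2, n_perm=20, rng_seed=0)
        assert res2.overall == pytest.approx(base.overall, abs=1e-12)

    def test_random_relabeling_within_null(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 4, size=(16, 60))
        aln = Alignment(
            tuple(f"s{i}" for i in range(16)),
            tuple("".join("ACGT"[c] for c in row) for row in codes),
        )
        labels = ["A"] * 8 + ["B"] * 8
        rng.shuffle(labels)
        pm = PopulationMap.from_pairs(list(zip(aln.sample_ids, labels)))
        dist = mt.pairwise_difference_distance(aln)
        res = mt.amova_phist(aln, pm, dist, n_perm=200, rng_seed=1)
        assert 0.025 <= res.overall_p  # observed stat not in the extreme tail

    def test_permutation_p_reproducible(self, toy_alignment, toy_popmap):
        dist = mt.pairwise_difference_distance(toy_alignment)
        a = mt.amova_phist(toy_alignment, toy_popmap, dist, n_perm=50, rng_seed=4)
        b = mt.amova_phist(toy_alignment, toy_popmap, dist, n_perm=50, rng_seed=4)
        assert a.overall_p == b.overall_p
        assert np.array_equal(a.pairwise_p, b.pairwise_p, equal_nan=True)


class TestHaplotypeFst:
    def test_identical_frequencies_near_zero(self):
        seqs = ["AAAA", "AAAT"] * 4
        aln, ids = _aln(seqs)
        pm = PopulationMap.from_pairs(
            [(i, "A" if k < 4 else "B") for k, i in enumerate(ids)]
        )
        ht = mt.collapse_haplotypes(aln, pm)
        res = mt.haplotype_fst(ht, n_perm=50, rng_seed=0)
        assert abs(res.overall) < 1e-9 or res.overall < 0

    def test_fixed_haplotypes_fst_one(self, toy_alignment, toy_popmap):
        ht = mt.collapse_haplotypes(toy_alignment, toy_popmap)
        res = mt.haplotype_fst(ht, n_perm=50, rng_seed=0)
        assert res.overall == pytest.approx(1.0)


def _by_flags_oracle(pvals, alpha):
    """Brute-force step-up enumeration of Benjamini-Yekutieli."""
    m = len(pvals)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * alpha / (m * c):
            k_star = rank
    flags = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            flags[i] = True
    return flags


class TestFdr:
    def test_all_zero_all_significant(self):
        flags, _ = mt.fdr_correct([0.0] * 6)
        assert flags.all()

    def test_hand_listed_pvalues_vs_enumeration(self):
        pvals = [0.001, 0.3, 0.04, 0.012, 0.9, 0.02, 0.05, 0.0001, 0.25, 0.6,
                 0.013, 0.007, 0.11, 0.049, 0.018]
        flags, _ = mt.fdr_correct(pvals, alpha=0.05)
        assert flags.tolist() == _by_flags_oracle(pvals, 0.05)

    def test_critical_value_for_15_tests(self):
        # m = 15 pairwise tests at alpha 0.05 -> alpha/c(15) ~ 0.0151
        _, crit = mt.fdr_correct([0.5] * 15, alpha=0.05)
        assert crit == pytest.approx(0.015, abs=0.001)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            mt.fdr_correct([])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            mt.fdr_correct([0.5, 1.2])
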