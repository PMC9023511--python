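"""Weir-Cockerham FST, diversity and relatedness statistics."""

import itertools

import numpy as np
import pytest

from retropop.popgen import (
    het_missingness_regression,
    individual_heterozygosity,
    pairwise_fst_matrix,
    relatedness_ajk,
    sfs_diversity,
    wc_components,
    wc_fst,
)
from retropop.simulate import SimulationConfig, simulate_two_pops

from conftest import make_matrix


def wc_oracle_one_locus(geno_by_pop):
    """Scalar transcription of the 1984 variance-component formulas for one
    biallelic locus, written independently of the vectorised code path."""
    r = len(geno_by_pop)
    n = [len(g) for g in geno_by_pop]
    p = [sum(g) / (2 * len(g)) for g in geno_by_pop]
    h = [sum(1 for x in g if x == 1) / len(g) for g in geno_by_pop]
    n_bar = sum(n) / r
    n_tot = sum(n)
    n_c = (n_tot - sum(ni**2 for ni in n) / n_tot) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_tot
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / n_tot
    if p_bar in (0.0, 1.0) or n_bar <= 1 or n_c <= 0:
        return 0.0, 0.0, 0.0
    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a, b, c


class TestWcFst:
    def test_hand_derived_single_locus_example(self):
        # pop1 AA,AA,Aa,Aa vs pop2 aa,aa,Aa,aa (dosages count the a allele)
        dosage = np.array([[0], [0], [1], [1], [2], [2], [1], [2]], dtype=np.int8)
        est = wc_fst(dosage, [1, 1, 1, 1, 2, 2, 2, 2])
        assert est.a[0] == pytest.approx(0.1771, abs=1e-4)
        assert est.b[0] == pytest.approx(-0.0208, abs=1e-4)
        assert est.c[0] == pytest.approx(0.1875, abs=1e-4)
        assert est.theta == pytest.approx(0.515, abs=1e-3)

    def test_fixed_difference_is_one(self):
        dosage = np.array([[0]] * 4 + [[2]] * 4, dtype=np.int8)
        assert wc_fst(dosage, [1] * 4 + [2] * 4).theta == pytest.approx(1.0)

    def test_panmictic_split_is_null(self):
        conf = SimulationConfig(divergence_F=0.0, seed=21)
        geno, _ = simulate_two_pops(50, 50, conf)
        labels = np.r_[np.ones(50), 2 * np.ones(50)]
        assert abs(wc_fst(geno, labels).theta) < 0.005

    def test_matches_scalar_oracle_on_exhaustive_small_instances(self):
        # all 2-population dosage assignments with 2+2 and 3+2 samples, 1 locus
        rng_states = itertools.product([0, 1, 2], repeat=5)
        for state in rng_states:
            for n1 in (2, 3):
                g1, g2 = list(state[:n1]), list(state[n1 : n1 + 2])
                dosage = np.array(g1 + g2, dtype=np.int8)[:, None]
                labels = [1] * len(g1) + [2] * len(g2)
                a, b, c = wc_components(dosage, labels)
                oa, ob, oc = wc_oracle_one_locus([g1, g2])
                assert a[0] == pytest.approx(oa, abs=1e-12)
                assert b[0] == pytest.approx(ob, abs=1e-12)
                assert c[0] == pytest.approx(oc, abs=1e-12)

    def test_three_population_components_match_oracle(self):
        g = [[0, 1, 2], [1, 1, 0], [2, 2, 1]]
        dosage = np.array(sum(g, []), dtype=np.int8)[:, None]
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        a, b, c = wc_components(dosage, labels)
        oa, ob, oc = wc_oracle_one_locus(g)
        assert (a[0], b[0], c[0]) == pytest.approx((oa, ob, oc), abs=1e-12)

    def test_label_swap_and_locus_order_invariance(self, two_pop_strong):
        geno, truth = two_pop_strong
        labels = truth["true_pop"].to_numpy()
        t1 = wc_fst(geno, labels).theta
        t2 = wc_fst(geno, 3 - labels).theta
        perm = np.random.default_rng(0).permutation(geno.n_loci)
        t3 = wc_fst(geno.take_loci(perm), labels).theta
        assert t1 == pytest.approx(t2, abs=1e-14)
        assert t1 == pytest.approx(t3, abs=1e-12)

    def test_underpowered_population_rejected(self):
        dosage = np.array([[0], [1], [2]], dtype=np.int8)
        with pytest.raises(ValueError, match="<2 genotyped"):
            wc_fst(dosage, [1, 1, 2])

    def test_bootstrap_p_small_under_divergence(self, two_pop_strong):
        geno, truth = two_pop_strong
        est = wc_fst(
            geno, truth["true_pop"], n_resamples=500, rng=np.random.default_rng(1)
        )
        assert est.p_value == 0.0
        assert est.ci_95[0] > 0

    def test_permutation_p_large_under_null(self):
        conf = SimulationConfig(n_loci=200, divergence_F=0.0, seed=13)
        geno, _ = simulate_two_pops(20, 20, conf)
        est = wc_fst(
            geno, [1] * 20 + [2] * 20, n_resamples=99, method="permutation",
            rng=np.random.default_rng(3),
        )
        assert est.p_value > 0.05


class TestPairwiseMatrix:
    def test_differentiation_grows_with_cluster2_share(self, default_study):
        geno = default_study.genotypes
        truth = default_study.truth
        periods = np.array([g.split("_")[1] for g in truth.group])
        pw = pairwise_fst_matrix(
            geno, periods, n_resamples=200, rng=np.random.default_rng(0)
        )
        t_old_new = pw.theta.loc["1910-1960", "2000"]
        t_mid_new = pw.theta.loc["1970-1990", "2000"]
        assert t_old_new > t_mid_new > 0

    def test_null_split_not_significant_after_fdr(self):
        conf = SimulationConfig(n_loci=500, divergence_F=0.0, seed=17)
        geno, _ = simulate_two_pops(40, 0, conf)
        groups = np.r_[["a"] * 20, ["b"] * 20]
        pw = pairwise_fst_matrix(
            geno, groups, n_resamples=500, rng=np.random.default_rng(4)
        )
        assert pw.q_value.loc["a", "b"] > 0.05

    def test_small_groups_skipped_with_warning(self, two_pop_strong):
        geno, truth = two_pop_strong
        groups = truth["true_pop"].astype(str).to_numpy().copy()
        groups[0] = "tiny"
        with pytest.warns(UserWarning, match="below minimum size"):
            pw = pairwise_fst_matrix(geno, groups, n_resamples=10)
        assert np.isnan(pw.theta.loc["tiny", "1"])

    def test_q_values_are_benjamini_hochberg_of_raw_p(self, default_study):
        geno = default_study.genotypes
        truth = default_study.truth
        periods = np.array([g.split("_")[1] for g in truth.group])
        pw = pairwise_fst_matrix(
            geno, periods, n_resamples=100, rng=np.random.default_rng(2)
        )
        pairs = list(itertools.combinations(pw.groups, 2))
        raw = np.array([pw.p_value.loc[a, b] for a, b in pairs])
        # textbook BH: sorted p * m / rank, cumulative minimum from the tail
        order = np.argsort(raw)
        m = len(raw)
        stepped = raw[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        got = np.array([pw.q_value.loc[a, b] for a, b in pairs])[order]
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert (got >= raw[order] - 1e-12).all() and (got <= 1).all()


class TestHeterozygosity:
    def test_proportion_of_genotyped_loci(self):
        geno = make_matrix(np.array([[0, 1, 1, 2], [0, 1, -1, 2], [1, 1, 1, 1]]))
        het = individual_heterozygosity(geno)
        assert het.iloc[0] == pytest.approx(0.5)
        assert het.iloc[1] == pytest.approx(1 / 3)
        assert het.iloc[2] == pytest.approx(1.0)

    def test_all_missing_sample_flagged(self):
        geno = make_matrix(np.array([[0, 1], [-1, -1]]))
        with pytest.warns(UserWarning, match="zero genotyped"):
            het = individual_heterozygosity(geno)
        assert np.isnan(het.iloc[1])


class TestSfsDiversity:
    def test_pi_for_two_of_four_chromosomes(self):
        geno = make_matrix(np.array([[1], [1]]))  # 2 het of 2 samples: 2/4 alt
        sfs = sfs_diversity(geno)
        assert sfs.pi == pytest.approx(2 * 2 * 2 / (4 * 3), abs=1e-12)
        assert sfs.S == 1

    def test_watterson_normaliser(self):
        # 5 samples, 10 chromosomes, 7 segregating sites
        cols = [[1, 0, 0, 0, 0]] * 7
        geno = make_matrix(np.array(cols).T)
        sfs = sfs_diversity(geno, projection_n=10)
        assert sfs.a_n == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert sfs.theta_w == pytest.approx(7 / 2.828968, abs=1e-5)

    def test_monomorphic_subset_is_empty_spectrum(self):
        geno = make_matrix(np.zeros((4, 5), dtype=np.int8))
        sfs = sfs_diversity(geno)
        assert sfs.S == 0 and sfs.pi == 0 and sfs.theta_w == 0

    def test_folded_spectrum_sums_to_S_under_projection(self, two_pop_strong):
        geno, _ = two_pop_strong
        for n in (10, 20, 40):
            sfs = sfs_diversity(geno, projection_n=n)
            assert sfs.folded.sum() == pytest.approx(sfs.S, abs=1e-8)

    def test_projection_to_full_size_is_identity(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(6, 100)).astype(np.int8)
        geno = make_matrix(dosage)
        sfs = sfs_diversity(geno, projection_n=12)
        alt, total = geno.allele_counts()
        seg = (alt > 0) & (alt < total)
        minor = np.minimum(alt[seg], total[seg] - alt[seg])
        expected = np.bincount(minor, minlength=7)[1:7]
        np.testing.assert_allclose(sfs.folded, expected, atol=1e-9)

    def test_projection_larger_than_sample_rejected(self):
        geno = make_matrix(np.zeros((3, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            sfs_diversity(geno, projection_n=8)
        with pytest.raises(ValueError):
            sfs_diversity(geno, projection_n=1)


class TestRelatedness:
    def test_duplicate_and_unrelated_pairs(self):
        conf = SimulationConfig(n_loci=1000, divergence_F=0.0, seed=31)
        geno, _ = simulate_two_pops(50, 0, conf)
        dup = geno.dosage.copy()
        dup = np.vstack([dup, dup[0][None, :]])
        geno2 = make_matrix(dup, chrom=geno.loci.chrom, pos=geno.loci.pos,
                            qual=geno.loci.qual,
                            samples=geno.samples + ["S0_copy"])
        A, flags = relatedness_ajk(geno2)
        assert A.loc["P1_000", "S0_copy"] == pytest.approx(1.0, abs=0.1)
        assert abs(A.loc["P1_001", "P1_002"]) < 0.1
        dup_flags = flags[flags.flag == "duplicate"]
        assert {"P1_000", "S0_copy"} == set(
            dup_flags[["sample_1", "sample_2"]].iloc[0]
        )
        assert dup_flags.ibs.iloc[0] == 1.0

    def test_monomorphic_only_rejected(self):
        geno = make_matrix(np.zeros((4, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="polymorphic"):
            relatedness_ajk(geno)


class TestHetMissingRegression:
    def test_constant_het_is_flat(self):
        slope, r2, p = het_missingness_regression([0.2] * 10, np.linspace(0, 1, 10))
        assert (slope, r2, p) == (0.0, 0.0, 1.0)

    def test_perfect_dependence(self):
        x = np.linspace(0.0, 0.1, 20)
        slope, r2, p = het_missingness_regression(x, x)
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_inputs_give_null_r2(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(20):
            het = rng.normal(0.25, 0.02, 100)
            miss = rng.uniform(0, 0.05, 100)
            slope, r2, p = het_missingness_regression(het, miss)
            pvals.append(p)
            assert r2 < 0.2
        assert 0.05 < np.mean(pvals) < 0.95  # roughly uniform p under the null

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            het_missingness_regression([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
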