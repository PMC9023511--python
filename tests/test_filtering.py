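"""SNP filter cascade: exact tests, pruning and the audited toy fixture."""

import math
from fractions import Fraction

import numpy as np
import pytest

from retropop.filtering import (
    FilterConfig,
    duplicate_concordance_filter,
    find_duplicate_pairs,
    hwe_exact,
    ld_prune,
    run_filter_cascade,
)
from retropop.genotypes import MISSING, read_vcf, write_vcf

from conftest import make_matrix


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent brute-force enumeration with exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return Fraction(1)
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_min, hom_maj = (n_minor - h) // 2, n - h - (n_minor - h) // 2
        if hom_maj < 0:
            continue
        probs[h] = Fraction(
            math.factorial(n) * 2**h * math.factorial(n_minor) * math.factorial(2 * n - n_minor),
            math.factorial(hom_min) * math.factorial(h) * math.factorial(hom_maj) * math.factorial(2 * n),
        )
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact(10, 0, 0) == 1.0

    def test_modal_het_count_is_one(self):
        assert hwe_exact(5, 10, 5) == pytest.approx(1.0)

    def test_zero_hets_at_half_maf_is_tiny(self):
        assert hwe_exact(10, 0, 10) < 1e-3

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)

    def test_matches_exhaustive_enumeration_oracle(self):
        # every genotype configuration with n <= 30 samples
        for n in range(1, 31):
            for n_aa in range(n + 1):
                for n_het in range(n - n_aa + 1):
                    n_AA = n - n_aa - n_het
                    p = hwe_exact(n_AA, n_het, n_aa)
                    q = hwe_oracle(n_AA, n_het, n_aa)
                    assert abs(p - float(q)) < 1e-12, (n_AA, n_het, n_aa)


class TestLdPrune:
    def test_duplicated_locus_dropped(self):
        base = [0, 0, 1, 2, 1, 0]
        geno = make_matrix(
            np.array([base, base]).T, chrom=["s", "s"], pos=[100, 200]
        )
        assert list(ld_prune(geno)) == [0]

    def test_uncorrelated_neighbours_kept(self):
        geno = make_matrix(
            np.array([[0, 0, 2, 2], [0, 2, 0, 2]]).T, chrom=["s", "s"], pos=[100, 200]
        )
        assert list(ld_prune(geno)) == [0, 1]

    def test_hand_computed_r2_pair(self):
        x = [0, 1, 2, 2, 1, 0]
        y = [0, 1, 1, 2, 1, 0]
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 == pytest.approx(0.794, abs=5e-4)
        geno = make_matrix(np.array([x, y]).T, chrom=["s", "s"], pos=[100, 200])
        assert list(ld_prune(geno)) == [0]

    def test_distant_identical_loci_both_kept(self):
        base = [0, 0, 1, 2, 1, 0]
        geno = make_matrix(
            np.array([base, base]).T, chrom=["s", "s"], pos=[100, 2000]
        )
        assert list(ld_prune(geno)) == [0, 1]

    def test_unsorted_input_rejected(self):
        geno = make_matrix(
            np.zeros((4, 2), dtype=np.int8), chrom=["s", "s"], pos=[500, 100]
        )
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(geno)

    def test_no_high_r2_pairs_survive(self, default_study):
        geno = default_study.genotypes
        kept = ld_prune(geno)
        sub = geno.take_loci(kept)
        chrom = sub.loci.chrom.to_numpy()
        pos = sub.loci.pos.to_numpy()
        X = sub.dosage_float()
        for j in range(1, sub.n_loci):
            for i in range(j - 1, -1, -1):
                if chrom[i] != chrom[j] or pos[j] - pos[i] >= 800:
                    break
                ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
                if ok.sum() > 1 and X[ok, i].std() and X[ok, j].std():
                    r2 = np.corrcoef(X[ok, i], X[ok, j])[0, 1] ** 2
                    assert r2 < 0.25


class TestDuplicateConcordance:
    def _geno(self, col_a, col_dup):
        """3 pairs: (S0,S0d), (S1,S1d), (S2,S2d); one test locus."""
        dosage = np.array([col_a + col_dup]).T
        return make_matrix(
            dosage,
            samples=["S0", "S1", "S2", "S0_dup", "S1_dup", "S2_dup"],
        )

    def test_fully_concordant_kept(self):
        keep, flagged = duplicate_concordance_filter(
            self._geno([0, 1, 2], [0, 1, 2]), [(0, 3), (1, 4), (2, 5)]
        )
        assert keep.all() and not flagged.any()

    def test_two_of_three_matching_dropped(self):
        # 2/3 = 0.667 <= 0.80
        keep, _ = duplicate_concordance_filter(
            self._geno([0, 1, 2], [0, 1, 1]), [(0, 3), (1, 4), (2, 5)]
        )
        assert not keep[0]

    def test_all_missing_pairs_kept_but_flagged(self):
        keep, flagged = duplicate_concordance_filter(
            self._geno([0, 1, 2], [MISSING, MISSING, MISSING]),
            [(0, 3), (1, 4), (2, 5)],
        )
        assert keep[0] and flagged[0]

    def test_no_pairs_warns_and_keeps_all(self):
        geno = self._geno([0, 1, 2], [0, 1, 2])
        with pytest.warns(UserWarning, match="no duplicate pairs"):
            keep, _ = duplicate_concordance_filter(geno, [])
        assert keep.all()

    def test_pairs_found_by_naming_convention(self):
        assert find_duplicate_pairs(["A", "B", "A_dup", "C"]) == [(0, 2)]


def toy_cascade_fixture():
    """Twelve loci engineered so each cascade rule removes exactly one.

    L01 multiallelic, L02 low QUAL, L03 MAC=2, L04 27% missing, L05 inflated
    depth, L07 perfect LD with L06, L08 duplicate-discordant, L09 no hets at
    ~50% MAF; survivors L06, L10, L11, L12.  Sample S9 misses half the
    surviving loci, so the call-rate step removes it.
    """
    M = MISSING
    base = [0, 1, 1, 0, 1, 2, 1, 0, 0, 0, 0]  # S0..S9 + S0_dup; MAC 6, HWE-quiet
    cols = {
        "L01": base,
        "L02": base,
        "L03": [0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
        "L04": [0, M, M, M, 1, 2, 1, 0, 0, 0, 0],
        "L05": base,
        "L06": base,
        "L07": base,
        "L08": [0, 1, 1, 0, 1, 2, 1, 0, 0, 0, 2],  # S0 vs S0_dup disagree
        "L09": [0, 0, 0, 0, 0, 2, 2, 2, 2, 2, 0],
        "L10": [0, 1, 1, 0, 1, 2, 1, 0, 0, M, 0],
        "L11": [0, 1, 1, 0, 1, 2, 1, 0, 0, M, 0],
        "L12": base,
    }
    names = list(cols)
    dosage = np.array([cols[c] for c in names]).T
    chrom = [f"sc_{c}" for c in names]
    chrom[6] = chrom[5]  # L06/L07 share a scaffold...
    pos = [1000] * len(names)
    pos[6] = 1100  # ...100 bp apart
    qual = [100.0] * len(names)
    qual[1] = 20.0
    depth = np.full(dosage.shape, 30, dtype=np.int32)
    depth[:, 4] = 300
    alt = ["G"] * len(names)
    alt[0] = "G,T"
    geno = make_matrix(
        dosage, chrom=chrom, pos=pos, qual=qual, depth=depth, alt=alt,
        samples=[f"S{i}" for i in range(10)] + ["S0_dup"],
    )
    survivors = {"sc_L06", "sc_L10", "sc_L11", "sc_L12"}
    return geno, survivors


class TestFilterCascade:
    @pytest.mark.parametrize("via_vcf", [False, True], ids=["in_memory", "vcf_round_trip"])
    def test_toy_fixture_loses_one_locus_per_rule(self, tmp_path, via_vcf):
        geno, survivors = toy_cascade_fixture()
        if via_vcf:
            write_vcf(geno, tmp_path / "toy.vcf")
            geno = read_vcf(tmp_path / "toy.vcf")
        out, report = run_filter_cascade(geno)
        df = report.to_dataframe().set_index("step")
        removed = df.loci_before - df.loci_after
        expected = {
            "biallelic_snp": 1, "qual": 1, "mac": 1, "locus_missingness": 1,
            "excess_depth": 1, "ld_prune": 1, "duplicate_concordance": 1,
            "hwe": 1, "sample_call_rate": 0,
        }
        assert dict(removed) == expected
        assert set(out.loci.chrom) == survivors
        assert "S9" not in out.samples and out.n_samples == 10

    def test_sample_call_rate_drop(self):
        geno, _ = toy_cascade_fixture()
        out, report = run_filter_cascade(geno)
        df = report.to_dataframe().set_index("step")
        assert df.loc["sample_call_rate", "samples_before"] == 11
        assert df.loc["sample_call_rate", "samples_after"] == 10

    def test_mac_filter_removes_all_singletons_and_doubletons(self, default_study):
        out, _ = run_filter_cascade(default_study.genotypes)
        alt, total = out.allele_counts()
        assert (np.minimum(alt, total - alt) >= 3).all()

    def test_generator_calibrated_qual_and_depth_casualties(self, default_study):
        _, report = run_filter_cascade(default_study.genotypes)
        df = report.to_dataframe().set_index("step")
        frac_qual = (df.loc["qual", "loci_before"] - df.loc["qual", "loci_after"]) / 1840
        frac_depth = (
            df.loc["excess_depth", "loci_before"] - df.loc["excess_depth", "loci_after"]
        ) / df.loc["excess_depth", "loci_before"]
        assert 0.02 <= frac_qual <= 0.09  # nominal 5%
        assert 0.005 <= frac_depth <= 0.05  # nominal 2%

    def test_idempotent_with_frozen_realized_threshold(self, default_study):
        conf = FilterConfig()
        out1, report1 = run_filter_cascade(default_study.genotypes, conf)
        frozen = FilterConfig(
            depth_threshold=report1.realized_param("excess_depth", "threshold")
        )
        out2, report2 = run_filter_cascade(out1, frozen, duplicate_pairs=[])
        assert out2.n_loci == out1.n_loci
        assert out2.samples == out1.samples
        np.testing.assert_array_equal(out2.dosage, out1.dosage)

    def test_empty_input_rejected(self):
        geno, _ = toy_cascade_fixture()
        with pytest.raises(ValueError, match="empty"):
            run_filter_cascade(geno.take_loci(np.array([], dtype=int)))

    def test_all_loci_removed_raises_with_report(self):
        geno, _ = toy_cascade_fixture()
        with pytest.raises(ValueError, match="all loci removed"):
            run_filter_cascade(geno, FilterConfig(min_qual=1e6))
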