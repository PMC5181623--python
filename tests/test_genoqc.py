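"""Genotype QC: call-rate filters, exact Hardy-Weinberg test, X-chromosome
inbreeding sex check and genotype principal components."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from regmeth.data import GenotypeData
from regmeth.genoqc import (
    filter_sample_callrate,
    filter_snps,
    genotype_pcs,
    hwe_exact_p,
    x_inbreeding_f,
)

from conftest import random_genotypes


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the conditional heterozygote
    distribution; independent of the implementation under test."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    nm = min(na, 2 * n - na)
    if nm == 0:
        return 1.0
    weights = {}
    for h in range(nm % 2, nm + 1, 2):
        hom_minor = (nm - h) // 2
        hom_major = n - h - hom_minor
        weights[h] = Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(hom_minor) * math.factorial(hom_major),
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHweExact:
    def test_extreme_heterozygote_deficit(self):
        assert hwe_exact_p(50, 0, 50) < 1e-20

    def test_most_probable_configuration_near_one(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), abs=1e-12
        )

    def test_monomorphic_returns_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0

    def test_agrees_with_enumeration_for_all_small_tables(self):
        """Every genotype table with n <= 50 within 1e-12 of the oracle."""
        worst = 0.0
        for n in (5, 17, 50):
            for n_het in range(n + 1):
                for n_alt_hom in range(n - n_het + 1):
                    n_ref_hom = n - n_het - n_alt_hom
                    got = hwe_exact_p(n_ref_hom, n_het, n_alt_hom)
                    want = hwe_enumeration_oracle(n_ref_hom, n_het, n_alt_hom)
                    worst = max(worst, abs(got - want))
        assert worst <= 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


def _geno_with_missing(pattern):
    """Build GenotypeData from a dosage array where -9 marks missing."""
    d = np.array(pattern, dtype=float)
    d[d == -9] = np.nan
    n, m = d.shape
    snps = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * 100,
         "id": [f"v{j}" for j in range(m)], "ref": "A", "alt": "G"}
    )
    return GenotypeData([f"p{i}" for i in range(n)], snps, d)


class TestSampleCallrate:
    def test_sample_above_threshold_removed(self):
        # sample 0 missing 6% of 50 SNPs
        d = np.ones((4, 50))
        d[0, :3] = np.nan
        geno = _geno_with_missing(d)
        out, report = filter_sample_callrate(geno, max_missing=0.05)
        assert out.n_samples == 3
        assert report.steps[0]["removed_ids"] == ["p0"]

    def test_complete_data_identity(self):
        geno = _geno_with_missing(np.ones((3, 10)))
        out, _ = filter_sample_callrate(geno)
        assert out.n_samples == 3

    def test_threshold_one_keeps_everything(self):
        d = np.full((3, 10), np.nan)
        d[:, 0] = 1
        out, _ = filter_sample_callrate(_geno_with_missing(d), max_missing=1.0)
        assert out.n_samples == 3

    def test_all_removed_is_an_error(self):
        d = np.full((2, 10), np.nan)
        d[:, 0] = 1
        with pytest.raises(ValueError):
            filter_sample_callrate(_geno_with_missing(d), max_missing=0.01)


class TestFilterSnps:
    def _fixture(self):
        rng = np.random.default_rng(20)
        n = 100
        cols = {
            "good": rng.binomial(2, 0.3, n).astype(float),
            "high_missing": rng.binomial(2, 0.3, n).astype(float),
            "hwe_fail": np.concatenate([np.zeros(50), np.full(50, 2.0)]),
            "rare": np.r_[1.0, np.zeros(n - 1)],
        }
        cols["high_missing"][:10] = np.nan  # 10% missing
        d = np.column_stack(list(cols.values()))
        snps = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 200, 300, 400],
             "id": list(cols), "ref": "A", "alt": "G"}
        )
        return GenotypeData([f"p{i}" for i in range(n)], snps, d)

    def test_successive_attribution(self):
        """A SNP failing filter (i) is never re-counted by later filters."""
        geno = self._fixture()
        out, report = filter_snps(geno)
        by_name = {s["filter"]: s["removed_ids"] for s in report.steps}
        assert by_name["snp_callrate"] == ["high_missing"]
        assert by_name["hwe"] == ["hwe_fail"]
        assert by_name["maf"] == ["rare"]
        assert list(out.snps["id"]) == ["good"]

    def test_ideal_snps_pass_untouched(self):
        rng = np.random.default_rng(21)
        geno = random_genotypes(rng, 200, 20, maf_lo=0.2)
        out, report = filter_snps(geno)
        assert out.n_snps == 20
        assert all(s["n_removed"] == 0 for s in report.steps)

    def test_differential_missingness_filter(self):
        rng = np.random.default_rng(22)
        n = 200
        d = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        cc = np.r_[np.ones(100), np.zeros(100)]
        d[:60, 1] = np.nan  # missing only in cases
        snps = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 200], "id": ["even", "skewed"],
             "ref": "A", "alt": "G"}
        )
        geno = GenotypeData([f"p{i}" for i in range(n)], snps, d)
        out, report = filter_snps(geno, cc_labels=cc)
        assert list(out.snps["id"]) == ["even"]

    def test_final_set_stable_under_independent_filters(self):
        """When no SNP fails two filters, attribution is order bookkeeping
        only: the surviving set equals complement of the union."""
        geno = self._fixture()
        out, report = filter_snps(geno)
        removed = {i for s in report.steps for i in s["removed_ids"]}
        assert set(out.snps["id"]) == set(geno.snps["id"]) - removed


class TestXInbreeding:
    def _x_geno(self, dosages):
        d = np.asarray(dosages, dtype=float)
        m = d.shape[1]
        snps = pd.DataFrame(
            {"chrom": "X", "pos": np.arange(1, m + 1) * 10,
             "id": [f"x{j}" for j in range(m)], "ref": "A", "alt": "G"}
        )
        return GenotypeData([f"p{i}" for i in range(d.shape[0])], snps, d)

    def test_all_het_at_half_frequency_gives_minus_one(self):
        # two samples het everywhere: p = 0.5 per SNP, O = m, E = m/2
        geno = self._x_geno(np.ones((2, 60)))
        tab = x_inbreeding_f(geno, {"p0": "F", "p1": "F"})
        assert tab["F"].to_numpy() == pytest.approx([-1.0, -1.0])

    def test_zero_het_flags_recorded_female(self):
        rng = np.random.default_rng(23)
        d = rng.binomial(2, 0.5, size=(40, 100)).astype(float)
        d[0] = np.where(d[0] == 1, 2.0, d[0])  # sample 0: no het calls
        tab = x_inbreeding_f(
            self._x_geno(d), {f"p{i}": ("F" if i == 0 else "M") for i in range(40)}
        )
        assert tab.loc[0, "F"] == pytest.approx(1.0)
        assert tab.loc[0, "flag"] == "remove"

    def test_balanced_het_gives_zero(self):
        rng = np.random.default_rng(24)
        d = rng.binomial(2, 0.5, size=(300, 400)).astype(float)
        tab = x_inbreeding_f(self._x_geno(d), {f"p{i}": "F" for i in range(300)})
        assert abs(tab["F"].mean()) < 0.05

    def test_invariant_to_snp_order_and_own_missing(self):
        rng = np.random.default_rng(25)
        d = rng.binomial(2, 0.4, size=(60, 80)).astype(float)
        geno = self._x_geno(d)
        f0 = x_inbreeding_f(geno, {})["F"][0]
        perm = rng.permutation(80)
        f_perm = x_inbreeding_f(geno.take_snps(np.sort(perm[:80])), {})["F"][0]
        assert f0 == pytest.approx(f_perm)
        # removing SNPs that are missing in this sample leaves its F unchanged
        d2 = d.copy()
        d2[0, :5] = np.nan
        masked = self._x_geno(d2)
        full = x_inbreeding_f(masked, {})["F"][0]
        dropped = x_inbreeding_f(
            self._x_geno(np.delete(d2, np.s_[:5], axis=1)), {}
        )["F"][0]
        # allele frequencies shift slightly when other samples keep those SNPs
        assert full == pytest.approx(dropped, abs=0.02)


class TestGenotypePcs:
    def test_pc1_separates_two_populations(self):
        rng = np.random.default_rng(26)
        n_half, m = 60, 300
        p1 = rng.uniform(0.1, 0.5, m)
        shift = np.clip(p1 + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
        d = np.vstack(
            [rng.binomial(2, p1, (n_half, m)), rng.binomial(2, shift, (n_half, m))]
        ).astype(float)
        snps = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, m + 1) * 50,
             "id": [f"v{j}" for j in range(m)], "ref": "A", "alt": "G"}
        )
        geno = GenotypeData([f"p{i}" for i in range(2 * n_half)], snps, d)
        scores = genotype_pcs(geno, 2)
        labels = np.r_[np.zeros(n_half), np.ones(n_half)]
        r = np.corrcoef(scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_k_zero_empty(self):
        rng = np.random.default_rng(27)
        assert genotype_pcs(random_genotypes(rng, 10, 20), 0).shape == (10, 0)

    def test_duplicate_samples_score_identically(self):
        rng = np.random.default_rng(28)
        geno = random_genotypes(rng, 30, 50)
        d = geno.dosages.copy()
        d[1] = d[0]
        dup = GenotypeData(geno.samples, geno.snps, d)
        scores = genotype_pcs(dup, 3)
        assert np.allclose(scores[0], scores[1], atol=1e-8)

    def test_k_beyond_rank_rejected(self):
        rng = np.random.default_rng(29)
        geno = random_genotypes(rng, 5, 100)
        with pytest.raises(ValueError):
            genotype_pcs(geno, 6)
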