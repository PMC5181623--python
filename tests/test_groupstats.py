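"""Group comparison tests and contextual summaries.

The two-proportion fixtures are frozen from R's prop.test (the convention
the implementation mirrors); Welch and KS cases are textbook closed forms.
"""

import numpy as np
import pandas as pd
import pytest

from regmeth.groupstats import (
    context_summaries,
    h2_variance_partition,
    ks_2samp,
    predicted_h2_increase,
    risk_region_compare,
    two_prop_test,
    welch_t,
)


class TestWelch:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = welch_t(x, x)
        assert t == 0.0 and p == 1.0

    def test_large_separation(self):
        rng = np.random.default_rng(50)
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000) + 1.0
        _, _, p = welch_t(x, y)
        assert p < 1e-100

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(51)
        x, y = rng.standard_normal(30), rng.standard_normal(25) + 0.4
        t1, _, p1 = welch_t(x, y)
        t2, _, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hand_computed_fixture(self):
        # n1=n2=2: t = (mean diff)/sqrt(s1^2/2 + s2^2/2)
        x, y = np.array([0.0, 2.0]), np.array([10.0, 12.0])
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(-10.0 / np.sqrt(2.0), rel=1e-10)

    def test_degenerate_equal_constants(self):
        t, _, p = welch_t(np.ones(5), np.ones(7))
        assert t == 0.0 and p == 1.0


class TestKs:
    def test_identical_samples_d_zero(self):
        x = np.arange(20.0)
        d, _ = ks_2samp(x, x)
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_d_one(self):
        d, p = ks_2samp(np.arange(20.0), np.arange(100.0, 120.0))
        assert d == 1.0 and p < 1e-6

    def test_matches_ecdf_gap_oracle(self):
        rng = np.random.default_rng(52)
        for _ in range(50):
            x = rng.standard_normal(rng.integers(10, 40))
            y = rng.standard_normal(rng.integers(10, 40)) + rng.uniform(-1, 1)
            d, _ = ks_2samp(x, y)
            grid = np.sort(np.concatenate([x, y]))
            gap = max(
                abs((x <= v).mean() - (y <= v).mean()) for v in grid
            )
            assert d == pytest.approx(gap, abs=1e-12)


class TestTwoProp:
    # (k1, n1, k2, n2) -> (chi2, p) frozen from R prop.test (Yates corrected)
    R_FIXTURES = [
        ((50, 100, 10, 100), (36.21428571, 1.767699828e-09)),
        ((5, 20, 10, 30), (0.09920634921, 0.7527841326)),
        ((1, 10, 9, 10), (9.8, 0.0017451187)),
        ((30, 300, 20, 100), (5.973333333, 0.01452380124)),
    ]

    @pytest.mark.parametrize("args,expect", R_FIXTURES)
    def test_matches_r_prop_test(self, args, expect):
        chi2, p = two_prop_test(*args)
        assert chi2 == pytest.approx(expect[0], rel=1e-9)
        assert p == pytest.approx(expect[1], rel=1e-8)

    def test_uncorrected_matches_r(self):
        chi2, p = two_prop_test(50, 100, 10, 100, correction=False)
        assert chi2 == pytest.approx(38.0952381, rel=1e-9)
        assert p == pytest.approx(6.737436019e-10, rel=1e-8)

    def test_equal_proportions_p_one(self):
        chi2, p = two_prop_test(5, 50, 10, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_symmetric_under_group_swap(self):
        a = two_prop_test(13, 40, 29, 70)
        b = two_prop_test(29, 70, 13, 40)
        assert a == pytest.approx(b)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_prop_test(11, 10, 1, 10)


class TestSlopePrediction:
    def test_worked_example(self):
        # fitted slope of h2 on window SNP count, evaluated at the deciles
        assert f"{predicted_h2_increase(2.372e-5, 304):.1e}" == "7.2e-03"
        assert f"{predicted_h2_increase(2.372e-5, 2733):.1e}" == "6.5e-02"


def _site_table(seed=53, n_per_group=60, h2_by_density=None):
    """Synthetic per-site table across the eight contextual groups."""
    rng = np.random.default_rng(seed)
    h2_by_density = h2_by_density or {"island": 0.1, "sea": 0.1}
    rows = []
    k = 0
    for dens in ("island", "sea"):
        for genic in ("tss_expressed", "tss_not_expressed", "intragenic",
                      "intergenic"):
            for _ in range(n_per_group):
                h2 = max(rng.normal(h2_by_density[dens], 0.05), 0.0)
                # p loosely tied to h2 so 'heritable' tracks the h2 level
                p = float(np.clip(rng.uniform(0, 1) * np.exp(-8 * h2), 1e-6, 1))
                rows.append(
                    {"id": f"cg{k}", "chrom": "chr1", "pos": 1000 + k * 100,
                     "mean_m": rng.normal(-2 if dens == "island" else 1.5, 0.5),
                     "resvar": rng.gamma(4, 0.05),
                     "h2": h2, "p": p, "sigma_g2": h2 * 0.2,
                     "density": dens, "genic": genic}
                )
                k += 1
    return pd.DataFrame(rows)


class TestContextSummaries:
    def test_eight_groups_plus_density_classes(self):
        tab = _site_table()
        summary, tests, corr = context_summaries(tab)
        assert (summary["group"].str.contains("_")).sum() == 8
        assert len(tests) == 28  # all pairs of 8 groups
        assert set(corr) == {"island", "sea"}

    def test_sea_heritability_excess_detected(self):
        tab = _site_table(h2_by_density={"island": 0.02, "sea": 0.35},
                          n_per_group=120)
        summary, tests, _ = context_summaries(tab)
        sea = summary[summary["group"] == "sea"].iloc[0]
        isl = summary[summary["group"] == "island"].iloc[0]
        assert sea["prop_heritable"] > isl["prop_heritable"]
        cross = tests[
            tests["group_a"].str.startswith("island")
            & tests["group_b"].str.startswith("sea")
        ]
        assert (cross["prop_p_heritable"] < 0.05).any()

    def test_identical_values_give_p_one(self):
        tab = _site_table(n_per_group=10)
        tab["mean_m"] = 1.0
        _, tests, _ = context_summaries(tab)
        assert np.allclose(tests["welch_p_mean"], 1.0)

    def test_site_order_invariance(self):
        tab = _site_table(n_per_group=20)
        a, _, _ = context_summaries(tab)
        b, _, _ = context_summaries(tab.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )


class TestH2VariancePartition:
    def _inputs(self, slope=0.0, seed=54, n=400):
        rng = np.random.default_rng(seed)
        tab = _site_table(seed=seed, n_per_group=n // 8)
        rh = tab[["id", "chrom", "pos", "h2", "p"]].copy()
        rh["n_snps"] = rng.integers(100, 2000, len(rh))
        rh["h2"] = np.clip(
            rh["h2"] + slope * rh["n_snps"] + rng.normal(0, 0.01, len(rh)), 0, 1
        )
        rh["p"] = 0.01  # everything significant: regression sees all sites
        return rh, tab

    def test_null_slope_near_zero(self):
        rh, tab = self._inputs(slope=0.0)
        out = h2_variance_partition(rh, tab)
        assert abs(out["snp_count"]["slope"]) < 1e-4
        assert out["snp_count"]["p"] > 1e-4

    def test_injected_slope_recovered(self):
        rh, tab = self._inputs(slope=2e-5)
        out = h2_variance_partition(rh, tab)
        assert out["snp_count"]["slope"] == pytest.approx(2e-5, rel=0.3)
        assert out["snp_count"]["p"] < 1e-3

    def test_context_shift_detected_by_anova(self):
        rh, tab = self._inputs(slope=0.0, seed=55)
        shift = tab["density"].eq("sea") * 0.2
        rh = rh.copy()
        rh["h2"] = np.clip(rh["h2"] + shift.to_numpy(), 0, 1)
        out = h2_variance_partition(rh, tab)
        assert out["context_anova"]["p"] < 0.05

    def test_too_few_significant_sites(self):
        rh, tab = self._inputs()
        rh["p"] = 0.9
        out = h2_variance_partition(rh, tab)
        assert out["snp_count"] is None


class TestRiskRegions:
    def _rh(self):
        rng = np.random.default_rng(56)
        n = 300
        return pd.DataFrame(
            {"id": [f"cg{k}" for k in range(n)], "chrom": "chr1",
             "pos": rng.integers(1, 50_000_000, n),
             "h2": rng.uniform(0, 0.6, n), "p": rng.uniform(0, 1, n)}
        )

    def test_site_exactly_one_megabase_away_is_within(self):
        rh = pd.DataFrame(
            [{"id": "cg0", "chrom": "chr1", "pos": 2_000_000, "h2": 0.3,
              "p": 0.01}]
        )
        risk = pd.DataFrame([{"chrom": "chr1", "pos": 1_000_000, "id": "rs1"}])
        out = risk_region_compare(rh, risk)
        assert out["within"]["n_sites"] == 1
        assert out["outwith"]["n_sites"] == 0

    def test_whole_genome_risk_region_empties_outwith(self):
        rh = self._rh()
        risk = pd.DataFrame(
            [{"chrom": "chr1", "pos": p, "id": f"rs{p}"}
             for p in range(500_000, 50_500_000, 1_000_000)]
        )
        out = risk_region_compare(rh, risk)
        assert out["outwith"]["n_sites"] == 0
        assert out["prop_test"] is None

    def test_empty_risk_list_everything_outwith(self):
        rh = self._rh()
        out = risk_region_compare(rh, pd.DataFrame(columns=["chrom", "pos", "id"]))
        assert out["within"]["n_sites"] == 0
        assert out["outwith"]["n_sites"] == len(rh)

    def test_equal_distributions_give_moderate_p(self):
        rh = self._rh()
        risk = pd.DataFrame([{"chrom": "chr1", "pos": 10_000_000, "id": "rs1"}])
        out = risk_region_compare(rh, risk)
        assert out["prop_test"]["p"] > 1e-4  # no fabricated contrast
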