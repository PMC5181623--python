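"""SNP-by-SNP association of residualized methylation with dosage.

Each test is a simple linear regression of the residual M-value on
alt-allele dosage (the PLINK --assoc model): Wald t on n - 2 df, with
R^2 the squared Pearson correlation. SNP-site pairs are binned cis
(same chromosome, |distance| <= 1 Mb, boundary inclusive) versus trans,
and observed significant counts are compared with the expectation
n_tests x threshold under independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeData, MethylationData

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000


@dataclass
class AssocResult:
    snp_id: str
    site_id: str
    beta: float
    se: float
    t: float
    p: float
    r2: float
    relation: str  # cis | trans
    distance: float  # bp on the same chromosome, NaN across chromosomes


def snp_assoc(y: np.ndarray, g: np.ndarray) -> dict | None:
    """OLS of trait on dosage; None when untestable (monomorphic / n < 3).

    Missing dosages are dropped pairwise.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g = y[ok], g[ok]
    n = y.size
    if n < 3 or np.ptp(g) == 0:
        return None
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    syy = float(yc @ yc)
    r2 = float((gc @ yc) ** 2 / (sxx * syy)) if syy > 0 else 0.0
    return {"beta": beta, "se": se, "t": t, "p": p, "r2": r2, "n": n}


def classify_relation(
    snp_chrom: str, snp_pos: int, site_chrom: str, site_pos: int,
    cis_window: int = CIS_WINDOW,
) -> tuple[str, float]:
    """cis iff same chromosome and |distance| <= the window (inclusive)."""
    if snp_chrom != site_chrom:
        return "trans", np.nan
    d = float(snp_pos - site_pos)
    return ("cis" if abs(d) <= cis_window else "trans"), d


def expected_count(n_tests: int, threshold: float) -> float:
    """Expected significant count under independent null tests."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    return n_tests * threshold


def gwas_scan(
    resid: MethylationData,
    geno: GenotypeData,
    thresholds=(5e-2, 5e-4, 5e-8),
    cis_window: int = CIS_WINDOW,
    min_mac: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All site x SNP associations plus the cis/trans count summary.

    SNPs with minor allele count below ``min_mac`` among non-missing calls
    are skipped and excluded from the number of tests. The summary gives,
    per threshold and relation class, the observed significant count, the
    independence-based expected count, and the number of sites with at least
    one significant association.
    """
    if resid.samples != geno.samples:
        raise ValueError("residual and genotype samples are not aligned")
    rows = []
    snp_chrom = geno.snps["chrom"].to_numpy()
    snp_pos = geno.snps["pos"].to_numpy()
    snp_ids = geno.snps["id"].to_numpy()
    mac = np.minimum(np.nansum(geno.dosages, axis=0),
                     np.nansum(2 - geno.dosages, axis=0))
    testable = np.flatnonzero(mac >= min_mac)
    if testable.size < geno.n_snps:
        logger.info("%d SNPs below MAC %d skipped", geno.n_snps - testable.size, min_mac)
    for k, site in enumerate(resid.sites.itertuples()):
        y = resid.values[:, k]
        for j in testable:
            core = snp_assoc(y, geno.dosages[:, j])
            if core is None:
                continue
            rel, dist = classify_relation(
                snp_chrom[j], int(snp_pos[j]), site.chrom, int(site.pos), cis_window
            )
            rows.append(
                {"snp_id": snp_ids[j], "site_id": site.id, "beta": core["beta"],
                 "se": core["se"], "t": core["t"], "p": core["p"],
                 "r2": core["r2"], "relation": rel, "distance": dist}
            )
    table = pd.DataFrame(rows)
    summaries = []
    for rel in ("cis", "trans"):
        sub = table[table["relation"] == rel] if len(table) else table
        n_tests = len(sub)
        for thr in thresholds:
            sig = sub[sub["p"] < thr] if n_tests else sub
            summaries.append(
                {"relation": rel, "threshold": thr, "n_tests": n_tests,
                 "count": len(sig),
                 "count_expected": expected_count(n_tests, thr),
                 "count_sites": sig["site_id"].nunique() if len(sig) else 0}
            )
    return table, pd.DataFrame(summaries)


def top_snp_vs_region(
    rh_results: pd.DataFrame,
    assoc_results: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Pair each significantly heritable site with its top cis SNP.

    The top SNP minimizes p (ties: larger r2, then smaller |distance|). The
    ratio r2_top / h2 measures how much of the regional estimate one SNP
    explains; the summary reports the fraction of sites where the region
    explains at least as much as the SNP (ratio <= 1).
    """
    sig = rh_results[(rh_results["p"] < alpha) & (rh_results["h2"] > 0)]
    cis = assoc_results[assoc_results["relation"] == "cis"]
    rows, n_missing = [], 0
    for rec in sig.itertuples():
        mine = cis[cis["site_id"] == rec.id]
        if not len(mine):
            n_missing += 1
            continue
        mine = mine.sort_values(
            ["p", "r2", "distance"], ascending=[True, False, True],
            key=lambda s: s.abs() if s.name == "distance" else s,
        )
        top = mine.iloc[0]
        rows.append(
            {"site_id": rec.id, "snp_id": top["snp_id"], "r2_top": top["r2"],
             "h2": rec.h2, "ratio": top["r2"] / rec.h2}
        )
    table = pd.DataFrame(rows)
    frac = float((table["ratio"] <= 1).mean()) if len(table) else np.nan
    return table, {
        "n_paired": len(table),
        "n_missing_cis": n_missing,
        "frac_region_ge_snp": frac,
    }
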