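"""Contextual group summaries and hypothesis tests.

Per contextual group (island/sea crossed with the four genic classes):
moments of the per-site mean M-value, mean residual variance, the proportion
of significantly heritable sites and the mean h2 among them. Group
comparisons use Welch's t, the two-sample Kolmogorov-Smirnov test and the
two-proportion chi-square test with Yates continuity correction (the
R ``prop.test`` convention), all two-sided.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return np.inf, float(x.size + y.size - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ks_2samp(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 10:
        logger.warning("KS asymptotic p is unreliable below n = 10 per group")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def two_prop_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> tuple[float, float]:
    """Two-sided test of equal proportions (chi-square with 1 df).

    Matches the 2x2 contingency chi-square with Yates continuity correction,
    the behavior of R's ``prop.test`` default; pass ``correction=False`` for
    the uncorrected pooled test. Returns (chi-square statistic, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = obs.sum()
    expect = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expect == 0).any():  # a margin is empty: proportions trivially equal
        return 0.0, 1.0
    dev = np.abs(obs - expect)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expect).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def predicted_h2_increase(slope: float, n_snps: float) -> float:
    """Predicted h2 increase at a window SNP count, from the fitted slope."""
    return slope * n_snps


# ---------------------------------------------------------------------------
# contextual summaries


def _group_frame(site_table: pd.DataFrame, density_groups=("island", "sea")) -> pd.Series:
    lab = site_table["density"].where(
        site_table["density"].isin(density_groups), other=None
    )
    return lab + "_" + site_table["genic"]


def context_summaries(
    site_table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Eight-group (and six density-class) summaries with pairwise tests.

    ``site_table`` holds one row per site with columns ``mean_m`` (per-site
    mean M-value), ``resvar`` (residual variance), ``h2``, ``p`` (mixture-LRT
    p), ``sigma_g2``, ``density`` and ``genic``. Returns the group summary
    table, the pairwise test table (Welch t and KS on mean_m, Welch t on
    resvar, two-proportion test on the heritable fraction) and the
    proportion-heritable vs mean-genetic-variance correlation within sea and
    island (computed over 4 points each; descriptive only).
    """
    tab = site_table.copy()
    tab["group"] = _group_frame(tab)
    tab["heritable"] = tab["p"] < alpha

    def _summarize(sub: pd.DataFrame, label: str) -> dict:
        sig = sub[sub["heritable"]]
        return {
            "group": label,
            "n_sites": len(sub),
            "mean_m": sub["mean_m"].mean(),
            "median_m": sub["mean_m"].median(),
            "var_m": sub["mean_m"].var(ddof=1) if len(sub) > 1 else np.nan,
            "mean_resvar": sub["resvar"].mean(),
            "prop_heritable": sub["heritable"].mean() if len(sub) else np.nan,
            "mean_h2_significant": sig["h2"].mean() if len(sig) else np.nan,
            "mean_sigma_g2": sub["sigma_g2"].mean(),
        }

    summaries = [
        _summarize(tab[tab["group"] == g], g)
        for g in sorted(tab["group"].dropna().unique())
    ]
    summaries += [
        _summarize(tab[tab["density"] == d], d)
        for d in sorted(tab["density"].unique())
    ]
    summary = pd.DataFrame(summaries)

    groups = sorted(tab["group"].dropna().unique())
    tests = []
    for ga, gb in itertools.combinations(groups, 2):
        a = tab[tab["group"] == ga]
        b = tab[tab["group"] == gb]
        row = {"group_a": ga, "group_b": gb}
        if len(a) >= 2 and len(b) >= 2:
            _, _, row["welch_p_mean"] = welch_t(a["mean_m"], b["mean_m"])
            _, row["ks_p_mean"] = ks_2samp(a["mean_m"], b["mean_m"])
            _, _, row["welch_p_resvar"] = welch_t(a["resvar"], b["resvar"])
            _, row["prop_p_heritable"] = two_prop_test(
                int(a["heritable"].sum()), len(a),
                int(b["heritable"].sum()), len(b),
            )
        else:
            row.update({k: np.nan for k in
                        ("welch_p_mean", "ks_p_mean", "welch_p_resvar",
                         "prop_p_heritable")})
        tests.append(row)

    corr = {}
    for dens in ("island", "sea"):
        pts = summary[summary["group"].str.startswith(f"{dens}_", na=False)]
        if len(pts) >= 3 and pts["prop_heritable"].notna().all():
            r = float(np.corrcoef(pts["prop_heritable"], pts["mean_sigma_g2"])[0, 1])
        else:
            r = np.nan
        corr[dens] = r
    return summary, pd.DataFrame(tests), corr


def h2_variance_partition(
    rh_results: pd.DataFrame,
    site_table: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """What predicts the size of a significant h2 estimate?

    Over significantly heritable sites: (a) OLS of h2 on window SNP count
    (slope, R^2, p); (b) OLS of h2 on residual variance (R^2, p); (c) a
    sequential (type I) ANOVA F-test for the contextual-group factor after
    residual variance. Needs >= 3 significant sites; returns None entries
    otherwise.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    merged = rh_results.merge(
        site_table[["id", "resvar", "density", "genic"]], on="id"
    )
    sig = merged[merged["p"] < alpha].copy()
    if len(sig) < 3:
        logger.warning("fewer than 3 significant sites; no regression fitted")
        return {"snp_count": None, "resvar": None, "context_anova": None,
                "n_significant": len(sig)}
    sig["group"] = sig["density"] + "_" + sig["genic"]

    fit_n = smf.ols("h2 ~ n_snps", data=sig).fit()
    fit_v = smf.ols("h2 ~ resvar", data=sig).fit()
    out = {
        "n_significant": int(len(sig)),
        "snp_count": {
            "slope": float(fit_n.params["n_snps"]),
            "r2": float(fit_n.rsquared),
            "p": float(fit_n.pvalues["n_snps"]),
        },
        "resvar": {
            "slope": float(fit_v.params["resvar"]),
            "r2": float(fit_v.rsquared),
            "p": float(fit_v.pvalues["resvar"]),
        },
    }
    if sig["group"].nunique() > 1:
        fit_c = smf.ols("h2 ~ resvar + C(group)", data=sig).fit()
        anova = anova_lm(fit_c, typ=1)
        out["context_anova"] = {
            "F": float(anova.loc["C(group)", "F"]),
            "p": float(anova.loc["C(group)", "PR(>F)"]),
        }
    else:
        out["context_anova"] = None
    return out


def risk_region_compare(
    rh_results: pd.DataFrame,
    risk_snps: pd.DataFrame,
    half_window: int = 1_000_000,
    alpha: float = 0.05,
) -> dict:
    """Heritability of sites within versus outwith disease risk regions.

    A risk region is +/- ``half_window`` bp around each risk SNP (boundary
    inclusive); sites are partitioned by overlap with the union of regions.
    Reports the heritable proportion and mean significant h2 per partition
    and the two-proportion test between them.
    """
    within = np.zeros(len(rh_results), dtype=bool)
    for snp in risk_snps.itertuples():
        within |= (
            (rh_results["chrom"].to_numpy() == snp.chrom)
            & (np.abs(rh_results["pos"].to_numpy() - snp.pos) <= half_window)
        )

    def _part(mask) -> dict:
        sub = rh_results[mask]
        sig = sub[sub["p"] < alpha]
        return {
            "n_sites": int(len(sub)),
            "n_heritable": int(len(sig)),
            "prop_heritable": float(len(sig) / len(sub)) if len(sub) else np.nan,
            "mean_h2_significant": float(sig["h2"].mean()) if len(sig) else np.nan,
        }

    res = {"within": _part(within), "outwith": _part(~within)}
    if res["within"]["n_sites"] and res["outwith"]["n_sites"]:
        chi2, p = two_prop_test(
            res["within"]["n_heritable"], res["within"]["n_sites"],
            res["outwith"]["n_heritable"], res["outwith"]["n_sites"],
        )
        res["prop_test"] = {"chi2": chi2, "p": p}
    else:
        res["prop_test"] = None
    return res
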