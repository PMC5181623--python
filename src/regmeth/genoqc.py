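"""Genotype quality control: sample call rate, the four successive SNP
filters (call rate, Hardy-Weinberg, MAF, differential missingness), the
X-chromosome inbreeding sex check, and genotype principal components."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeData
from .reml import standardize_genotypes

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Per-filter removal record; successive filters remove disjoint sets."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, threshold, removed_ids) -> None:
        removed_ids = list(removed_ids)
        seen = {i for s in self.steps for i in s["removed_ids"]}
        if seen & set(removed_ids):
            raise ValueError("filters must remove disjoint sets")
        self.steps.append(
            {"filter": name, "threshold": threshold, "removed_ids": removed_ids,
             "n_removed": len(removed_ids)}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"filter": s["filter"], "threshold": s["threshold"],
                 "n_removed": s["n_removed"],
                 "removed_ids": ",".join(map(str, s["removed_ids"]))}
                for s in self.steps
            ]
        )


def filter_sample_callrate(
    geno: GenotypeData, max_missing: float = 0.05
) -> tuple[GenotypeData, QcReport]:
    """Drop samples whose missing-genotype fraction exceeds ``max_missing``."""
    if geno.n_snps == 0:
        raise ValueError("empty dosage matrix")
    miss = np.isnan(geno.dosages).mean(axis=1)
    keep = miss <= max_missing
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    report = QcReport()
    report.add(
        "sample_callrate", max_missing,
        [s for s, k in zip(geno.samples, keep) if not k],
    )
    return geno.take_samples(np.flatnonzero(keep)), report


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of matching parity, the probabilities not exceeding that of the
    observed configuration (the standard exact HWE test). Monomorphic
    genotype tables return p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    # log P(het = h | allele counts) up to a shared constant
    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = []
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        logs.append(
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(hom_major + 1)
        )
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = list(hets).index(n_het)
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def snp_stats(geno: GenotypeData) -> pd.DataFrame:
    """Per-SNP missing rate, genotype counts, allele frequency and MAF."""
    d = geno.dosages
    miss = np.isnan(d).mean(axis=0)
    n0 = np.nansum(d == 0, axis=0)
    n1 = np.nansum(d == 1, axis=0)
    n2 = np.nansum(d == 2, axis=0)
    freq = geno.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    return pd.DataFrame(
        {"id": geno.snps["id"], "missing": miss, "n_hom_ref": n0, "n_het": n1,
         "n_hom_alt": n2, "alt_freq": freq, "maf": maf}
    )


def filter_snps(
    geno: GenotypeData,
    cc_labels=None,
    max_missing: float = 0.05,
    hwe_p: float = 1e-4,
    min_maf: float = 0.01,
    diff_miss_p: float = 1e-5,
) -> tuple[GenotypeData, QcReport]:
    """The four successive SNP filters, applied in the stated order.

    (i) call rate: missing in more than ``max_missing`` of samples;
    (ii) Hardy-Weinberg exact p below ``hwe_p``;
    (iii) minor allele frequency below ``min_maf``;
    (iv) missingness rate differing between cases and controls at
    ``diff_miss_p`` (two-proportion test; skipped when ``cc_labels`` is None).

    Each filter sees only the SNPs surviving the previous ones, so the
    per-filter removal counts in the report are attribution under that order.
    """
    from .groupstats import two_prop_test

    report = QcReport()
    ids = geno.snps["id"].to_numpy()
    alive = np.ones(geno.n_snps, dtype=bool)
    stats_df = snp_stats(geno)

    fail = alive & (stats_df["missing"].to_numpy() > max_missing)
    report.add("snp_callrate", max_missing, ids[fail])
    alive &= ~fail

    hwe = np.array(
        [
            hwe_exact_p(int(r.n_hom_ref), int(r.n_het), int(r.n_hom_alt))
            if alive[i] else 1.0
            for i, r in enumerate(stats_df.itertuples())
        ]
    )
    fail = alive & (hwe < hwe_p)
    report.add("hwe", hwe_p, ids[fail])
    alive &= ~fail

    fail = alive & (stats_df["maf"].to_numpy() < min_maf)
    report.add("maf", min_maf, ids[fail])
    alive &= ~fail

    if cc_labels is not None:
        cc = np.asarray(cc_labels)
        case = cc == 1
        fail = np.zeros_like(alive)
        for j in np.flatnonzero(alive):
            miss = np.isnan(geno.dosages[:, j])
            k1, n1 = int(miss[case].sum()), int(case.sum())
            k2, n2 = int(miss[~case].sum()), int((~case).sum())
            _, p = two_prop_test(k1, n1, k2, n2)
            if p < diff_miss_p:
                fail[j] = True
        report.add("diff_missingness", diff_miss_p, ids[fail])
        alive &= ~fail
    else:
        logger.info("no case/control labels: differential-missingness filter skipped")

    return geno.take_snps(np.flatnonzero(alive)), report


def x_inbreeding_f(
    x_geno: GenotypeData, sex: pd.Series | dict
) -> pd.DataFrame:
    """Per-sample X-chromosome inbreeding coefficient and sex-check flags.

    F = 1 - O(het)/E(het) with E(het) the sum of 2 p (1 - p) over the
    sample's non-missing X SNPs (p = sample alt-allele frequency). Samples
    recorded female with F > 0.98 or recorded male with F < 0.2 are flagged
    for removal (recorded and genetic sex disagree). Zero expected
    heterozygosity leaves F undefined (unevaluable).
    """
    freqs = x_geno.allele_freq()
    poly = (freqs > 0) & (freqs < 1)
    if poly.sum() < 50:
        logger.warning("only %d polymorphic X SNPs; F is unstable", int(poly.sum()))
    het_exp_snp = 2 * freqs * (1 - freqs)
    sex_map = sex if isinstance(sex, dict) else sex.to_dict()
    rows = []
    for i, sample in enumerate(x_geno.samples):
        d = x_geno.dosages[i]
        obs_mask = ~np.isnan(d)
        o_het = float((d[obs_mask] == 1).sum())
        e_het = float(het_exp_snp[obs_mask].sum())
        if e_het == 0:
            rows.append({"sample": sample, "F": np.nan, "flag": "unevaluable"})
            continue
        f = 1.0 - o_het / e_het
        recorded = str(sex_map.get(sample, "")).lower()
        flag = ""
        if recorded in ("f", "female", "2") and f > 0.98:
            flag = "remove"
        elif recorded in ("m", "male", "1") and f < 0.2:
            flag = "remove"
        rows.append({"sample": sample, "F": f, "flag": flag})
    return pd.DataFrame(rows)


def genotype_pcs(geno: GenotypeData, k: int) -> np.ndarray:
    """Top-k genotype principal-component scores (samples x k).

    Dosages are standardized with mean imputation of missing calls; scores
    are left singular vectors scaled by singular values. The sign of each
    component is fixed by making its largest-magnitude SNP loading positive.
    """
    if k == 0:
        return np.zeros((geno.n_samples, 0))
    if geno.n_samples < k + 1:
        raise ValueError("need at least k + 1 samples")
    W, _ = standardize_genotypes(geno.dosages)
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
    if k > rank:
        raise ValueError(f"k = {k} exceeds genotype matrix rank {rank}")
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores
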