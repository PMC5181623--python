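"""End-to-end driver: genotype QC -> methylation prep -> annotation ->
regional heritability scan -> GWAS -> contextual summaries."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, assoc, genoqc, groupstats, io, methprep, scan
from .data import CovariateTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated paths and knobs for a full run."""

    vcf: str
    meth: str
    out_dir: str
    covar: str | None = None
    detp: str | None = None
    islands_bed: str | None = None
    genes: str | None = None
    exclude: str | None = None
    risk_snps: str | None = None
    sex: str | None = None
    meth_scale: str = "beta"
    half_window: int = 1_000_000
    alpha: float = 0.05
    thresholds: tuple = (5e-2, 5e-4, 5e-8)
    covariate_mode: str = "fixed"  # fixed | residualize
    n_pcs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.covariate_mode not in ("fixed", "residualize"):
            raise ValueError("covariate_mode must be 'fixed' or 'residualize'")
        for name in ("vcf", "meth", "covar", "detp", "islands_bed", "genes",
                     "exclude", "risk_snps", "sex"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order, writing artifacts under ``out_dir``.

    Any stage failure raises with the stage name attached. Returns the
    manifest (inputs, digests, per-stage counts, headline summary).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    for name in ("vcf", "meth", "covar", "detp", "islands_bed", "genes",
                 "exclude", "risk_snps"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256_16": _digest(p)}

    stage = "geno_qc"
    try:
        geno = io.read_vcf(config.vcf)
        geno, samp_report = genoqc.filter_sample_callrate(geno)
        geno, snp_report = genoqc.filter_snps(geno)
        report = pd.concat([samp_report.to_frame(), snp_report.to_frame()])
        io.write_table(report, out / "geno_qc_report.tsv")
        manifest["stages"][stage] = {
            "n_samples": geno.n_samples, "n_snps": geno.n_snps,
        }

        stage = "meth_prep"
        meth = io.read_meth_tsv(config.meth, scale=config.meth_scale)
        if config.detp:
            detp = io.read_matrix_tsv(config.detp)
            keep = methprep.detection_filter_sites(
                detp.to_numpy().T  # stored sites x samples
            )
            meth = meth.take_sites(np.flatnonzero(keep))
        if config.exclude:
            ids = [l.strip() for l in open(config.exclude) if l.strip()]
            meth = methprep.exclusion_filter(meth, ids)
        meth = methprep.to_m_scale(meth)
        covars = io.read_covariates(config.covar) if config.covar else None
        common = io.check_sample_alignment(
            *( [geno, meth] + ([covars] if covars else []) )
        )
        geno = geno.take_samples([geno.samples.index(s) for s in common])
        meth = meth.take_samples([meth.samples.index(s) for s in common])
        if covars is not None:
            covars = CovariateTable(
                covars.table.loc[common], categorical=covars.categorical
            )
            if config.n_pcs:
                pcs = genoqc.genotype_pcs(geno, config.n_pcs)
                for k in range(config.n_pcs):
                    covars.table[f"pc{k + 1}"] = pcs[:, k]
        if covars is not None:
            resid, resvar = methprep.residualize(meth, covars)
        else:
            resid = meth
            resvar = meth.values.var(axis=0, ddof=1)
        io.write_meth_tsv(resid, out / "meth_residuals.tsv")
        manifest["stages"][stage] = {
            "n_sites": meth.n_sites, "n_samples": meth.n_samples,
        }

        stage = "annotate"
        if config.islands_bed:
            islands = io.read_bed(config.islands_bed, name_prefix="isl")
        else:
            islands = annotate.IntervalSet.from_records([])
        genes = io.read_gene_table(config.genes) if config.genes else []
        expressed = {g.gene_id for g in genes if g.expressed_wcb}
        contexts = annotate.annotate_sites(meth.sites, islands, genes, expressed)
        io.write_table(contexts, out / "site_contexts.tsv")
        manifest["stages"][stage] = {"n_islands": len(islands), "n_genes": len(genes)}

        stage = "rh_scan"
        scan_covars = covars if config.covariate_mode == "fixed" else None
        scan_meth = meth if config.covariate_mode == "fixed" else resid
        rh, rh_summary = scan.rh_scan(
            scan_meth, geno, scan_covars,
            half_window=config.half_window, alpha=config.alpha,
            covariate_mode="fixed" if scan_covars is not None else "none",
        )
        io.write_table(rh, out / "rh_results.tsv")
        manifest["stages"][stage] = rh_summary

        stage = "gwas"
        assoc_table, assoc_summary = assoc.gwas_scan(
            resid, geno, thresholds=config.thresholds,
            cis_window=config.half_window,
        )
        io.write_table(assoc_table, out / "gwas_results.tsv")
        io.write_table(assoc_summary, out / "gwas_summary.tsv")
        manifest["stages"][stage] = {"n_pairs": int(len(assoc_table))}

        stage = "summarize"
        site_table = contexts.merge(rh[["id", "h2", "p", "sigma_g2"]], on="id")
        site_table["mean_m"] = [
            resid.values[:, list(resid.sites["id"]).index(i)].mean()
            + (meth.values[:, list(meth.sites["id"]).index(i)].mean()
               if config.covariate_mode == "fixed" else 0.0)
            for i in site_table["id"]
        ]
        site_table["resvar"] = [
            resvar[list(meth.sites["id"]).index(i)] for i in site_table["id"]
        ]
        summary, tests, corr = groupstats.context_summaries(
            site_table, alpha=config.alpha
        )
        io.write_table(summary, out / "context_summary.tsv")
        io.write_table(tests, out / "context_tests.tsv")
        partition = groupstats.h2_variance_partition(
            rh, site_table, alpha=config.alpha
        )
        results = {"scan": rh_summary, "fig9_correlation": corr,
                   "h2_partition": partition}
        if config.risk_snps:
            risk = pd.read_csv(config.risk_snps, sep="\t", dtype={"chrom": str})
            results["risk_regions"] = groupstats.risk_region_compare(
                rh, risk, half_window=config.half_window, alpha=config.alpha
            )
        manifest["stages"][stage] = {"n_groups": int(len(summary))}
        manifest["summary"] = results
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
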