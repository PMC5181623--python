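"""File-format boundary: VCF, BED, TSV matrices and result writers.

Conventions: 1-based point coordinates internally (as in VCF), 0-based
half-open intervals (as in BED), converted only here. Matrix TSVs carry
sites as rows and samples as columns with a header row of sample ids.
Writers are deterministic (sorted keys, %.6g floats).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel, IntervalSet
from .data import CovariateTable, GenotypeData, MethylationData

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeData:
    """Genotypes from a VCF (diploid GT; '.' = missing; multi-allelic
    records are skipped with a logged count)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    records, dosage_cols = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = missing
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan
        records.append(
            {"chrom": var.CHROM, "pos": var.POS, "id": var.ID or f"{var.CHROM}:{var.POS}",
             "ref": var.REF, "alt": var.ALT[0]}
        )
        dosage_cols.append(g)
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not records:
        raise ValueError(f"no usable biallelic records in {path}")
    snps = pd.DataFrame(records)
    return GenotypeData(samples, snps, np.column_stack(dosage_cols))


def write_vcf(geno: GenotypeData, path) -> None:
    """Minimal VCF 4.2 with GT-only genotypes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples) + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(geno.snps.itertuples()):
            calls = [
                "./." if np.isnan(d) else gt_map[d] for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# BED and gene models


def read_bed(path, name_prefix: str = "iv") -> IntervalSet:
    """BED (0-based half-open) into an IntervalSet."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
    )
    if df["name"].isna().any():
        df["name"] = [f"{name_prefix}{i}" for i in range(len(df))]
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> list:
    """Gene models from a TSV: gene_id, chrom, strand, tss (1-based), length,
    expressed_wcb, expressed_lcm."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneModel.from_tss(
            r.gene_id, r.chrom, r.strand, int(r.tss) - 1, int(r.length),
            bool(r.expressed_wcb), bool(r.expressed_lcm),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes, path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "tss": g.tss + 1,
             "length": max(e for _, e in g.regions.values())
             - min(s for s, _ in g.regions.values())
             - 1500,  # regulatory upstream flank excluded from gene length
             "expressed_wcb": g.expressed_wcb, "expressed_lcm": g.expressed_lcm}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices and tables


def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature x sample TSV with a header of sample ids and an index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_meth_tsv(meth: MethylationData, path) -> None:
    """Sites as rows, samples as columns; site coordinates as extra columns."""
    df = pd.DataFrame(
        meth.values.T, index=meth.sites["id"], columns=meth.samples
    )
    df.insert(0, "chrom", meth.sites["chrom"].to_numpy())
    df.insert(1, "pos", meth.sites["pos"].to_numpy())
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="id")


def read_meth_tsv(path, scale: str = "M") -> MethylationData:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    sites = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["pos"].astype(int), "id": df.index}
    ).reset_index(drop=True)
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    values = df[samples].to_numpy(dtype=float).T
    return MethylationData(samples, sites, values, scale=scale)


def read_covariates(path, categorical=("sex", "batch", "diagnosis", "side")) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cats = tuple(c for c in categorical if c in df.columns)
    return CovariateTable(df, categorical=cats)


def write_covariates(covars: CovariateTable, path) -> None:
    covars.table.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def check_sample_alignment(*objs) -> list:
    """Common sample ids across inputs; raises listing any mismatch."""
    sets = [list(o.samples) if hasattr(o, "samples") else list(o.table.index) for o in objs]
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    if not common:
        raise ValueError("no samples shared across inputs")
    missing = [sorted(set(s) ^ common)[:5] for s in sets if set(s) != common]
    if missing:
        logger.warning("sample sets differ across inputs; e.g. %s", missing[0])
    return [s for s in sets[0] if s in common]
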