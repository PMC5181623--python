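"""Synthetic genotypes, annotation, covariates and methylation with known truth.

The generator emulates the data the analysis expects: Hardy-Weinberg
genotypes with short-range LD, CpG islands and schematic gene models laid
out so every simulated site lands in a requested contextual group, expression
detection matrices defining the expressed-gene sets, and M-scale methylation
generated under the analysis model itself,

    y = X beta + W u + e,

with the realized genetic variance fraction pinned exactly to the drawn true
local h2. The returned truth table (true h2, causal SNPs and effects,
context per site) is the oracle for parameter-recovery and calibration
tests.

Geometry: each site owns a 30 kb slot; a site's island (if any) is centred
on it and its gene (if any) is placed so the site falls in the intended
sub-region. Slots are far enough apart that contexts never interfere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModel, IntervalSet
from .data import CovariateTable, GenotypeData, MethylationData

logger = logging.getLogger(__name__)

SLOT_BP = 30_000
MARGIN_BP = 1_050_000  # keeps full-width SNP windows for every site

DENSITY_GROUPS = ("island", "sea")
GENIC_GROUPS = ("tss_expressed", "tss_not_expressed", "intragenic", "intergenic")
CONTEXT_GROUPS = tuple(f"{d}_{g}" for d in DENSITY_GROUPS for g in GENIC_GROUPS)


def _uniform_mix() -> dict:
    return {c: 1.0 / len(CONTEXT_GROUPS) for c in CONTEXT_GROUPS}


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions.

    n_samples 132 and maf_range (0.05, 0.5) with ~300 SNPs per +/- 1 Mb
    window (snp_density 1.5e-4/bp) match the cohort the analysis was built
    for; ld_rho sets adjacent-haplotype copying, h2_dist the true local
    heritability per context (point mass or Beta), covariate_effects the
    fixed effects on the M scale. ``seed`` is mandatory.
    """

    seed: int
    n_samples: int = 132
    chrom: str = "chr1"
    chrom_length: int | None = None  # None: sized from n_sites
    snp_density: float = 1.5e-4
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.3
    n_sites: int = 200
    context_mix: dict = field(default_factory=_uniform_mix)
    h2_dist: dict = field(default_factory=lambda: {"default": ("point", 0.3)})
    n_causal_per_site: int = 3
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.3, "age": 0.004, "batch": 0.25, "side": 0.1}
    )
    missing_rate: float = 0.0
    island_halfwidth: int = 500
    gene_length: int = 5_000
    max_genes: int | None = None
    n_lcm_only: int = 10
    n_expr_samples: dict = field(default_factory=lambda: {"wcb": 11, "lcm": 9})
    detection_p: float = 0.01

    def __post_init__(self) -> None:
        total = sum(self.context_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"context_mix proportions sum to {total}, not 1")
        unknown = set(self.context_mix) - set(CONTEXT_GROUPS)
        if unknown:
            raise ValueError(f"unknown context groups: {sorted(unknown)}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        tss_mass = sum(
            p for c, p in self.context_mix.items() if "tss" in c and p > 0
        )
        if self.max_genes == 0 and tss_mass > 0:
            raise ValueError(
                "context_mix requests TSS contexts but max_genes is 0"
            )
        if self.chrom_length is None:
            self.chrom_length = 2 * MARGIN_BP + self.n_sites * SLOT_BP
        if self.chrom_length <= 10_000:
            raise ValueError("chrom_length must exceed 10 kb")
        need = 2 * MARGIN_BP + self.n_sites * SLOT_BP
        if self.chrom_length < need:
            raise ValueError(
                f"chrom_length {self.chrom_length} too short for {self.n_sites} "
                f"sites; need >= {need}"
            )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class Annotation:
    """Simulated genome annotation plus the per-site placement plan."""

    islands: IntervalSet
    genes: list
    expressed_wcb: set
    expressed_lcm: set
    site_plan: pd.DataFrame  # id, chrom, pos (1-based), density, genic


def sim_annotation(config: SimConfig) -> Annotation:
    """Lay out islands, genes and expressed-gene sets for every site slot.

    Contexts are drawn from ``context_mix``; each site's slot receives an
    island centred on the site (island contexts) and/or a gene positioned so
    the site falls in TSS200 (TSS contexts) or the gene body (intragenic).
    The LCM expressed set is a subset of the WCB set apart from
    ``n_lcm_only`` genes private to the epithelial condition.
    """
    rng = config._rng(0)
    contexts = rng.choice(
        list(config.context_mix), size=config.n_sites,
        p=list(config.context_mix.values()),
    )
    islands, genes = [], []
    rows = []
    n_genes = 0
    for i, ctx in enumerate(contexts):
        dens, genic = ctx.split("_", 1)
        c = MARGIN_BP + i * SLOT_BP + SLOT_BP // 2  # 0-based site position
        if dens == "island":
            islands.append(
                (config.chrom, c - config.island_halfwidth,
                 c + config.island_halfwidth, f"isl{i:05d}")
            )
        if genic in ("tss_expressed", "tss_not_expressed"):
            if config.max_genes is not None and n_genes >= config.max_genes:
                raise ValueError("max_genes too small for the requested contexts")
            genes.append(
                GeneModel.from_tss(
                    f"gene{i:05d}", config.chrom, "+", c + 100,
                    config.gene_length,
                    expressed_wcb=(genic == "tss_expressed"),
                )
            )
            n_genes += 1
        elif genic == "intragenic":
            if config.max_genes is None or n_genes < config.max_genes:
                genes.append(
                    GeneModel.from_tss(
                        f"gene{i:05d}", config.chrom, "+", c - 1600,
                        config.gene_length,
                        expressed_wcb=bool(rng.integers(2)),
                    )
                )
                n_genes += 1
        rows.append(
            {"id": f"cg{i:06d}", "chrom": config.chrom, "pos": c + 1,
             "density": dens, "genic": genic}
        )
    # epithelial-only genes live in the left margin, far from every site
    for j in range(config.n_lcm_only):
        genes.append(
            GeneModel.from_tss(
                f"lcm{j:03d}", config.chrom, "+",
                100_000 + j * (config.gene_length + 2_000),
                config.gene_length, expressed_wcb=False, expressed_lcm=True,
            )
        )
    wcb = {g.gene_id for g in genes if g.expressed_wcb}
    lcm_shared = {g for k, g in enumerate(sorted(wcb)) if k % 2 == 0}
    lcm = lcm_shared | {g.gene_id for g in genes if g.expressed_lcm}
    for g in genes:
        g.expressed_lcm = g.gene_id in lcm
    return Annotation(
        islands=IntervalSet.from_records(islands).merged(),
        genes=genes,
        expressed_wcb=wcb,
        expressed_lcm=lcm,
        site_plan=pd.DataFrame(rows),
    )


def sim_genotypes(config: SimConfig) -> tuple[GenotypeData, np.ndarray]:
    """HWE genotypes with first-order haplotype-copying LD.

    Haplotype alleles along the chromosome copy the previous SNP's allele
    with probability ``ld_rho`` and otherwise draw fresh from Bernoulli(p_j),
    p_j ~ Uniform(maf_range). Dosage is the sum of two independent
    haplotypes. Returns the data plus each SNP's true marginal allele
    frequency under the copying chain (q_j = rho q_{j-1} + (1-rho) p_j).
    """
    rng = config._rng(1)
    n_snps = max(int(round(config.chrom_length * config.snp_density)), 1)
    pos = np.sort(
        rng.choice(np.arange(1, config.chrom_length + 1), size=n_snps, replace=False)
    )
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    n_hap = 2 * config.n_samples
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < p[0]
    true_freq = np.empty(n_snps)
    true_freq[0] = p[0]
    for j in range(1, n_snps):
        copy = rng.random(n_hap) < config.ld_rho
        fresh = rng.random(n_hap) < p[j]
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        true_freq[j] = config.ld_rho * true_freq[j - 1] + (1 - config.ld_rho) * p[j]
    dosages = (hap[0::2] + hap[1::2]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    snps = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos,
         "id": [f"snp{j:06d}" for j in range(n_snps)],
         "ref": "A", "alt": "G"}
    )
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    return GenotypeData(samples, snps, dosages), true_freq


def sim_covariates(config: SimConfig) -> CovariateTable:
    """Sex ~ Bern(0.5), age ~ U(30, 80), batch ~ cat(4), side ~ Bern(0.5)."""
    rng = config._rng(2)
    n = config.n_samples
    table = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(30, 80, n),
            "batch": rng.integers(0, 4, n).astype(str),
            "side": np.where(rng.integers(0, 2, n) == 1, "right", "left"),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample"),
    )
    return CovariateTable(table)


def _covariate_shift(config: SimConfig, covars: CovariateTable) -> np.ndarray:
    """Fixed-effect contribution X beta on the M scale, per sample."""
    t = covars.table
    eff = config.covariate_effects
    shift = np.zeros(len(t))
    shift += eff.get("sex", 0.0) * t["sex"].to_numpy(dtype=float)
    shift += eff.get("age", 0.0) * (t["age"].to_numpy(dtype=float) - 55.0)
    shift += eff.get("batch", 0.0) * t["batch"].to_numpy(dtype=float)
    shift += eff.get("side", 0.0) * (t["side"] == "right").to_numpy(dtype=float)
    return shift


def _draw_h2(config: SimConfig, context: str, rng: np.random.Generator) -> float:
    spec = config.h2_dist.get(context, config.h2_dist.get("default", ("point", 0.3)))
    kind = spec[0]
    if kind == "point":
        h2 = float(spec[1])
    elif kind == "beta":
        h2 = float(rng.beta(spec[1], spec[2]))
    else:
        raise ValueError(f"unknown h2 distribution kind {kind!r}")
    if not 0 <= h2 < 1:
        raise ValueError(f"true h2 must lie in [0, 1), got {h2}")
    return h2


def sim_methylation(
    geno: GenotypeData,
    annot: Annotation,
    config: SimConfig,
    half_window: int = 1_000_000,
) -> tuple[MethylationData, CovariateTable, pd.DataFrame]:
    """M-scale methylation under y = X beta + W u + e, with truth recorded.

    Per site: true h2 is drawn for its context, causal SNPs are sampled from
    the +/- ``half_window`` cis window, effects u ~ N(0, 1) are rescaled so
    the realized genetic variance is exactly h2 of a unit phenotypic
    variance, and noise (orthogonalized against the genetic value) supplies
    the remaining 1 - h2. Covariate effects are then added on top.
    """
    rng = config._rng(3)
    covars = sim_covariates(config)
    shift = _covariate_shift(config, covars)
    n = geno.n_samples
    plan = annot.site_plan
    values = np.empty((n, len(plan)))
    truth_rows = []
    snp_pos = geno.snps["pos"].to_numpy()
    snp_ids = geno.snps["id"].to_numpy()
    for k, rec in enumerate(plan.itertuples()):
        h2 = _draw_h2(config, f"{rec.density}_{rec.genic}", rng)
        widx = np.flatnonzero(
            (geno.snps["chrom"].to_numpy() == rec.chrom)
            & (snp_pos >= rec.pos - half_window)
            & (snp_pos <= rec.pos + half_window)
        )
        n_causal = min(config.n_causal_per_site, widx.size)
        if n_causal < config.n_causal_per_site:
            logger.warning(
                "site %s window has %d SNPs < %d causal requested; reduced",
                rec.id, widx.size, config.n_causal_per_site,
            )
        causal = np.sort(rng.choice(widx, size=n_causal, replace=False)) if n_causal else np.array([], dtype=int)
        e = rng.standard_normal(n)
        g = np.zeros(n)
        u = np.array([])
        if h2 > 0 and n_causal:
            u = rng.standard_normal(n_causal)
            dos = geno.dosages[:, causal]
            dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
            g = (dos - dos.mean(axis=0)) @ u
            var_g = g.var(ddof=0)
            if var_g > 0:
                scale = np.sqrt(h2 / var_g)
                g *= scale
                u *= scale
            else:
                logger.warning("site %s: causal SNPs monomorphic; h2 set to 0", rec.id)
                h2, u = 0.0, u * 0.0
        # noise orthogonal to the genetic value, variance exactly 1 - h2
        e -= e.mean()
        if h2 > 0 and g.std() > 0:
            gc = g - g.mean()
            e -= gc * (e @ gc) / (gc @ gc)
        sd = e.std(ddof=0)
        e *= np.sqrt(1.0 - h2) / sd if sd > 0 else 0.0
        values[:, k] = shift + g + e
        truth_rows.append(
            {"id": rec.id, "chrom": rec.chrom, "pos": rec.pos, "true_h2": h2,
             "causal_snps": ",".join(snp_ids[causal]),
             "causal_effects": ",".join(f"{b:.17g}" for b in u),
             "density": rec.density, "genic": rec.genic}
        )
    meth = MethylationData(
        geno.samples, plan[["chrom", "pos", "id"]].copy(), values, scale="M"
    )
    return meth, covars, pd.DataFrame(truth_rows)


def sim_expression_detp(
    annot: Annotation, config: SimConfig
) -> dict[str, tuple[pd.DataFrame, dict]]:
    """Detection p-value matrices for the WCB and LCM expression conditions.

    Expressed genes get detection p < ``detection_p`` in at least the
    qualifying number of samples (strict >80% rule); non-expressed genes
    always fall short of it. Returns, per condition, the samples x probes
    matrix and the probe-to-gene map.
    """
    from .annotate import min_detect_count

    rng = config._rng(4)
    out = {}
    for cond, expressed in (("wcb", annot.expressed_wcb), ("lcm", annot.expressed_lcm)):
        n = config.n_expr_samples[cond]
        need = min_detect_count(n)
        probes, cols = {}, {}
        for g in annot.genes:
            probe = f"pr_{g.gene_id}"
            probes[probe] = g.gene_id
            k = (
                int(rng.integers(need, n + 1))
                if g.gene_id in expressed
                else int(rng.integers(0, need))
            )
            p = rng.uniform(config.detection_p, 1.0, size=n)
            hit = rng.choice(n, size=k, replace=False)
            p[hit] = rng.uniform(0.0, config.detection_p * 0.9, size=k)
            cols[probe] = p
        detp = pd.DataFrame(
            cols, index=[f"E{cond}{i:02d}" for i in range(n)]
        )
        out[cond] = (detp, probes)
    return out


def simulate_dataset(config: SimConfig, half_window: int = 1_000_000):
    """Full bundle: annotation, genotypes, methylation, covariates, truth."""
    annot = sim_annotation(config)
    geno, true_freq = sim_genotypes(config)
    meth, covars, truth = sim_methylation(geno, annot, config, half_window)
    detp = sim_expression_detp(annot, config)
    return {
        "annotation": annot,
        "genotypes": geno,
        "true_freq": true_freq,
        "methylation": meth,
        "covariates": covars,
        "truth": truth,
        "expression_detp": detp,
    }
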