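"""CpG-density and genic-context annotation of methylation sites.

Two independent axes classify every CpG site:

* density — island / north shore / south shore / north shelf / south shelf /
  sea, by distance from the nearest CpG island. Islands are maximal runs of
  adjacent 500 bp genome sections with C+G density > 50% and an observed to
  expected CpG-dinucleotide ratio > 0.60. Shores reach 2 kb from an island
  edge, shelves 2-4 kb, and everything further is sea. North/south means
  lower/higher genomic coordinate (genome orientation, not gene strand).
* genic — TSS of an expressed gene / TSS of a non-expressed gene /
  intragenic / intergenic, resolved by successive filters in that order so
  the four classes are mutually exclusive. TSS200 and TSS1500 are the
  0-200 bp and 200-1500 bp stretches upstream (5' on the gene's strand) of
  the transcription start site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECTION = 500
SHORE_BP = 2_000
SHELF_BP = 4_000

DENSITY_CLASSES = ("island", "shoreN", "shoreS", "shelfN", "shelfS", "sea")
GENIC_CLASSES = ("tss_expressed", "tss_not_expressed", "intragenic", "intergenic")

TSS_REGIONS = ("tss200", "tss1500")
GENE_BODY_REGIONS = ("utr5", "first_exon", "body", "utr3")


@dataclass
class IntervalSet:
    """Sorted, merged genomic intervals (chrom, 0-based half-open)."""

    df: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals need start < end")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        return cls(pd.DataFrame(records, columns=["chrom", "start", "end", "name"]))

    def merged(self) -> "IntervalSet":
        """Union of overlapping or book-ended intervals, per chromosome."""
        rows = []
        for chrom, grp in self.df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e, f"{chrom}:{cur_s}-{cur_e}"))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e, f"{chrom}:{cur_s}-{cur_e}"))
        return IntervalSet.from_records(rows)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneModel:
    """One gene: TSS-anchored regulatory and body sub-intervals.

    Sub-intervals are 0-based half-open on the genome. ``tss200`` abuts the
    TSS on its upstream (5') side and ``tss1500`` abuts ``tss200``; for a
    minus-strand gene upstream means higher coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based position of the transcription start
    regions: dict = field(default_factory=dict)
    expressed_wcb: bool = False
    expressed_lcm: bool = False

    @classmethod
    def from_tss(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        tss: int,
        length: int,
        expressed_wcb: bool = False,
        expressed_lcm: bool = False,
    ) -> "GeneModel":
        """Build a schematic gene of ``length`` bp downstream of the TSS.

        Layout (plus strand): tss1500 | tss200 | TSS | 5'UTR(100) |
        first exon(200) | body | 3'UTR(200); minus strand mirrors it.
        """
        if length < 600:
            raise ValueError("gene length must cover UTRs, first exon and body")
        if strand == "+":
            regions = {
                "tss1500": (tss - 1500, tss - 200),
                "tss200": (tss - 200, tss),
                "utr5": (tss, tss + 100),
                "first_exon": (tss + 100, tss + 300),
                "body": (tss + 300, tss + length - 200),
                "utr3": (tss + length - 200, tss + length),
            }
        elif strand == "-":
            regions = {
                "tss1500": (tss + 201, tss + 1501),
                "tss200": (tss + 1, tss + 201),
                "utr5": (tss - 99, tss + 1),
                "first_exon": (tss - 299, tss - 99),
                "body": (tss - length + 201, tss - 299),
                "utr3": (tss - length + 1, tss - length + 201),
            }
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return cls(gene_id, chrom, strand, tss, regions, expressed_wcb, expressed_lcm)

    def covers(self, pos: int, region_names) -> bool:
        """True if 0-based ``pos`` falls in any named sub-interval."""
        return any(
            s <= pos < e
            for name in region_names
            for s, e in [self.regions[name]]
            if name in self.regions
        )


# ---------------------------------------------------------------------------
# island calling from sequence


def call_islands(seq: str, chrom: str = "chr1", offset: int = 0) -> IntervalSet:
    """Call CpG islands from genomic sequence.

    The genome is tiled in consecutive non-overlapping 500 bp sections framed
    from coordinate 0 (so the result does not depend on where the input
    sequence was split, provided ``offset`` is the sequence's genomic start).
    A section qualifies iff (C+G)/500 > 0.5 and the observed/expected CpG
    ratio (N_CpG * 500) / (N_C * N_G) > 0.60; maximal runs of adjacent
    qualifying sections merge into islands. Sections containing N never
    qualify.
    """
    seq = seq.upper()
    first = offset + (-offset) % SECTION  # first full frame at a multiple of 500
    if first != offset:
        logger.info("sequence start %d not frame-aligned; leading bases ignored", offset)
    qualifying = []
    for start in range(first, offset + len(seq) - SECTION + 1, SECTION):
        sec = seq[start - offset : start - offset + SECTION]
        if "N" in sec:
            logger.info("section at %d contains N; treated as non-qualifying", start)
            continue
        n_c = sec.count("C")
        n_g = sec.count("G")
        n_cpg = sec.count("CG")
        gc = (n_c + n_g) / SECTION
        if gc <= 0.5 or n_c == 0 or n_g == 0:
            continue
        obs_exp = n_cpg * SECTION / (n_c * n_g)
        if obs_exp > 0.60:
            qualifying.append((chrom, start, start + SECTION, "island"))
    return IntervalSet.from_records(qualifying).merged()


# ---------------------------------------------------------------------------
# density classification


def density_class(pos: int, islands: IntervalSet, chrom: str | None = None):
    """Density class and signed distance to the nearest island edge.

    ``pos`` shares the islands' 0-based coordinate space. Distance is
    negative upstream (north, lower coordinates) and positive downstream
    (south); 0 inside an island. Ties between two equally near islands are
    broken toward the upstream side (the site is called north of the
    downstream island).
    """
    df = islands.df
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    if not len(df):
        return "sea", math.nan
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    inside = (starts <= pos) & (pos < ends)
    if inside.any():
        return "island", 0
    # gap to the nearest island on each side
    up = starts[starts > pos]  # islands downstream of the site; site is north
    down = ends[ends <= pos]  # islands upstream of the site; site is south
    d_north = int(up.min() - pos) if up.size else None
    d_south = int(pos - down.max()) if down.size else None
    if d_south is None or (d_north is not None and d_north <= d_south):
        dist, signed = d_north, -d_north
        label = "shoreN" if dist <= SHORE_BP else "shelfN" if dist <= SHELF_BP else "sea"
    else:
        dist, signed = d_south, d_south
        label = "shoreS" if dist < SHORE_BP else "shelfS" if dist < SHELF_BP else "sea"
    if label == "sea":
        return "sea", signed
    return label, signed


# ---------------------------------------------------------------------------
# expression calls


def min_detect_count(n_samples: int, min_frac: float = 0.8) -> int:
    """Smallest count strictly exceeding ``min_frac`` of ``n_samples``
    (e.g. 9 of 11, 8 of 9, 9 of 10 at the 80% rule)."""
    return int(math.floor(min_frac * n_samples + 1e-9)) + 1


def expressed_gene_calls(
    detp: pd.DataFrame,
    probe_to_gene: dict,
    p_thresh: float = 0.01,
    min_frac: float = 0.8,
) -> set:
    """Genes detected above background in more than ``min_frac`` of samples.

    ``detp`` is samples x probes of detection p-values. A probe qualifies iff
    strictly more than ``min_frac`` of samples have p < ``p_thresh``; a gene
    is expressed iff at least one of its probes qualifies. Probes without a
    gene mapping are dropped (count logged).
    """
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must lie in (0, 1)")
    need = min_detect_count(len(detp), min_frac)
    unmapped = [p for p in detp.columns if p not in probe_to_gene]
    if unmapped:
        logger.info("%d probes lack a gene mapping and are ignored", len(unmapped))
    counts = (detp < p_thresh).sum(axis=0)
    expressed = {
        probe_to_gene[probe]
        for probe, c in counts.items()
        if probe in probe_to_gene and c >= need
    }
    return expressed


# ---------------------------------------------------------------------------
# genic classification


def genic_class(pos: int, genes, expressed: set) -> str:
    """Mutually exclusive genic context by successive filters.

    Order: TSS (TSS200/TSS1500) of an expressed gene; TSS of any gene;
    within 5'UTR / first exon / body / 3'UTR of any gene; else intergenic.
    ``pos`` is 0-based genomic. Gene list order never matters: each tier is
    evaluated over the whole set before falling through.
    """
    in_tss = [g for g in genes if g.covers(pos, TSS_REGIONS)]
    if any(g.gene_id in expressed for g in in_tss):
        return "tss_expressed"
    if in_tss:
        return "tss_not_expressed"
    if any(g.covers(pos, GENE_BODY_REGIONS) for g in genes):
        return "intragenic"
    return "intergenic"


def annotate_sites(
    sites: pd.DataFrame,
    islands: IntervalSet,
    genes,
    expressed: set,
) -> pd.DataFrame:
    """Per-site context table: density class, genic class, signed distance.

    ``sites`` needs columns chrom, pos (1-based cytosine coordinate), id.
    """
    rows = []
    for rec in sites.itertuples():
        pos0 = int(rec.pos) - 1
        dens, dist = density_class(pos0, islands, chrom=rec.chrom)
        gen = genic_class(
            pos0, [g for g in genes if g.chrom == rec.chrom], expressed
        )
        rows.append(
            {"id": rec.id, "chrom": rec.chrom, "pos": rec.pos,
             "density": dens, "genic": gen, "island_distance": dist}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance-from-island profile


def distance_profile(
    site_means: np.ndarray,
    signed_distances: np.ndarray,
    bin_bp: int = 100,
    span_bp: int = 4_000,
) -> pd.DataFrame:
    """Mean methylation as a function of signed distance from island edges.

    The +/- ``span_bp`` flanks are divided into ``bin_bp`` bins (40 north +
    40 south by default). Each emitted bin carries the mean of the per-site
    mean values within it and the standard error sd/sqrt(n); empty bins have
    missing mean and bins with a single site a missing standard error.
    """
    site_means = np.asarray(site_means, dtype=float)
    d = np.asarray(signed_distances, dtype=float)
    edges = np.arange(-span_bp, span_bp + bin_bp, bin_bp)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        # inner edge of each flank is exclusive at 0 (0 = inside an island)
        sel = (d >= lo) & (d < hi) & (d != 0)
        n = int(sel.sum())
        vals = site_means[sel]
        mean = float(vals.mean()) if n else math.nan
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append(
            {"bin_start": int(lo), "bin_end": int(hi), "n_sites": n,
             "mean": mean, "se": se}
        )
    return pd.DataFrame(rows)
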