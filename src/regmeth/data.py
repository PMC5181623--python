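"""Core in-memory containers for genotype and methylation matrices.

Conventions: sample-major matrices (samples x features), 1-based point
coordinates for SNPs and CpG cytosines, ``numpy.nan`` for missing dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
SITE_COLUMNS = ["chrom", "pos", "id"]


@dataclass
class GenotypeData:
    """Sample x SNP alt-allele dosage matrix with SNP coordinates.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, one per matrix row.
    snps : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, id, ref, alt``;
        ``pos`` is 1-based and strictly increasing within a chromosome.
    dosages : ndarray of float, shape (n_samples, n_snps)
        Count of alternate alleles in {0, 1, 2}; missing calls are NaN.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("SNP positions must be sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freq(self) -> np.ndarray:
        """Sample alt-allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def take_snps(self, index) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            self.samples, self.snps.iloc[index], self.dosages[:, index]
        )

    def take_samples(self, index) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            [self.samples[i] for i in index], self.snps, self.dosages[index, :]
        )

    def window_index(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Positional indices of SNPs with ``lo <= pos <= hi`` on ``chrom``."""
        mask = (
            (self.snps["chrom"].to_numpy() == chrom)
            & (self.snps["pos"].to_numpy() >= lo)
            & (self.snps["pos"].to_numpy() <= hi)
        )
        return np.flatnonzero(mask)


@dataclass
class MethylationData:
    """Sample x CpG-site methylation matrix (beta or M scale)."""

    samples: list[str]
    sites: pd.DataFrame
    values: np.ndarray
    scale: str = "M"

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.values.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.scale == "beta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and ((finite <= 0) | (finite >= 1)).any():
                raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index) -> "MethylationData":
        index = np.asarray(index)
        return MethylationData(
            self.samples, self.sites.iloc[index], self.values[:, index], self.scale
        )

    def take_samples(self, index) -> "MethylationData":
        index = np.asarray(index)
        return MethylationData(
            [self.samples[i] for i in index], self.sites, self.values[index, :],
            self.scale,
        )


@dataclass
class CovariateTable:
    """Per-sample covariates entering the fixed-effect design.

    ``table`` holds one row per sample (indexed by sample id) with columns
    such as sex, age, batch, diagnosis, side and genotype PCs. ``categorical``
    names the columns expanded to indicator contrasts when building a design
    matrix; everything else enters numerically.
    """

    table: pd.DataFrame
    categorical: tuple[str, ...] = ("sex", "batch", "diagnosis", "side")

    def design_matrix(self, samples: list[str] | None = None) -> np.ndarray:
        """Intercept + covariate design for ``samples`` (default: all rows)."""
        tab = self.table if samples is None else self.table.loc[samples]
        if tab.isna().any().any():
            raise ValueError("covariate table has missing entries for modeled samples")
        cols = [np.ones(len(tab))]
        for name in tab.columns:
            if name in self.categorical:
                dummies = pd.get_dummies(tab[name], drop_first=True)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy(dtype=float))
            else:
                cols.append(tab[name].to_numpy(dtype=float))
        return np.column_stack(cols)
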