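"""Methylation value transformation, probe filtering and covariate adjustment.

Beta values (methylated fraction, in (0,1)) and M-values
(``log2(beta/(1-beta))``) are the two interchangeable scales; analysis runs
on the M scale, where variance is less mean-dependent. Covariate adjustment
is per-site OLS residualization against the full fixed-effect design (sex,
age, batch, diagnosis, colon side, genotype PCs).
"""

from __future__ import annotations

import logging

import numpy as np

from .data import CovariateTable, MethylationData

logger = logging.getLogger(__name__)

BETA_CLIP_EPS = 1e-6


def beta_to_m(beta):
    """M-value from beta: log2(beta / (1 - beta)); beta 0.5 maps to M = 0.

    Input is clipped to [eps, 1-eps] (eps = 1e-6) so boundary betas stay
    finite.
    """
    beta = np.clip(np.asarray(beta, dtype=float), BETA_CLIP_EPS, 1 - BETA_CLIP_EPS)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`; maps all of R into (0, 1)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def to_m_scale(meth: MethylationData) -> MethylationData:
    """Return ``meth`` on the M scale (identity if already there)."""
    if meth.scale == "M":
        return meth
    return MethylationData(
        meth.samples, meth.sites, beta_to_m(meth.values), scale="M"
    )


def detection_filter_sites(
    detp: np.ndarray, p_thresh: float = 0.01, max_fail_frac: float = 0.05
) -> np.ndarray:
    """Mask of sites detected above background in enough samples.

    A sample fails a site when its detection p-value is >= ``p_thresh``; the
    site is retained iff the failing fraction is <= ``max_fail_frac``
    (i.e. removed when undetected in more than 5% of samples by default).
    """
    detp = np.asarray(detp, dtype=float)
    fail_frac = (detp >= p_thresh).mean(axis=0)
    return fail_frac <= max_fail_frac


def exclusion_filter(
    meth: MethylationData,
    exclude_ids,
    autosomes_only: bool = False,
) -> MethylationData:
    """Drop listed site ids (e.g. cross-reactive probes) and, optionally,
    every non-autosomal site. Unknown ids are ignored with a logged count."""
    exclude = set(exclude_ids)
    known = set(meth.sites["id"])
    unknown = exclude - known
    if unknown:
        logger.info("%d exclusion ids not present in the matrix", len(unknown))
    keep = ~meth.sites["id"].isin(exclude)
    if autosomes_only:
        chroms = meth.sites["chrom"].astype(str).str.removeprefix("chr")
        keep &= chroms.str.isdigit()
    if not keep.any():
        logger.warning("exclusion filter removed every site")
    return meth.take_sites(np.flatnonzero(keep.to_numpy()))


def residualize(
    meth: MethylationData, covars: CovariateTable
) -> tuple[MethylationData, np.ndarray]:
    """Per-site OLS residuals of M-values against the covariate design.

    Returns the residual matrix (same shape, M scale) and the per-site
    residual variance with the unbiased n - rank denominator. Aliased
    (linearly dependent) design columns are dropped with a warning.
    """
    if meth.scale != "M":
        raise ValueError("residualize expects M-scale values; call to_m_scale first")
    X = covars.design_matrix(meth.samples)
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "design rank %d < %d columns; dropping aliased columns", rank, X.shape[1]
        )
        # QR pivoting keeps an independent column subset
        _, _, piv = _qr_pivot(X)
        X = X[:, sorted(piv[:rank])]
    if n <= rank:
        raise ValueError("need more samples than design columns")
    Y = meth.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resvar = (resid**2).sum(axis=0) / (n - rank)
    out = MethylationData(meth.samples, meth.sites, resid, scale="M")
    return out, resvar


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    return qr(X, pivoting=True)
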