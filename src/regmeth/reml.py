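"""Regional heritability of a quantitative trait by REML.

The model is the standard GREML mixed linear model

    y = X beta + W u + e,   u ~ N(0, I sigma_u^2),   e ~ N(0, I sigma_e^2),

where W holds standardized dosages of the N SNPs within a window around the
trait (here, a CpG site) and A = W W' / N is the genomic relationship matrix
(VanRaden). Writing sigma_g^2 = N sigma_u^2, the covariance of y is
A sigma_g^2 + I sigma_e^2 and the regional heritability is

    h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Estimation profiles the restricted log-likelihood over h2 in [0, 1) after a
single eigendecomposition of A: for each h2 the covariance is diagonal in the
eigenbasis, so each evaluation is O(n p^2). A grid pass followed by
golden-section refinement locates the optimum; the null likelihood is the
same function evaluated at h2 = 0, so the likelihood-ratio statistic is
exactly nested. Because the null pins a variance to the boundary of its
parameter space, the LRT is referred to a 50:50 mixture of chi-square
distributions with 0 and 1 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import GenotypeData

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
H2_UPPER = 1.0 - 1e-6


def standardize_genotypes(
    dosages: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale dosage columns to the VanRaden W matrix.

    Column j becomes ``(g - 2 p_j) / sqrt(2 p_j (1 - p_j))`` with p_j the
    sample alt-allele frequency (or ``freqs`` if given). Missing dosages are
    imputed to ``2 p_j``, i.e. to 0 after centering. Monomorphic columns
    (p = 0 or 1) cannot be standardized and are dropped.

    Returns
    -------
    W : ndarray, shape (n_samples, n_kept)
    kept : ndarray of int
        Column indices of the retained (polymorphic) SNPs.
    """
    dosages = np.asarray(dosages, dtype=float)
    if freqs is None:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(dosages, axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    kept = np.flatnonzero((freqs > 0.0) & (freqs < 1.0))
    if kept.size < freqs.size:
        logger.warning("dropping %d monomorphic SNPs", freqs.size - kept.size)
    g = dosages[:, kept]
    p = freqs[kept]
    g = np.where(np.isnan(g), 2.0 * p, g)
    W = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return W, kept


@dataclass
class Grm:
    """Genomic relationship matrix A = W W' / N over N window SNPs."""

    A: np.ndarray
    n_snps: int
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")


def make_grm(dosages: np.ndarray, snp_ids=None) -> Grm:
    """GRM from raw dosages (standardization and imputation included)."""
    W, kept = standardize_genotypes(dosages)
    n_snps = W.shape[1]
    if n_snps == 0:
        raise ValueError("no polymorphic SNPs; GRM undefined")
    A = W @ W.T / n_snps
    ids = [snp_ids[i] for i in kept] if snp_ids is not None else []
    return Grm(A=A, n_snps=n_snps, snp_ids=ids)


def regional_grm(
    geno: GenotypeData, chrom: str, center: int, half_window: int = 1_000_000
) -> Grm | None:
    """GRM from SNPs within ``center +/- half_window`` (inclusive both ends).

    Returns None when the window holds no polymorphic SNP (site skipped).
    """
    idx = geno.window_index(chrom, center - half_window, center + half_window)
    if idx.size == 0:
        return None
    sub = geno.take_snps(idx)
    try:
        return make_grm(sub.dosages, list(sub.snps["id"]))
    except ValueError:
        return None


def lrt_pvalue(ll_alt: float, ll_null: float) -> tuple[float, float]:
    """Boundary-mixture likelihood-ratio test of h2 = 0.

    T = 2 (ll_alt - ll_null); the null distribution is the 50:50 mixture of
    a point mass at zero (chi2 with 0 df) and chi2 with 1 df, so
    p = 1 for T = 0 and 0.5 * Pr(chi2_1 >= T) otherwise.
    """
    t = 2.0 * (ll_alt - ll_null)
    if t < -1e-8:
        raise ValueError(f"alternative log-likelihood below null by {-t / 2:.3g}")
    t = max(t, 0.0)
    p = 1.0 if t == 0.0 else 0.5 * float(stats.chi2.sf(t, df=1))
    return t, p


class RegionalHeritabilityModel:
    """REML variance-component model for one trait against one GRM.

    Parameters
    ----------
    y : ndarray, shape (n,)
        Trait values (typically M-scale methylation at one CpG site).
    grm : Grm or ndarray
        Genomic relationship matrix over the window SNPs.
    X : ndarray, shape (n, p), optional
        Fixed-effect design. An intercept column is always included; pass
        covariates without one (or with — duplicated constant columns are
        not checked, keep the design full rank).
    """

    def __init__(self, y: np.ndarray, grm, X: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        A = grm.A if isinstance(grm, Grm) else np.asarray(grm, dtype=float)
        if A.shape != (n, n):
            raise ValueError(f"GRM shape {A.shape} does not match n = {n}")
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.grm = grm if isinstance(grm, Grm) else Grm(A, n_snps=0)
        if X is None:
            X = np.ones((n, 1))
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != n:
                raise ValueError("X row count does not match y")
            if not np.any(np.all(X == X[0], axis=0) & (X[0] != 0)):
                X = np.column_stack([np.ones(n), X])
        self.X = X
        self.nobs = n
        self.k_fixed = X.shape[1]
        if np.linalg.matrix_rank(X) < self.k_fixed:
            raise ValueError("fixed-effect design is rank deficient")
        if n <= self.k_fixed:
            raise ValueError("need more samples than fixed-effect columns")
        # one eigendecomposition serves every likelihood evaluation
        lam, U = np.linalg.eigh(0.5 * (A + A.T))
        neg = lam < -1e-8 * max(lam.max(), 1.0)
        if neg.any():
            logger.warning("clipped %d negative GRM eigenvalues", int(neg.sum()))
        self._lam = np.clip(lam, 0.0, None)
        self._yt = U.T @ self.y
        self._Xt = U.T @ self.X

    # -- restricted likelihood ------------------------------------------------

    def _profile(self, h2: float):
        """Restricted log-likelihood at h2, profiling beta and total variance.

        With V = sigma_p^2 D(h2), D = h2 lam + (1 - h2) in the eigenbasis,
        the GLS residual quadratic form Q gives sigma_p^2 = Q / (n - p) and

        ll = -1/2 [ (n-p)(log sigma_p^2 + 1 + log 2 pi)
                    + sum log D + log det(X' D^-1 X) ].
        """
        d = h2 * self._lam + (1.0 - h2)
        Xw = self._Xt / d[:, None]
        XtDX = self._Xt.T @ Xw
        Xty = Xw.T @ self._yt
        try:
            c, low = np.linalg.cholesky(XtDX), True
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        beta = np.linalg.solve(XtDX, Xty)
        q = float(self._yt @ (self._yt / d) - Xty @ beta)
        dof = self.nobs - self.X.shape[1]
        if q <= 0:
            q = np.finfo(float).tiny
        sigma_p2 = q / dof
        logdet_xtdx = 2.0 * float(np.log(np.diag(c)).sum())
        ll = -0.5 * (
            dof * (np.log(sigma_p2) + 1.0 + _LOG2PI)
            + float(np.log(d).sum())
            + logdet_xtdx
        )
        return ll, sigma_p2, (beta, XtDX)

    def loglike(self, h2: float) -> float:
        """Restricted log-likelihood profiled over beta and total variance."""
        return self._profile(float(h2))[0]

    def fit(self, grid_points: int = 512, tol: float = 1e-6):
        """Maximize the restricted likelihood over h2 in [0, 1).

        A ``grid_points``-point grid pass brackets the optimum, then
        golden-section search refines to ``|dh2| < tol``. When the profile is
        flat (e.g. A = I, where the two variance components are not separately
        identifiable) the boundary h2 = 0 is reported by convention.
        """
        grid = np.linspace(0.0, H2_UPPER, grid_points)
        lls = np.array([self._profile(h)[0] for h in grid])
        converged = bool(np.isfinite(lls).all())
        ll_null = lls[0]
        best = int(np.argmax(lls))
        # treat a flat profile as the null fit
        if lls[best] <= ll_null + 1e-10:
            h2_hat, ll_hat = 0.0, ll_null
        else:
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, grid_points - 1)]
            res = optimize.minimize_scalar(
                lambda h: -self._profile(h)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": tol},
            )
            h2_hat, ll_hat = float(res.x), -float(res.fun)
            if ll_hat < lls[best]:  # refinement must not lose the grid optimum
                h2_hat, ll_hat = float(grid[best]), float(lls[best])
            if ll_hat <= ll_null:
                h2_hat, ll_hat = 0.0, float(ll_null)
        ll_hat = float(ll_hat)
        ll_null = float(ll_null)
        _, sigma_p2, aux = self._profile(h2_hat)
        beta, XtDX = aux
        lrt, p = lrt_pvalue(ll_hat, ll_null)
        beta_cov = sigma_p2 * np.linalg.inv(XtDX)
        return RegionalHeritabilityResults(
            model=self,
            h2=h2_hat,
            sigma_g2=sigma_p2 * h2_hat,
            sigma_e2=sigma_p2 * (1.0 - h2_hat),
            llf=ll_hat,
            ll_null=ll_null,
            lrt=lrt,
            pvalue=p,
            fe_params=beta,
            fe_cov=beta_cov,
            converged=converged,
        )


@dataclass
class RegionalHeritabilityResults:
    """REML fit of one trait: variance components, h2 and the mixture LRT."""

    model: RegionalHeritabilityModel
    h2: float
    sigma_g2: float
    sigma_e2: float
    llf: float
    ll_null: float
    lrt: float
    pvalue: float
    fe_params: np.ndarray
    fe_cov: np.ndarray
    converged: bool

    @property
    def fe_bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.fe_cov))

    def summary(self) -> str:
        n = self.model.nobs
        lines = [
            "Regional heritability (REML)",
            "=" * 46,
            f"{'No. observations:':<28}{n}",
            f"{'No. window SNPs:':<28}{self.model.grm.n_snps}",
            f"{'sigma_g^2:':<28}{self.sigma_g2:.6g}",
            f"{'sigma_e^2:':<28}{self.sigma_e2:.6g}",
            f"{'h2:':<28}{self.h2:.4f}",
            f"{'Restricted loglik:':<28}{self.llf:.4f}",
            f"{'Loglik (h2 = 0):':<28}{self.ll_null:.4f}",
            f"{'LRT (chi2_0:chi2_1 mix):':<28}{self.lrt:.4f}",
            f"{'P(h2 = 0):':<28}{self.pvalue:.4g}",
            f"{'Converged:':<28}{self.converged}",
            "-" * 46,
            f"{'fixed effect':<16}{'coef':>12}{'se':>12}",
        ]
        for j, (b, s) in enumerate(zip(self.fe_params, self.fe_bse)):
            lines.append(f"{'x' + str(j):<16}{b:>12.4f}{s:>12.4f}")
        return "\n".join(lines)


@dataclass
class SnpFixedResult:
    """Variance decomposition of a window around one SNP of interest.

    ``h2_all`` fits the full window GRM; ``h2_reduced`` drops the SNP from
    the GRM; ``h2_full`` additionally fits the SNP dosage as a fixed effect.
    ``prop_explained = 1 - h2_full / h2_all`` is the share of the regional
    heritability attributable to the SNP.
    """

    site_id: str
    snp_id: str
    h2_all: float
    p_all: float
    h2_full: float
    p_full: float
    h2_reduced: float
    p_reduced: float
    snp_beta: float
    snp_se: float
    prop_explained: float


def prop_explained(h2_all: float, h2_full: float) -> float:
    """Share of regional heritability attributable to a fixed SNP effect."""
    if h2_all <= 0:
        return np.nan
    return 1.0 - h2_full / h2_all


def snp_fixed_decomposition(
    y: np.ndarray,
    geno: GenotypeData,
    snp_id: str,
    site_chrom: str,
    site_pos: int,
    X: np.ndarray | None = None,
    half_window: int = 1_000_000,
    site_id: str = "",
) -> SnpFixedResult:
    """Quantify how much of a site's regional h2 one named SNP explains.

    Three REML fits share the +/- ``half_window`` SNP window around the site:
    all window SNPs in the GRM; the GRM without the SNP; and the GRM without
    the SNP plus its dosage as a fixed-effect covariate. The SNP effect is
    reported per copy of the minor allele (sample-frequency minor; a tie at
    p = 0.5 keeps the alt allele).
    """
    idx = geno.window_index(
        site_chrom, site_pos - half_window, site_pos + half_window
    )
    window = geno.take_snps(idx)
    ids = list(window.snps["id"])
    if snp_id not in ids:
        raise ValueError(f"SNP {snp_id!r} not inside the +/-{half_window} bp window")
    j = ids.index(snp_id)

    def _fit(dosages, snp_ids, extra_col=None):
        grm = make_grm(dosages, snp_ids)
        design = X
        if extra_col is not None:
            design = (
                extra_col[:, None]
                if design is None
                else np.column_stack([design, extra_col])
            )
        return RegionalHeritabilityModel(y, grm, design).fit()

    all_fit = _fit(window.dosages, ids)
    mask = np.arange(window.n_snps) != j
    red_geno = window.take_snps(np.flatnonzero(mask))
    red_fit = _fit(red_geno.dosages, list(red_geno.snps["id"]))

    g = window.dosages[:, j].copy()
    p_alt = np.nanmean(g) / 2.0
    if p_alt > 0.5:  # count minor-allele copies
        g = 2.0 - g
    g = np.where(np.isnan(g), np.nanmean(g), g)
    full_fit = _fit(red_geno.dosages, list(red_geno.snps["id"]), extra_col=g)
    snp_beta = float(full_fit.fe_params[-1])
    snp_se = float(full_fit.fe_bse[-1])

    return SnpFixedResult(
        site_id=site_id,
        snp_id=snp_id,
        h2_all=all_fit.h2,
        p_all=all_fit.pvalue,
        h2_full=full_fit.h2,
        p_full=full_fit.pvalue,
        h2_reduced=red_fit.h2,
        p_reduced=red_fit.pvalue,
        snp_beta=snp_beta,
        snp_se=snp_se,
        prop_explained=prop_explained(all_fit.h2, full_fit.h2),
    )
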