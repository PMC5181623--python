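# Methods

## The regional heritability model

Per CpG site the methylation M-values are modeled as
`y = Xβ + Wu + ε` with `u ~ N(0, I σu²)` and `ε ~ N(0, I σε²)`. `W` holds
window SNP dosages standardized to `(g − 2p)/√(2p(1−p))` with the sample
alt-allele frequency `p`; missing dosages are mean-imputed inside the
standardization only (they become 0 after centering) and never altered in
stored data. Monomorphic SNPs cannot be standardized and are dropped from
the window. The genomic relationship matrix is `A = WW′/N` over the `N`
surviving SNPs; under Hardy–Weinberg sampling its diagonal averages ≈ 1.
Writing `σg² = N σu²`, `Var(y) = A σg² + I σε²` and the regional
heritability is `h² = σg²/(σg² + σε²)`.

**Window convention.** The window is `site ± 1,000,000 bp`, inclusive at
both endpoints, same chromosome only. The same inclusive boundary defines
cis versus trans in the association scan and risk-region membership, so the
three analyses partition SNP–site pairs identically.

## REML estimation

The restricted likelihood is profiled over h² ∈ [0, 1):

* eigendecompose `A = UΛU′` once per site; negative eigenvalues (numerical
  artifacts) are clipped at zero with a logged count;
* in the eigenbasis `Var(y) = σp² D(h²)` with `D = h²Λ + (1−h²)I` diagonal,
  so each evaluation is a weighted GLS solve, O(n·p²);
* β and the total variance σp² are profiled out analytically
  (`σ̂p² = Q/(n−p)` from the GLS residual quadratic form);
* a 512-point grid over h² ∈ [0, 1−10⁻⁶] brackets the optimum, then bounded
  scalar refinement tightens it to |Δh²| < 10⁻⁶. A refinement that fails to
  beat the grid maximum is discarded in favor of the grid point, so the
  reported optimum never falls below the profile seen on the grid.

The null log-likelihood is the same function at h² = 0, guaranteeing nested
comparability. When the profile is flat — e.g. `A = I`, where σg² and σε²
are not separately identifiable — the boundary h² = 0 is reported by
convention with p = 1. The grid-plus-refinement contract is validated in
the test suite against a dense 10⁴-point grid oracle (|Δh²| ≤ 10⁻³ over
random small instances).

**Testing h² = 0.** The LRT statistic `T = 2(llₐ − ll₀)` has a boundary
null distribution: a 50:50 mixture of a point mass at zero and χ²₁, so
`p = 1` when `T = 0` and `p = 0.5·Pr(χ²₁ ≥ T)` otherwise. Tiny negative `T`
(within 10⁻⁸, numerical noise) is clipped to zero. Sites are declared
heritable at nominal p < α with α = 0.05 and no multiple-testing
correction — the scan's purpose is a rate, not a discovery list — but a
Benjamini–Hochberg column is emitted for users who want one. `α ≥ 1` is
interpreted as "every converged site", since the p-value's point mass at 1
would otherwise exclude exact-null fits even at α = 1.

**Covariates.** The default is to carry the full covariate set (sex, age,
batch, diagnosis, side, genotype PCs) as fixed effects `X` inside the REML
fit. The alternative path — OLS-residualize first, then scan — is exposed
too; the two are numerically identical when the residual scan retains the
same design (the restricted likelihood projects out the same subspace), and
differ only through degrees of freedom (observed ≤ 0.06 at n = 132 with a
9-column design) when the residual scan keeps only an intercept. The
pipeline therefore retains the design in both modes.

**SNP decomposition.** For a named SNP, three fits quantify its share of a
site's regional h²: the full window GRM (`h2_all`); the GRM excluding the
SNP (`h2_reduced`); and the GRM excluding the SNP with its dosage added to
`X` (`h2_full`). `prop_explained = 1 − h2_full/h2_all`, undefined when
`h2_all = 0`. The SNP effect is reported per copy of the sample-frequency
minor allele (a tie at p = 0.5 keeps the alt allele), with its GLS standard
error at the fitted variance components.

## Genotype QC

Four successive SNP filters, each seeing only the survivors of the previous
one: call rate (> 5% missing), Hardy–Weinberg (exact p < 10⁻⁴), MAF
(< 0.01), and differential missingness between cases and controls
(two-proportion test, p < 10⁻⁵; skipped without labels). Sample call rate
(> 5% missing) is applied first, and allele frequencies are recomputed
after sample filtering. The HWE test is the exact conditional test —
enumeration of heterozygote counts given allele counts, summing
probabilities ≤ that of the observed table — computed in log-space and
verified against an exact-rational enumeration oracle; the exact test is
preferred over the χ² approximation because window SNP counts and rare
genotype classes are small. The X-chromosome sex check uses
`F = 1 − O(het)/E(het)` with `E(het) = Σ 2pᵢ(1−pᵢ)` over the sample's
non-missing X SNPs; recorded females with F > 0.98 and recorded males with
F < 0.2 are flagged. Genotype PCs come from the SVD of the standardized
dosage matrix (scores = left singular vectors × singular values), with the
sign fixed by the largest-magnitude loading.

## Methylation preparation

`M = log₂(β/(1−β))`, with β clipped to [10⁻⁶, 1−10⁻⁶] to keep boundary
values finite; M = 0 is 50% methylation. Sites are dropped when their
detection p-value is ≥ 0.01 in more than 5% of samples, and an external
exclusion list (e.g. cross-reactive probes) is consumed as-is. Covariate
residualization is per-site OLS with categorical covariates as indicator
contrasts; residual variance uses the unbiased n − rank denominator.
Aliased design columns are dropped with a warning rather than failing.

## Annotation

CpG islands are called from sequence by tiling fixed 500-bp frames from
coordinate 0 (frame-fixed tiling makes the caller deterministic and
invariant to where the input sequence was split): a frame qualifies iff
GC > 50% and observed/expected CpG = `N_CpG·500/(N_C·N_G)` > 0.60; adjacent
qualifying frames merge. Frames containing N never qualify.

Density classes measure distance from the nearest island edge: shore ≤ 2 kb,
shelf 2–4 kb, else sea. **North = lower genomic coordinate, south = higher**,
by genome orientation, not gene strand (array manifests use the same
convention; stated here because it is easy to invert). Distances are signed
(north negative). Upstream uses `(0, 2000]`/`(2000, 4000]` on the raw gap
`start − pos` and downstream `[0, 2000)`/`[2000, 4000)` on `pos − end`; the
two half-open conventions make every base classified exactly once under
0-based half-open islands. Ties between equally near islands resolve to the
upstream side.

Genic classes are mutually exclusive by successive filters: TSS
(TSS200/TSS1500, strand-aware upstream) of an expressed gene → TSS of any
gene → gene body (5′UTR/first exon/body/3′UTR) → intergenic. A gene is
expressed when ≥ 1 probe is detected (p < 0.01) in strictly more than 80%
of samples — 9 of 11, 8 of 9, 9 of 10.

## Association scan

Each SNP–site test is OLS of residual M-value on dosage (Wald t, n − 2 df,
R² = squared Pearson correlation), missing dosages dropped pairwise, SNPs
with minor-allele count < 3 skipped and excluded from the test count.
Expected significant counts are `n_tests × threshold`, an independence
approximation that ignores LD-induced test dependence — deliberately, since
the observed/expected contrast is the quantity of interest. The top-SNP
comparison pairs each significantly heritable site with its smallest-p cis
SNP (ties: larger R², then smaller distance) and reports `R²_top/h²`.

## Group statistics

Welch's t (unequal variances, Welch–Satterthwaite df), two-sample KS with
asymptotic p, and the two-proportion χ² with Yates continuity correction —
matching R's `prop.test`, against which the implementation is frozen-value
tested; the correction can be disabled. The proportion-heritable versus
mean-genetic-variance correlation within islands and within sea uses the
four genic-group points per density class and is flagged descriptive: four
points support no inference. The h²-variance partition regresses
significant-site h² on window SNP count and on residual variance (OLS), and
tests the contextual-group factor by sequential (type I) ANOVA after
residual variance.

## Synthetic data

The generator produces data with exactly the structure the analysis
assumes, plus truth for recovery tests. Defaults are the study conditions:
132 samples, MAF ~ Uniform(0.05, 0.5), SNP density 1.5×10⁻⁴/bp (~300 SNPs
per ±1 Mb window), true local h² a point mass at 0.3, 3 causal SNPs per
site, modest covariate effects (|β| ≤ 0.5 M-units).

* **Genotypes** — two haplotypes per sample; along the chromosome each
  haplotype copies the previous SNP's allele with probability `ld_rho`
  (default 0.3) and otherwise draws fresh. This first-order copying chain is
  a deliberately simple stationary short-range LD model with one
  controllable knob, not an attempt to model any real cohort's LD; its
  implied marginal frequency `q_j = ρ q_{j−1} + (1−ρ) p_j` is returned as
  truth.
* **Annotation** — each site owns a 30-kb slot; islands (1 kb, centred) and
  schematic genes (TSS1500|TSS200|5′UTR|first exon|body|3′UTR) are placed so
  the site lands in its assigned contextual group, and slots are spaced so
  contexts cannot interfere. The generated layout is verified against the
  package's own classifier in the tests. The LCM expressed-gene set is a
  subset of the WCB set apart from 10 private genes, mirroring the
  whole-biopsy/epithelial relationship the analysis compares.
* **Phenotypes** — causal SNPs are drawn from the site's cis window, effects
  `u ~ N(0,1)` are rescaled so the realized genetic variance is *exactly*
  h² of a unit total (noise is orthogonalized against the genetic value and
  scaled to 1 − h²). Exact realized ratios make truth interpretable at
  n = 132, where an "in expectation" calibration would leave the recovery
  oracle itself noisy.
* **What it does not emulate** — raw array intensities, probe-type effects,
  cell-type heterogeneity, realistic LD decay, allele-frequency spectra or
  selection. Passing recovery and calibration tests therefore demonstrates
  correctness of the estimator under its own assumptions, not robustness to
  the ways real methylation data violate them.

Determinism: every stage draws from `default_rng([seed, stage])`, so a
config with a fixed seed reproduces byte-identical outputs regardless of
which stages are run.

## Problem sizes and numerical choices

The calibration suite uses 1000 null sites and the recovery suite 200 sites
at n = 132 with ~300-SNP windows — large enough that the binomial bound on
the false-positive rate (0.05 + 3·SE ≈ 0.071) and the ±0.05 band on the
mean ĥ² are informative, and small enough to run in well under a minute.
Other choices: β-clip 10⁻⁶; GRM eigenvalue clip at 0; LRT negative-T
tolerance 10⁻⁸; REML grid 512 points with 10⁻⁶ refinement; PSD and
convergence failures flagged, never silent.

## Known limitations

Whole-genome (polygenic) heritability is out of scope — at these sample
sizes the identity-by-descent variance across unrelated individuals is too
small genome-wide, which is precisely the motivation for the regional
estimator. Mixed-model association, imputation, relatedness pruning and
raw-intensity normalization (background correction, color-bias, probe-type
adjustment) are likewise out of scope; the pipeline accepts a normalized
β/M matrix. Significant-site summaries are subject to winner's curse: the
mean ĥ² among significant sites overstates the mean true h² of those sites,
which matters when comparing against unconditioned truths.
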