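# Methods

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization with
gene expression as the exposure. The inputs are per-SNP linear-regression
coefficients and standard errors from two non-overlapping cohorts — a trait
GWAS and a cis-eQTL study — plus a reference genotype panel used only to
estimate LD. Assumptions inherited from the method:

* the top cis-eQTL is a valid instrument: associated with expression
  (enforced by the instrument p-value threshold), affecting the trait only
  through expression (probed, not guaranteed, by HEIDI), and not
  confounded with the trait through population structure;
* GWAS and eQTL cohorts share ancestry and LD structure with the reference
  panel, and do not overlap (the HEIDI covariance omits a sample-overlap
  term accordingly);
* effects are small enough that first-order error propagation of the Wald
  ratio is adequate — true in practice because every SNP entering HEIDI
  must itself show an eQTL signal, bounding `se(b_eQTL)/|b_eQTL|`.

The SMR statistic `T = z_G²z_E²/(z_G²+z_E²)` is referred to χ²₁; it is
bounded by the weaker of the two z-scores, so the combined test can never
outrank either constituent association. p-values below double-precision
underflow are representable: the statistic and a log10 p-value are carried
alongside, and the readers accept a printed `p = 0` only when `|b/se| > 37`,
the point where the two-sided normal tail underflows.

## HEIDI

Candidates are cis-SNPs (top instrument excluded) with their own eQTL
signal (`p_eQTL < 1.57e-3`, i.e. |z| > ~3.16), in informative but
non-redundant LD with the top SNP (`r² ∈ [0.05, 0.9]`), capped at the 20
smallest eQTL p-values and requiring at least 3; all four constants are
exposed as flags. The deviation covariance `V` uses the *signed* LD
correlations, and is projected to the nearest PSD matrix (eigenvalue floor
at zero) when an estimated LD matrix makes it slightly indefinite.

The null distribution of `T_HEIDI` is the weighted χ²₁ sum with weights from
the unit-scaled `V`. Its tail probability is computed by Imhof's numerical
inversion of the characteristic function, which is exact up to quadrature
error. A skewness/kurtosis-matched noncentral-χ² (Liu-style) approximation
was evaluated as the primary method and rejected: its absolute error in the
distribution body reaches 0.01–0.05 on realistic 5-SNP weight spectra,
larger than the Monte-Carlo resolution (1e5 draws) used to validate the
implementation, while Imhof agrees with Monte Carlo to sampling noise. The
moment-matching approximation is retained as the first fallback — it is
accurate in the right tail, which is where Imhof's absolute quadrature
error floor (~1e-6) becomes limiting — and a 1e5-draw Monte-Carlo estimate
is the final fallback. The method actually used is recorded in
`HeidiResult.method`.

Two HEIDI retention conventions exist in practice: a fixed `p_HEIDI > 0.05`
floor, and a Bonferroni-relaxed floor `0.05/n_HEIDI` over the HEIDI tests
performed. The pipeline defaults to the Bonferroni variant (it is the rule
the packaged discovery table's survivors obey); both are reachable through
`ThresholdConfig`.

## Staged testing, replication, differential expression

Discovery pools the SMR test count across tissues (blood and brain analyses
are one code path run per tissue) and applies `p_SMR < α/n_SMR` strictly;
HEIDI is run only for SMR-significant genes, and its Bonferroni family is
the number of HEIDI tests actually performed. Replication declares a GWAS
lookup successful when the harmonized sign agrees and p beats `α/n_SNPs`
(missing SNPs stay in the denominator — conservative), and an eQTL lookup
successful at genome-wide significance (`p < 5e-8`) with sign concordance;
a zero replication effect counts as discordant. The brain-eQTL replication
criterion is the same flag-exposed threshold as blood — the source analyses
are asymmetric on this point, and the package makes the blood criterion the
default for both. Differential expression is ordinary least squares of
cross-platform-normalized expression on a case indicator with classical
t-tests and per-region Benjamini–Hochberg correction; a moderated
(empirical-Bayes) variance would shrink per-gene variances toward a pooled
prior and is noted as an extension, but its hyperparameters depend on the
source database and plain OLS keeps the stage exactly reproducible. The
reported "FC" is the model coefficient on the normalized (z-score) scale —
a signed case-minus-control difference, not an expression ratio.

Allele harmonization flips the eQTL (or replication) record onto the GWAS
effect allele, negating signs for swapped allele orders; palindromic A/T
and C/G SNPs are dropped by default because summary files carry no strand
information. Coordinates are 1-based and the cis window is closed
(`|bp − gene_bp| ≤ 1 Mb` by default) around a single anchor position per
gene.

## Synthetic cohorts

The generator emulates the statistical structure of consortium summary
data: two latent AR(1) Gaussian haplotype vectors per individual
(correlation `ld_rho^|i−j|`, default rho 0.8) are dichotomized at each
SNP's MAF quantile (MAF ~ U(0.1, 0.5)) and summed to dosages; expression is
`b_zx·g_c + N(0,1)` in the eQTL cohort (default n = 5,000, b_zx = 0.7,
giving top-eQTL |z| ≈ 30); the GWAS cohort (default n = 20,000) gets a
continuous trait mediated through expression (pleiotropy, default
b_xy = 0.2), affected directly by a *different* SNP in LD (linkage, default
direct effect 0.1), or pure noise (null); the reference panel (default
n = 500) is an independent draw. Dosage LD is attenuated relative to the
latent rho by the dichotomization, so the generator measures the realized
correlation between causal SNPs and writes it into the truth file; with
latent rho 0.8 the adjacent-SNP default spacing realizes r² ≈ 0.25–0.3,
which is why the linkage scenario places the two causal SNPs next to each
other. A continuous GWAS trait is used rather than case/control liability
because the SMR statistic consumes only (b, se) pairs and the continuous
model admits closed-form checks; per-SNP effects are estimated by OLS even
though some eQTL consortia use rank-based association, since OLS is the
structure the Wald ratio assumes.

What the simulator does *not* model: recombination-map realism, allele
frequency spectra beyond uniform MAF, sample overlap between cohorts,
trans-eQTLs, case/control ascertainment, and population stratification.
Passing calibration tests on these cohorts therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to the full messiness of real consortium data.

## Problem sizes and numerical choices

Calibration suites in the tests and the acceptance script use: 5,000 null
replicates at a reduced locus (10 SNPs, n = 2,000 per cohort — null
calibration is size-free, so smaller cohorts only speed it up), 500 HEIDI
replicates per scenario at the full default cohort sizes, 200 replicates
for effect-size recovery, and 50 random 5-SNP instances for the
quadratic-form oracle comparison; these sizes give Monte-Carlo standard
errors comfortably inside the tolerances being asserted. Deterministic
tie-breaking (smallest p, then largest |z|, then lexicographic SNP ID)
makes instrument selection reproducible; all simulation randomness flows
from a single integer seed through `numpy`'s `SeedSequence`. Zero-variance
SNPs are excluded from LD with a warning; missing dosages are mean-imputed
before correlation; degenerate HEIDI candidates whose deviation variance is
exactly zero are dropped from the quadratic form.

## Known limitations

Single-instrument Wald ratio only (no multi-SNP SMR extensions, no
multi-probe conditional HEIDI); no binary eQTL container formats; no
meta-analysis of discovery and replication; the convergence call is a
conjunction of stage flags with configurable thresholds, not a formal joint
model.
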