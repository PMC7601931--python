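# Methods

This note records the statistical models implemented in `cllassoc`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Cohort model and QC

A cohort is a set of samples (case/control label, per-SNP genotypes, gene
copy numbers, quantitative phenotypes, optional ordinal stage 0–4) plus the
SNP definitions their genotypes reference. Genotypes are unordered allele
pairs: equality and hashing ignore input order, and display order puts the
reference (major) allele first, so `"GA"` and `"AG"` are one heterozygote.
All tallies are oriented to each SNP's declared *minor* allele: the
"alt-homozygote" class in every downstream formula is the minor-allele
homozygote, matching the convention of writing a variant `G>A` by allele
frequency.

Missing genotypes are excluded per SNP, not per sample — a sample missing
one SNP still contributes everywhere else; no imputation is attempted.

CNV exclusion removes any sample whose copy number falls below the
threshold (default 2) for *any* listed gene. The rationale is specific to
genes in somatically deleted regions (17p in CLL): a hemizygous tumour
deletion makes the germline genotype call unreliable and distorts genotype
frequencies, so such samples are dropped from all analyses. A sample with
no copy-number call for a listed gene is retained with a logged warning:
a missing assay is a data defect, not evidence of deletion.

## Hardy–Weinberg departure

The departure coefficient is the normalised gap between observed and
expected homozygosity, equivalently written through heterozygosity as
f = 1 − H_obs/H_exp. Two estimator variants are exposed:

* **default**: H_exp = 2p(1−p) · 2n/(2n−1), the unbiased expected
  heterozygosity. This is the variant that reproduces the published
  reference values bundled with the package (all four departure
  coefficients and every confidence-interval bound at printed precision).
* **plain** (`small_sample_correction=False`): H_exp = 2p(1−p), the
  textbook quotient, for which f = 0 exactly when the observed
  alt-homozygote frequency equals p². The algebraic inverse
  P(alt-hom) = p² + fp(1−p), P(het) = 2p(1−p)(1−f),
  P(ref-hom) = (1−p)² + fp(1−p) reconstructs the observed genotype
  frequencies exactly only in this variant.

The two differ by O(1/n) and are indistinguishable at cohort sizes of a few
hundred except exactly at 2-decimal rounding boundaries.

The 95% CI is Wald, f ± 1.96·se, with asymptotic variance

    Var(f) = [ (1−f)²(1−2f) + f(1−f)(2−f) / (2p(1−p)) ] / n.

This formula was validated against three independently hand-evaluated
reference intervals before being frozen as the default; it is evaluated at
the estimated f, whichever variant produced it. f is undefined (an error)
at monomorphic loci.

Two HWE tests are provided because published p-values in this study family
rarely state their method: the exact conditional test (condition on the
allele counts; sum the probabilities of all heterozygote counts no more
probable than the one observed, ties included, no mid-p) and the 1-df
Pearson goodness-of-fit chi-squared. On the bundled reference counts the
exact test agrees with the published p-value to printed precision while the
chi-squared does not, so the exact test is the default attached to
`hwe_f` results; neither is asserted against published p-values in tests.

## Case-control association

The omnibus test is Pearson's chi-squared on the 3×2 genotype-by-status
table, no continuity correction, df = 2. A genotype class empty in both
arms is dropped with a df reduction and a warning.

Every reported odds ratio applies the Haldane–Anscombe correction — +0.5
added to **all four** cells unconditionally, not only when a zero occurs —
followed by the Woolf interval exp(ln OR ± 1.959964·√(1/a+1/b+1/c+1/d)) on
the corrected cells. The all-cell convention was fixed after verifying by
hand that it reproduces every bundled reference odds ratio and interval at
2 decimals, while uncorrected cross-products do not; it also guarantees
finite estimates for tables with empty cells (e.g. recessive models of rare
alleles). An uncorrected mode exists for algebraic checks and large-table
work; corrected and uncorrected estimates converge as counts grow.

Collapsed models reduce the genotype table before the same 2×2 machinery:
dominant (carriers vs other homozygote), recessive (effect-allele
homozygote vs rest), allelic (2n allele counts). The reference class for
per-genotype odds ratios is the major-allele homozygote, whose OR is 1 by
construction and omitted from reports. Collapsed-model results also carry
the 1-df chi-squared and Fisher exact p-values of the collapsed table,
since either may be wanted and published tables rarely say which was used.

No multiple-testing adjustment is applied by default — the intended use is
a small panel of a-priori hypotheses — but a Benjamini–Hochberg column is
available for exploratory runs.

Displayed percentages are plain n/total rounded to 2 decimals; they are
presentation values only and nothing downstream consumes them.

## Quantitative statistics

**Sn scale.** Sn = med_i med_j |x_i − x_j| is the typical absolute
difference between two random observations: a robust dispersion measure
needing no location estimate. The default mode is the literal double
median — inner index running over all j including i, plain midpoint
medians — because that is the form the quotient is usually quoted in; the
Rousseeuw–Croux estimator (j ≠ i, high-median inner, low-median outer,
consistency factor 1.1926, unbiased for σ under normality) is behind a
mode flag. The two disagree on small or even-length samples. Both are
checked against brute-force pure-Python oracles.

**ANOVA.** Standard one-way fixed-effects decomposition. Fligner–Killeen
(rank-based, robust to non-normality) tests variance homogeneity and is
attached to every result. Box-Cox, when requested, fits a single
maximum-likelihood λ (bounded to [−5, 5]) on the pooled data and applies it
to every group — a common monotone rescaling, so group membership is
untouched; non-positive values are an error instructing a shift. "When
needed" is operationalised as explicit flags defaulting to off, with an
advisory logged when Fligner–Killeen p < 0.05 or pooled |skewness| > 1.

**Planned contrasts.** For weights λ summing to zero,
L = Σλ_j ȳ_j, F_contrast = L²/(MSE·Σλ_j²/n_j) on (1, df_within) degrees of
freedom. Two effect sizes are reported: r_alerting, the Pearson correlation
between the k group means and the k weights (how well the *pattern* of
means matches the contrast, blind to within-group noise), and
r_effect_size = sign(L)·√(F_contrast/(F_contrast+df_within)) (how much of
the variation the contrast explains). They deliberately decouple: means can
lie on a near-perfect line while explaining almost nothing — the signature
of a clean trend swamped by within-group variability, which is why both are
reported side by side. The ordinal-stage trend uses centred equally spaced
weights over the supplied group order; sign conventions follow that order.

**Bootstrap F null.** Each group is centred at its own mean; the pooled
residuals are resampled with replacement into the original group sizes B
times (default 10 000) and the statistic recomputed;
p = (1 + #{F* ≥ F_obs})/(B + 1), which can never be zero. The scheme
imposes the null while preserving the pooled error distribution, so it is
robust to non-normal errors. Resampling uses a canonical group ordering and
a sorted residual pool, making the p-value exactly invariant to the order
in which groups are supplied, and deterministic per seed.

**Fisher's LSD.** Unprotected pairwise t tests with pooled MSE at α = 0.05
two-sided. The grouping notation lists maximal cliques of mutually
non-different groups in group order, parenthesised with `.` separators:
`AA (AG.GG)` = AA differs from both of AG and GG, which do not differ.
Cliques can overlap (`(0.1) (1.2)`) when significance is not transitive.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes, at the
scale of the motivating study (hundreds of samples per arm, minor-allele
frequencies 0.1–0.3, single-copy fractions of a few percent):

* genotype probabilities are the algebraic inverse of the plain departure
  coefficient, so (q, f) are recovered by estimation at large n;
* case genotype probabilities are the control probabilities reweighted by
  per-genotype odds ratios and renormalised — the exact genotype-level
  logistic correspondence, making odds-ratio recovery analytic. When no
  odds ratios are given, cases are drawn directly at (q, f_case);
* phenotypes are normal or log-normal conditional on genotype, with an
  optional additive linear shift per stage; percent-unit phenotypes are
  clipped to [0, 100];
* CNV single-copy flags and missing-genotype masks are independent
  Bernoulli draws.

Randomness uses one base seed with substreams keyed by stable hashes of
SNP/phenotype/gene identifiers, so adding a phenotype never perturbs
genotypes, and identical specs produce byte-identical files.

What it does **not** emulate — and therefore what passing recovery tests do
not establish about real data: linkage disequilibrium between SNPs,
age/sex or ancestry confounding, genotyping error, informative missingness,
correlation between phenotypes, or selection effects in which patients get
phenotyped. Recovery tests show the estimators are correct under the
model's own assumptions, not that those assumptions hold in any cohort.

## Problem sizes used in the test suite

Calibration and recovery checks run at sizes chosen to keep Monte-Carlo
noise well below the tolerances being asserted: 1000 replicates for type-I
error (binomial SE ≈ 0.7 points at the 5% level), 50 datasets × B = 2000
for bootstrap-vs-parametric agreement (per-dataset resampling SE up to
0.011, hence the band is asserted on the mean absolute difference), 500
seeds for confidence-interval coverage (SE ≈ 0.9 points on the coverage
percentage), and n = 30 000–50 000 draws for point-estimate recovery.

## Known limitations

* No logistic regression or covariate adjustment; association is
  table-based only.
* VCF support is deliberately minimal: biallelic SNPs with GT, no INFO
  parsing, multi-allelic records skipped.
* The exact HWE test enumerates the conditional distribution; this is
  O(min(n_a, 2n−n_a)) per table and fast for cohort-scale data, but the
  published p-values it is compared against informally were never asserted
  as oracles because their method is not stated.
* Fisher's LSD notation enumerates label subsets; intended for the small
  group counts (≤ 5–6) of genotype/stage analyses, not for many-group
  designs.
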