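"""Hardy-Weinberg departure estimation and tests.

The departure coefficient

    f = (p_cc - p_c^2) / (p_c (1 - p_c))

measures how far the observed homozygote frequency ``p_cc`` of allele ``c``
(here: the SNP's minor allele, frequency ``p_c``) sits from its
Hardy-Weinberg expectation ``p_c^2``, scaled to [-1, 1].  ``f > 0`` means a
deficit of heterozygotes (excess homozygosity, as under inbreeding or a
Wahlund effect), ``f < 0`` a deficit of homozygotes; ``f = 0`` is exact HWE.

Two tests are provided: the exact conditional test (sum of probabilities of
heterozygote counts no more probable than the observed one, given the
allele counts) and the classical 1-df Pearson goodness-of-fit chi-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .cohort import CohortError, GenotypeCounts

Z_95 = 1.959964


@dataclass(frozen=True)
class HWEResult:
    f: float
    se_f: float
    ci_low: float
    ci_high: float
    p_hwe: float
    allele_freq: float
    n: int


def _check_polymorphic(counts: GenotypeCounts) -> float:
    p = counts.alt_freq
    if p <= 0.0 or p >= 1.0:
        raise CohortError("f undefined for monomorphic locus")
    return p


def hwe_f(
    counts: GenotypeCounts,
    exact_p: bool = True,
    small_sample_correction: bool = True,
) -> HWEResult:
    """Departure coefficient f with a 95% Wald confidence interval.

    The quotient form of the coefficient is equivalently f = 1 - H_obs/H_exp
    with H_obs the observed heterozygote frequency and H_exp = 2p(1-p).
    With ``small_sample_correction`` (the default), H_exp carries the
    unbiased-heterozygosity factor 2n/(2n-1); without it the plain quotient
    is used, for which f = 0 exactly when the observed alt-homozygote
    frequency equals allele_freq².  The two differ by O(1/n).

    The standard error uses the asymptotic variance

        Var(f) = [ (1-f)^2 (1-2f) + f (1-f)(2-f) / (2 p (1-p)) ] / n,

    with p the minor-allele frequency.  f and p are carried at full
    precision; round only for display.  ``p_hwe`` is the exact conditional
    test p-value (or the 1-df chi-squared p if ``exact_p`` is false).
    """
    p = _check_polymorphic(counts)
    n = counts.n
    h_exp = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        h_exp *= 2.0 * n / (2.0 * n - 1.0)
    f = 1.0 - (counts.n_het / n) / h_exp
    var = ((1.0 - f) ** 2 * (1.0 - 2.0 * f) + f * (1.0 - f) * (2.0 - f) / (2.0 * p * (1.0 - p))) / n
    se = math.sqrt(max(var, 0.0))
    p_hwe = hwe_exact_p(counts) if exact_p else hwe_chisq_p(counts)
    return HWEResult(
        f=f,
        se_f=se,
        ci_low=f - Z_95 * se,
        ci_high=f + Z_95 * se,
        p_hwe=p_hwe,
        allele_freq=p,
        n=n,
    )


def expected_genotype_freqs(p: float, f: float) -> tuple[float, float, float]:
    """(ref-hom, het, alt-hom) frequencies induced by allele frequency p and departure f."""
    q = 1.0 - p
    return (q * q + f * p * q, 2.0 * p * q * (1.0 - f), p * p + f * p * q)


def _log_het_prob(n: int, n_alt_alleles: int, n_het: int) -> float:
    """Log conditional probability of a heterozygote count given allele counts.

    P(n_het | n, n_a) ∝ n! / (n_rr! n_het! n_aa!) * 2^n_het under the null
    that the 2n alleles pair at random (multivariate hypergeometric-type
    distribution of genotype configurations).
    """
    n_aa = (n_alt_alleles - n_het) // 2
    n_rr = n - n_het - n_aa
    lg = math.lgamma
    return (
        lg(n + 1) - lg(n_rr + 1) - lg(n_het + 1) - lg(n_aa + 1)
        + n_het * math.log(2.0)
        + lg(n_alt_alleles + 1) + lg(2 * n - n_alt_alleles + 1) - lg(2 * n + 1)
    )


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact conditional HWE test.

    Conditions on the observed allele counts and sums, over every
    heterozygote count of matching parity, the probabilities of all
    outcomes no more probable than the observed one (ties included in the
    rejection sum; no mid-p adjustment).  Monomorphic tables have a single
    outcome and return p = 1.
    """
    n = counts.n
    n_a = counts.n_alt_alleles
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    het_min = n_a % 2
    het_max = min(n_a, 2 * n - n_a)
    het_values = range(het_min, het_max + 1, 2)
    logps = {h: _log_het_prob(n, n_a, h) for h in het_values}
    obs = logps[counts.n_het]
    # tolerance guards against log-gamma rounding when comparing tied outcomes
    p = sum(math.exp(lp) for lp in logps.values() if lp <= obs + 1e-12)
    return min(p, 1.0)


def hwe_chisq_p(counts: GenotypeCounts) -> float:
    """1-df Pearson goodness-of-fit chi-squared test against HWE proportions."""
    p = counts.alt_freq
    if p <= 0.0 or p >= 1.0:
        return 1.0
    n = counts.n
    exp = [n * e for e in expected_genotype_freqs(p, 0.0)]
    stat = sum(
        (o - e) ** 2 / e for o, e in zip(counts.as_tuple(), exp) if e > 0
    )
    return float(stats.chi2.sf(stat, df=1))
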