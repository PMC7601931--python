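"""Genotype-phenotype and stage-phenotype statistics.

Implements the quantitative-trait side of the analysis: the Sn robust scale
estimator (double median of absolute pairwise differences), one-way ANOVA
with an optional Box-Cox transform and a Fligner-Killeen homogeneity check,
planned linear contrasts with the alerting and effect-size correlations,
a seeded bootstrap null for F statistics, Fisher's LSD post hoc test with
homogeneous-group notation, and a linear-trend contrast over ordinal
clinical stages.

Effect sizes for a contrast with weights λ_j on group means ȳ_j:

    L            = Σ λ_j ȳ_j
    F_contrast   = L² / (MSE · Σ λ_j²/n_j),  1 numerator df
    r_alerting   = corr(ȳ, λ)                 (ignores within-group noise)
    r_effect     = sign(L) · sqrt(F_contrast / (F_contrast + df_within))

r_alerting answers "how linear is the pattern of means?"; r_effect answers
"how much of the total variation does that pattern explain?".  With noisy
groups the two can diverge sharply: means can lie on a near-perfect line
(r_alerting ≈ 1) while the trend explains almost nothing (r_effect ≈ 0).
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortError

logger = logging.getLogger(__name__)

#: consistency factor making the Rousseeuw-Croux Sn unbiased for the
#: standard deviation under normality
SN_CONSISTENCY = 1.1926


class SnMode(str, enum.Enum):
    #: plain double median over j = 1..n (inner median includes j = i),
    #: midpoint convention for even-length medians
    EQ2_LITERAL = "eq2_literal"
    #: Rousseeuw-Croux estimator: j != i, high-median inner, low-median
    #: outer, scaled by the normal-consistency factor
    ROUSSEEUW_CROUX = "rousseeuw_croux"


@dataclass(frozen=True)
class SnResult:
    sn: float
    mode: SnMode


@dataclass
class QuantGroups:
    """Ordered groups of real-valued observations for one phenotype."""

    labels: list[str]
    values: list[np.ndarray]
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise CohortError("labels and value vectors must align")
        if len(self.labels) < 2:
            raise CohortError("need at least 2 groups")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if any(v.size == 0 for v in self.values):
            raise CohortError("every group must be nonempty")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_total(self) -> int:
        return int(sum(v.size for v in self.values))

    @property
    def sizes(self) -> np.ndarray:
        return np.array([v.size for v in self.values])

    @property
    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.values)


@dataclass(frozen=True)
class ContrastSpec:
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.allclose(w, 0.0):
            raise CohortError("contrast weights must be finite and not all zero")
        if abs(w.sum()) > 1e-9 * max(1.0, np.abs(w).max()):
            raise CohortError("contrast weights must sum to zero")


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    f_contrast: float
    df_within: int
    p_parametric: float
    r_alerting: float
    r_effect_size: float
    p_bootstrap: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_parametric: float
    variance_homogeneity_p: float
    mse: float
    boxcox_lambda: float | None = None
    p_bootstrap: float | None = None


@dataclass(frozen=True)
class LSDResult:
    labels: tuple[str, ...]
    p_matrix: np.ndarray
    alpha: float
    notation: str


# ---------------------------------------------------------------------------
# Sn robust scale
# ---------------------------------------------------------------------------

def _high_median(a: np.ndarray) -> float:
    """Order statistic of rank floor(n/2) + 1 (1-based)."""
    return float(np.partition(a, a.size // 2)[a.size // 2])


def _low_median(a: np.ndarray) -> float:
    """Order statistic of rank floor((n+1)/2) (1-based)."""
    k = (a.size + 1) // 2 - 1
    return float(np.partition(a, k)[k])


def sn_scale(x, mode: SnMode | str = SnMode.EQ2_LITERAL) -> SnResult:
    """Sn scale: med_i ( med_j |x_i - x_j| ).

    A robust dispersion measure interpretable as the typical absolute
    difference between two randomly sampled observations; unlike the MAD it
    needs no location estimate and keeps reasonable efficiency under
    asymmetry.  ``eq2_literal`` takes both medians as plain (midpoint)
    medians with the inner index running over all j including i;
    ``rousseeuw_croux`` is the classical estimator (j != i, high-median
    inner, low-median outer, consistency factor 1.1926).
    """
    mode = SnMode(mode)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise CohortError("sn_scale needs a nonempty 1-d vector")
    if x.size == 1:
        return SnResult(sn=0.0, mode=mode)
    diffs = np.abs(x[:, None] - x[None, :])
    if mode is SnMode.EQ2_LITERAL:
        inner = np.median(diffs, axis=1)
        return SnResult(sn=float(np.median(inner)), mode=mode)
    mask = ~np.eye(x.size, dtype=bool)
    inner = np.array([_high_median(diffs[i][mask[i]]) for i in range(x.size)])
    return SnResult(sn=SN_CONSISTENCY * _low_median(inner), mode=mode)


# ---------------------------------------------------------------------------
# ANOVA machinery
# ---------------------------------------------------------------------------

def _decompose(groups: QuantGroups) -> tuple[float, float, int, int]:
    """(SS_between, SS_within, df_between, df_within)."""
    grand = groups.pooled().mean()
    ss_b = float(sum(v.size * (v.mean() - grand) ** 2 for v in groups.values))
    ss_w = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values))
    return ss_b, ss_w, groups.k - 1, groups.n_total - groups.k


def boxcox_transform(x: np.ndarray, lmbda_range: tuple[float, float] = (-5.0, 5.0)):
    """Box-Cox transform with maximum-likelihood lambda over a bounded range."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise CohortError(
            "Box-Cox requires strictly positive data; shift the phenotype before transforming"
        )
    lam = float(stats.boxcox_normmax(x, brack=lmbda_range, method="mle"))
    lam = float(np.clip(lam, *lmbda_range))
    return stats.boxcox(x, lmbda=lam), lam


class Transform(str, enum.Enum):
    NONE = "none"
    BOXCOX = "boxcox"


def _apply_transform(groups: QuantGroups, transform: Transform) -> tuple[QuantGroups, float | None]:
    if transform is Transform.NONE:
        return groups, None
    pooled = groups.pooled()
    _, lam = boxcox_transform(pooled)
    values = [stats.boxcox(v, lmbda=lam) if lam != 0 else np.log(v) for v in groups.values]
    return QuantGroups(labels=list(groups.labels), values=values, units=groups.units), lam


def anova_oneway(groups: QuantGroups, transform: Transform | str = Transform.NONE) -> AnovaResult:
    """One-way fixed-effects ANOVA with a Fligner-Killeen homogeneity check.

    With ``transform='boxcox'`` the pooled data determine a single
    maximum-likelihood lambda which is applied to every group before the
    decomposition (a common monotone rescaling, so group structure is
    preserved).  An advisory message is logged when the Fligner-Killeen
    test or pooled skewness suggests a transform/bootstrap would be prudent.
    """
    transform = Transform(transform)
    if groups.n_total <= groups.k:
        raise CohortError("need more observations than groups")
    groups_t, lam = _apply_transform(groups, transform)
    ss_b, ss_w, df_b, df_w = _decompose(groups_t)
    if ss_w == 0.0:
        raise CohortError("zero within-group variance everywhere: F undefined")
    msb, mse = ss_b / df_b, ss_w / df_w
    f = msb / mse
    p = float(stats.f.sf(f, df_b, df_w))
    fligner_p = float(stats.fligner(*groups_t.values).pvalue)
    skew = float(stats.skew(groups_t.pooled()))
    if fligner_p < 0.05 or abs(skew) > 1.0:
        logger.info(
            "advisory: Fligner-Killeen p=%.3g, pooled skewness=%.2f — consider "
            "Box-Cox transform and/or bootstrap p-values", fligner_p, skew,
        )
    return AnovaResult(
        f=f, df_between=df_b, df_within=df_w, p_parametric=p,
        variance_homogeneity_p=fligner_p, mse=mse, boxcox_lambda=lam,
    )


def linear_contrast(groups: QuantGroups, contrast: ContrastSpec) -> ContrastResult:
    """Planned linear contrast on group means with effect-size correlations."""
    w = np.asarray(contrast.weights, dtype=float)
    if w.size != groups.k:
        raise CohortError(f"{w.size} weights for {groups.k} groups")
    means = groups.means
    sizes = groups.sizes
    _, ss_w, _, df_w = _decompose(groups)
    if df_w <= 0 or ss_w == 0.0:
        raise CohortError("within-group variance required for a contrast test")
    mse = ss_w / df_w
    L = float(w @ means)
    f_con = L * L / (mse * float((w * w / sizes).sum()))
    p = float(stats.f.sf(f_con, 1, df_w))
    # alerting correlation: Pearson r between the k means and the k weights
    mc, wc = means - means.mean(), w - w.mean()
    denom = math.sqrt(float(mc @ mc) * float(wc @ wc))
    r_alert = float(mc @ wc) / denom if denom > 0 else 0.0
    r_eff = math.copysign(math.sqrt(f_con / (f_con + df_w)), L) if f_con > 0 else 0.0
    return ContrastResult(
        estimate=L, f_contrast=f_con, df_within=df_w, p_parametric=p,
        r_alerting=r_alert, r_effect_size=r_eff,
    )


class BootStatistic(str, enum.Enum):
    OMNIBUS_F = "omnibus_F"
    CONTRAST_F = "contrast_F"


def bootstrap_f_pvalue(
    groups: QuantGroups,
    statistic: BootStatistic | str = BootStatistic.OMNIBUS_F,
    contrast: ContrastSpec | None = None,
    B: int = 10000,
    seed: int = 0,
) -> float:
    """Bootstrap p-value for an F statistic under the no-difference null.

    The null is imposed by centring each group at its own mean; the pooled
    residuals are resampled with replacement into the original group sizes
    B times and the statistic recomputed.  p = (1 + #{F* >= F_obs})/(B + 1),
    which is never zero and exact-friendly.  Deterministic for a fixed seed
    and invariant to group relabelling (the resampling pool is order-free).
    """
    statistic = BootStatistic(statistic)
    if B < 100:
        raise CohortError("B must be at least 100")
    if statistic is BootStatistic.CONTRAST_F and contrast is None:
        raise CohortError("contrast_F needs a ContrastSpec")

    # canonical group order + sorted residual pool make the resampling (and
    # hence p) invariant to the order in which groups are supplied
    order = sorted(
        range(groups.k),
        key=lambda j: (groups.values[j].size, groups.values[j].mean(), groups.values[j].sum()),
    )
    values0 = [groups.values[j] for j in order]
    labels0 = [groups.labels[j] for j in order]
    weights0 = (
        None if contrast is None else tuple(np.asarray(contrast.weights, float)[order])
    )
    sizes = np.array([v.size for v in values0])
    starts = np.concatenate([[0], np.cumsum(sizes)])
    resid = np.sort(np.concatenate([v - v.mean() for v in values0]))
    if np.allclose(resid, 0.0):
        return 1.0

    if statistic is BootStatistic.OMNIBUS_F:
        def stat_of(values: list[np.ndarray]) -> float:
            ss_b, ss_w, df_b, df_w = _decompose(QuantGroups(labels=labels0, values=values))
            return math.inf if ss_w == 0 else (ss_b / df_b) / (ss_w / df_w)
    else:
        cspec = ContrastSpec(weights=weights0)

        def stat_of(values: list[np.ndarray]) -> float:
            return linear_contrast(QuantGroups(labels=labels0, values=values), cspec).f_contrast

    f_obs = stat_of(values0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, resid.size, size=(B, resid.size))
    draws = resid[idx]
    exceed = 0
    for b in range(B):
        row = draws[b]
        values = [row[starts[j]:starts[j + 1]] for j in range(groups.k)]
        try:
            if stat_of(values) >= f_obs:
                exceed += 1
        except CohortError:  # degenerate resample
            continue
    return (1 + exceed) / (B + 1)


# ---------------------------------------------------------------------------
# Fisher's LSD and homogeneous-group notation
# ---------------------------------------------------------------------------

def fisher_lsd(groups: QuantGroups, alpha: float = 0.05) -> LSDResult:
    """All pairwise t tests with pooled MSE, plus homogeneous-group notation.

    The notation lists maximal cliques of mutually non-different groups in
    group order; cliques of more than one group are parenthesised with '.'
    separators, e.g. ``"AA (AG.GG)"`` means AA differs from both AG and GG,
    which do not differ from each other.  Unprotected (reported regardless
    of the omnibus result), two-sided.
    """
    k = groups.k
    if all(v.size < 2 for v in groups.values):
        raise CohortError("Fisher LSD needs at least one group of size >= 2")
    _, ss_w, _, df_w = _decompose(groups)
    if df_w <= 0 or ss_w == 0.0:
        raise CohortError("within-group variance required for LSD")
    mse = ss_w / df_w
    means, sizes = groups.means, groups.sizes
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[j]))
        t = (means[i] - means[j]) / se
        pmat[i, j] = pmat[j, i] = 2.0 * float(stats.t.sf(abs(t), df_w))
    notation = homogeneous_group_notation(list(groups.labels), pmat, alpha)
    return LSDResult(labels=tuple(groups.labels), p_matrix=pmat, alpha=alpha, notation=notation)


def homogeneous_group_notation(labels: list[str], p_matrix: np.ndarray, alpha: float) -> str:
    """Render maximal non-significant cliques as a grouping string.

    Groups i, j are "homogeneous" when p[i,j] >= alpha; cliques are maximal
    label subsets with every internal pair homogeneous, emitted in order of
    their first member.
    """
    k = len(labels)
    adj = p_matrix >= alpha
    cliques: list[tuple[int, ...]] = []
    for r in range(k, 0, -1):
        for combo in itertools.combinations(range(k), r):
            if all(adj[i, j] for i, j in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    cliques.sort(key=lambda c: c[0])
    parts = []
    for c in cliques:
        names = [labels[i] for i in c]
        parts.append(names[0] if len(c) == 1 else "(" + ".".join(names) + ")")
    return " ".join(parts)


def trend_by_ordinal(groups: QuantGroups) -> ContrastResult:
    """Linear-trend contrast over ordered (e.g. clinical-stage) groups.

    Uses centred, equally spaced weights over the group order, so a
    positive estimate means the phenotype rises with the ordinal score.
    """
    if groups.k < 3:
        raise CohortError("trend test needs at least 3 ordered groups")
    scores = np.arange(groups.k, dtype=float)
    w = scores - scores.mean()
    return linear_contrast(groups, ContrastSpec(weights=tuple(w)))


def group_summary(groups: QuantGroups) -> "pd.DataFrame":
    """Descriptive table: n, mean, Sn, median, quartiles, min, max per group."""
    import pandas as pd

    rows = []
    for label, v in zip(groups.labels, groups.values):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "group": label, "n": v.size, "mean": v.mean(),
                "sn": sn_scale(v).sn, "median": med, "q1": q1, "q3": q3,
                "min": v.min(), "max": v.max(), "units": groups.units,
            }
        )
    return pd.DataFrame(rows)


def box_whisker_plot(groups: QuantGroups, ax=None, title: str = ""):
    """Box-and-whisker display: mean as central point, quartile box, min-max whiskers."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots()
    positions = np.arange(1, groups.k + 1)
    for pos, v in zip(positions, groups.values):
        q1, q3 = np.percentile(v, [25, 75])
        ax.add_patch(
            Rectangle((pos - 0.25, q1), 0.5, q3 - q1, fill=False, edgecolor="black")
        )
        ax.vlines(pos, v.min(), v.max(), color="black", lw=0.8)
        ax.plot(pos, v.mean(), "ks", ms=5)
    ax.set_xticks(positions, groups.labels)
    if groups.units:
        ax.set_ylabel(groups.units)
    if title:
        ax.set_title(title)
    return ax
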