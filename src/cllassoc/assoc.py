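"""Case-control association statistics: genotype chi-squared tests and odds ratios.

Per-genotype odds ratios are computed against the homozygote of the more
frequent allele as reference.  Every reported odds ratio applies the
Haldane-Anscombe continuity correction (+0.5 added to all four cells
unconditionally), which keeps the estimate and its log-variance finite for
tables with empty cells; the confidence interval is the Woolf (log-OR Wald)
interval on the corrected cells.  Collapsed dominant/recessive/allelic
models reduce the 3x2 genotype table to 2x2 before the same machinery.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    Cohort,
    CohortError,
    GenotypeCounts,
    SnpDef,
    Status,
    tally_genotypes,
)
from .hwe import Z_95, hwe_chisq_p, hwe_f

__all__ = [
    "CaseControlTable",
    "ChiSquareResult",
    "Correction",
    "GeneticModel",
    "ModelKind",
    "OddsRatioResult",
    "association_report",
    "genotype_chisq",
    "model_odds_ratio",
    "odds_ratio_2x2",
    "case_control_table",
]


class Correction(str, enum.Enum):
    NONE = "none"
    HALDANE_ANSCOMBE = "haldane_anscombe"


class ModelKind(str, enum.Enum):
    CODOMINANT_PER_GENOTYPE = "codominant_per_genotype"
    DOMINANT_FOR_ALLELE = "dominant_for_allele"
    RECESSIVE_FOR_ALLELE = "recessive_for_allele"
    ALLELIC = "allelic"


@dataclass(frozen=True)
class GeneticModel:
    """Genotype-collapsing rule plus the allele whose effect is tested.

    dominant: carriers (het + effect-allele hom) vs the other homozygote;
    recessive: effect-allele hom vs the rest; allelic: 2n allele counts.
    """

    kind: ModelKind
    effect_allele: str


@dataclass(frozen=True)
class CaseControlTable:
    snp_id: str
    case_counts: GenotypeCounts
    control_counts: GenotypeCounts


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    correction: Correction
    comparison: str
    p_chisq: float | None = None
    p_fisher: float | None = None


def case_control_table(cohort: Cohort, snp: SnpDef | str) -> CaseControlTable:
    if isinstance(snp, str):
        snp = cohort.snp_defs[snp]
    return CaseControlTable(
        snp_id=snp.snp_id,
        case_counts=tally_genotypes(cohort, snp, Status.CASE),
        control_counts=tally_genotypes(cohort, snp, Status.CONTROL),
    )


def genotype_chisq(table: CaseControlTable) -> ChiSquareResult:
    """Pearson chi-squared on the 3x2 genotype-by-status table (no continuity correction).

    A genotype class empty in both arms is dropped (with reduced df) rather
    than contributing an undefined expected count.
    """
    obs = np.array([table.case_counts.as_tuple(), table.control_counts.as_tuple()], dtype=float)
    keep = obs.sum(axis=0) > 0
    if keep.sum() < 2:
        raise CohortError(f"{table.snp_id}: fewer than two non-empty genotype classes")
    if not keep.all():
        import logging

        logging.getLogger(__name__).warning(
            "%s: dropping %d empty genotype class(es) from chi-squared",
            table.snp_id, int((~keep).sum()),
        )
        obs = obs[:, keep]
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def odds_ratio_2x2(
    n_exposed_case: int,
    n_ref_case: int,
    n_exposed_ctrl: int,
    n_ref_ctrl: int,
    correction: Correction = Correction.HALDANE_ANSCOMBE,
    z: float = Z_95,
    comparison: str = "",
) -> OddsRatioResult:
    """Odds ratio with Woolf confidence interval for a 2x2 exposure-by-status table.

    With the Haldane-Anscombe correction, 0.5 is added to all four cells
    unconditionally before both the cross-product ratio and the log-OR
    standard error sqrt(1/a + 1/b + 1/c + 1/d).
    """
    cells = [n_exposed_case, n_ref_case, n_exposed_ctrl, n_ref_ctrl]
    if min(cells) < 0:
        raise CohortError("negative cell count")
    if n_exposed_case + n_ref_case == 0 or n_exposed_ctrl + n_ref_ctrl == 0:
        raise CohortError("an arm of the 2x2 table is empty")
    a, b, c, d = cells
    if correction is Correction.HALDANE_ANSCOMBE:
        a, b, c, d = (x + 0.5 for x in cells)
    elif 0 in cells:
        raise CohortError("zero cell with correction='none'; use haldane_anscombe")
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return OddsRatioResult(
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_or=log_or,
        se_log_or=se,
        correction=correction,
        comparison=comparison,
    )


def _collapse(counts: GenotypeCounts, snp: SnpDef, model: GeneticModel) -> tuple[int, int]:
    """(exposed, reference) totals for one arm under a collapsing model."""
    n_rr, n_het, n_aa = counts.as_tuple()
    minor = snp.minor_allele
    if model.effect_allele not in (snp.ref_allele, snp.alt_allele):
        raise CohortError(f"effect allele {model.effect_allele!r} not declared for {snp.snp_id}")
    effect_is_minor = model.effect_allele == minor
    hom_effect, hom_other = (n_aa, n_rr) if effect_is_minor else (n_rr, n_aa)
    if model.kind is ModelKind.DOMINANT_FOR_ALLELE:
        return hom_effect + n_het, hom_other
    if model.kind is ModelKind.RECESSIVE_FOR_ALLELE:
        return hom_effect, hom_other + n_het
    if model.kind is ModelKind.ALLELIC:
        return 2 * hom_effect + n_het, 2 * hom_other + n_het
    raise CohortError(f"model {model.kind} does not collapse to 2x2")


def model_odds_ratio(
    table: CaseControlTable,
    model: GeneticModel,
    snp: SnpDef,
    correction: Correction = Correction.HALDANE_ANSCOMBE,
) -> OddsRatioResult:
    """Collapse the genotype table per the genetic model, then compute the OR.

    Also attaches the collapsed 2x2 table's 1-df chi-squared p-value and
    Fisher exact p-value (both on uncorrected counts).
    """
    exp_case, ref_case = _collapse(table.case_counts, snp, model)
    exp_ctrl, ref_ctrl = _collapse(table.control_counts, snp, model)
    label = {
        ModelKind.DOMINANT_FOR_ALLELE: f"{model.effect_allele}-carriers vs non-carriers",
        ModelKind.RECESSIVE_FOR_ALLELE: f"{model.effect_allele}{model.effect_allele} vs rest",
        ModelKind.ALLELIC: f"allele {model.effect_allele} vs other",
    }[model.kind]
    res = odds_ratio_2x2(
        exp_case, ref_case, exp_ctrl, ref_ctrl, correction=correction, comparison=label
    )
    obs = np.array([[exp_case, ref_case], [exp_ctrl, ref_ctrl]], dtype=float)
    chi_p = float(stats.chi2_contingency(obs, correction=False)[1]) if (obs.sum(0) > 0).all() else None
    fisher_p = float(stats.fisher_exact([[exp_case, ref_case], [exp_ctrl, ref_ctrl]])[1])
    return dataclasses.replace(res, p_chisq=chi_p, p_fisher=fisher_p)


REPORT_COLUMNS = [
    "snp", "genotype", "n_case", "pct_case", "n_ctrl", "pct_ctrl",
    "or", "ci_low", "ci_high", "chisq", "df", "p",
    "f_case", "f_case_ci", "p_hwe_case", "f_ctrl", "f_ctrl_ci", "p_hwe_ctrl",
]


def _genotype_rows(snp: SnpDef) -> list[tuple[str, str]]:
    """(label, class) rows in display order: major-hom, het, minor-hom."""
    major, minor = snp.major_allele, snp.minor_allele
    return [
        (major + major, "ref_hom"),
        (major + minor, "het"),
        (minor + minor, "alt_hom"),
    ]


def association_report(
    cohort: Cohort,
    correction: Correction = Correction.HALDANE_ANSCOMBE,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-SNP association table: counts, percentages, ORs, chi-squared, HWE.

    One row per genotype plus one row each for the dominant and recessive
    models of the minor allele.  The reference genotype's OR (exactly 1 by
    construction) is omitted.  Percentages are display values rounded to 2
    decimals.  With ``bh_adjust``, a Benjamini-Hochberg-adjusted omnibus
    p-value column is appended for exploratory multi-SNP runs.
    """
    rows: list[dict] = []
    omnibus_ps: list[float] = []
    for snp_id, snp in cohort.snp_defs.items():
        table = case_control_table(cohort, snp)
        chisq = genotype_chisq(table)
        omnibus_ps.append(chisq.p)
        hwe_case = hwe_f(table.case_counts)
        hwe_ctrl = hwe_f(table.control_counts)
        n_case_tot = table.case_counts.n
        n_ctrl_tot = table.control_counts.n
        counts_by_class = {
            "ref_hom": (table.case_counts.n_ref_hom, table.control_counts.n_ref_hom),
            "het": (table.case_counts.n_het, table.control_counts.n_het),
            "alt_hom": (table.case_counts.n_alt_hom, table.control_counts.n_alt_hom),
        }
        ref_case, ref_ctrl = counts_by_class["ref_hom"]
        shared = {
            "snp": snp_id,
            "chisq": chisq.statistic,
            "df": chisq.df,
            "p": chisq.p,
            "f_case": hwe_case.f,
            "f_case_ci": f"{hwe_case.ci_low:.2f};{hwe_case.ci_high:.2f}",
            "p_hwe_case": hwe_case.p_hwe,
            "f_ctrl": hwe_ctrl.f,
            "f_ctrl_ci": f"{hwe_ctrl.ci_low:.2f};{hwe_ctrl.ci_high:.2f}",
            "p_hwe_ctrl": hwe_ctrl.p_hwe,
        }
        for label, cls in _genotype_rows(snp):
            n_case, n_ctrl = counts_by_class[cls]
            row = {
                **shared,
                "genotype": label,
                "n_case": n_case,
                "pct_case": round(100.0 * n_case / n_case_tot, 2),
                "n_ctrl": n_ctrl,
                "pct_ctrl": round(100.0 * n_ctrl / n_ctrl_tot, 2),
                "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            }
            if cls != "ref_hom":
                orr = odds_ratio_2x2(
                    n_case, ref_case, n_ctrl, ref_ctrl,
                    correction=correction,
                    comparison=f"{label} vs reference",
                )
                row.update({"or": orr.or_point, "ci_low": orr.ci_low, "ci_high": orr.ci_high})
            rows.append(row)
        for kind in (ModelKind.DOMINANT_FOR_ALLELE, ModelKind.RECESSIVE_FOR_ALLELE):
            model = GeneticModel(kind=kind, effect_allele=snp.minor_allele)
            orr = model_odds_ratio(table, model, snp, correction=correction)
            rows.append(
                {
                    **shared,
                    "genotype": f"{kind.value.split('_')[0]}:{snp.minor_allele}",
                    "n_case": n_case_tot, "pct_case": np.nan,
                    "n_ctrl": n_ctrl_tot, "pct_ctrl": np.nan,
                    "or": orr.or_point, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                }
            )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if bh_adjust and omnibus_ps:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(omnibus_ps, method="fdr_bh")[1]
        p_adj = dict(zip(cohort.snp_defs.keys(), adj))
        df["p_bh"] = df["snp"].map(p_adj)
    return df
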