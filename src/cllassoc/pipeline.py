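"""Pipeline orchestration: config-driven QC -> HWE -> association -> quantitative stages.

A single YAML config names the input tables, the SNP definitions, the CNV
exclusion rule, and the quantitative analyses (phenotype x grouping x
contrast).  Outputs are CSVs with fixed column orders plus a run log; runs
are deterministic given inputs and seed.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import quant
from .assoc import Correction, association_report
from .cohort import (
    Cohort,
    CohortError,
    SnpDef,
    Status,
    attach_tables,
    apply_cnv_exclusion,
    read_cnv_table,
    read_genotype_table,
    read_phenotype_table,
    read_samples_table,
    read_vcf_subset,
)

logger = logging.getLogger("cllassoc")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class QuantAnalysisSpec:
    phenotype: str
    group_by: str  # "genotype" or "stage"
    snp: str | None = None
    order: list[str] | None = None
    contrast: list[float] | None = None
    boxcox: bool = False
    bootstrap: bool = False
    arm: str = "case"

    def __post_init__(self) -> None:
        if self.group_by not in ("genotype", "stage"):
            raise CohortError(f"group_by must be 'genotype' or 'stage', got {self.group_by!r}")
        if self.group_by == "genotype" and not self.snp:
            raise CohortError(f"{self.phenotype}: genotype grouping needs a snp")


@dataclass
class RunConfig:
    inputs: dict[str, str]
    snp_defs: list[SnpDef]
    output_dir: str
    cnv_genes: list[str] = field(default_factory=list)
    cnv_threshold: int = 2
    correction: Correction = Correction.HALDANE_ANSCOMBE
    bh_adjust: bool = False
    quant_analyses: list[QuantAnalysisSpec] = field(default_factory=list)
    bootstrap_B: int = 10000
    seed: int | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if any(a.bootstrap for a in self.quant_analyses) and self.seed is None:
            raise CohortError("seed is mandatory when bootstrap p-values are enabled")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    inputs = {k: resolve(v) for k, v in raw.get("inputs", {}).items()}
    for k, p in inputs.items():
        if not os.path.exists(p):
            raise CohortError(f"input {k}: file not found: {p}")
    snp_defs = [
        SnpDef(
            snp_id=d["snp_id"],
            gene=d.get("gene", ""),
            ref_allele=d["ref"],
            alt_allele=d["alt"],
            minor_allele=d.get("minor", ""),
            chrom=str(d.get("chrom", "17")),
            pos=int(d.get("pos", 0)),
        )
        for d in raw.get("snps", [])
    ]
    cnv = raw.get("cnv_exclusion", {}) or {}
    assoc_cfg = raw.get("association", {}) or {}
    analyses = [QuantAnalysisSpec(**a) for a in raw.get("quant", []) or []]
    return RunConfig(
        inputs=inputs,
        snp_defs=snp_defs,
        output_dir=resolve(raw["output_dir"]),
        cnv_genes=list(cnv.get("genes", [])),
        cnv_threshold=int(cnv.get("threshold", 2)),
        correction=Correction(assoc_cfg.get("correction", "haldane_anscombe")),
        bh_adjust=bool(assoc_cfg.get("bh", False)),
        quant_analyses=analyses,
        bootstrap_B=int(raw.get("bootstrap_B", 10000)),
        seed=raw.get("seed"),
        alpha=float(raw.get("alpha", 0.05)),
    )


def _setup_logging(outdir: str) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(os.path.join(outdir, "run.log"), mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _load_cohort(config: RunConfig) -> Cohort:
    inputs = config.inputs
    if "vcf" in inputs:
        cohort = read_vcf_subset(inputs["vcf"])
        declared = {d.snp_id: d for d in config.snp_defs}
        for snp_id, d in declared.items():  # declared defs override VCF-derived ones
            if snp_id in cohort.snp_defs:
                cohort.snp_defs[snp_id] = d
    elif "genotypes" in inputs:
        cohort = read_genotype_table(inputs["genotypes"], config.snp_defs)
    else:
        raise CohortError("config must name a 'genotypes' TSV or a 'vcf' input")
    samples_df = read_samples_table(inputs["samples"]) if "samples" in inputs else None
    phen_df = read_phenotype_table(inputs["phenotypes"]) if "phenotypes" in inputs else None
    cnv_df = read_cnv_table(inputs["cnv"]) if "cnv" in inputs else None
    return attach_tables(cohort, samples_df, phen_df, cnv_df)


def _genotype_groups(
    cohort: Cohort, spec: QuantAnalysisSpec
) -> quant.QuantGroups | None:
    snp = cohort.snp_defs[spec.snp]
    order = spec.order or [
        snp.major_allele * 2,
        snp.major_allele + snp.minor_allele,
        snp.minor_allele * 2,
    ]
    status = Status(spec.arm)
    buckets: dict[str, list[float]] = {label: [] for label in order}
    for s in cohort.by_status(status):
        gt = s.genotypes.get(spec.snp)
        val = s.phenotypes.get(spec.phenotype)
        if gt is None or val is None:
            continue
        label = gt.display(snp)
        if label not in buckets and label[::-1] in buckets:
            label = label[::-1]
        if label in buckets:
            buckets[label].append(val)
    kept = [(lab, v) for lab, v in buckets.items() if v]
    if len(kept) < 2:
        return None
    return quant.QuantGroups(
        labels=[lab for lab, _ in kept],
        values=[np.array(v) for _, v in kept],
        units=cohort.phenotype_units.get(spec.phenotype, ""),
    )


def _stage_groups(cohort: Cohort, spec: QuantAnalysisSpec) -> quant.QuantGroups | None:
    buckets: dict[int, list[float]] = {}
    for s in cohort.by_status(Status(spec.arm)):
        val = s.phenotypes.get(spec.phenotype)
        if s.stage is None or val is None:
            continue
        buckets.setdefault(s.stage, []).append(val)
    stages = sorted(buckets)
    if len(stages) < 2:
        return None
    return quant.QuantGroups(
        labels=[str(st) for st in stages],
        values=[np.array(buckets[st]) for st in stages],
        units=cohort.phenotype_units.get(spec.phenotype, ""),
    )


QUANT_TEST_COLUMNS = [
    "phenotype", "group_by", "snp", "f", "df_between", "df_within",
    "p_param", "p_boot", "fligner_p", "lambda", "lsd_notation",
    "f_contrast", "contrast_p_param", "contrast_p_boot", "r_alerting", "r_effect_size",
]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute every configured stage; returns a name -> path map of outputs.

    Stage order: load -> CNV exclusion -> association report (with HWE) ->
    quantitative analyses.  Any stage error is re-raised as PipelineError
    tagged with the stage name; partial outputs stay on disk.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    _setup_logging(config.output_dir)
    outputs: dict[str, str] = {"log": os.path.join(config.output_dir, "run.log")}
    logger.info(
        "libraries of record: numpy %s, scipy %s, pandas %s",
        np.__version__, __import__("scipy").__version__, pd.__version__,
    )

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrap

    cohort = stage("load")(_load_cohort, config)
    logger.info("loaded %d samples, %d SNPs", len(cohort.samples), len(cohort.snp_defs))

    if config.cnv_genes:
        cohort, report = stage("cnv_exclusion")(
            apply_cnv_exclusion, cohort, config.cnv_genes, config.cnv_threshold
        )
        excl_path = os.path.join(config.output_dir, "exclusions.csv")
        pd.DataFrame({"removed_sample_id": report.removed_sample_ids}).to_csv(
            excl_path, index=False
        )
        outputs["exclusions"] = excl_path
        for gene, frac in report.single_copy_fraction.items():
            logger.info("CNV exclusion: %s single-copy fraction %.2f%%", gene, 100 * frac)
        logger.info(
            "CNV exclusion removed %d of %d samples", len(report.removed_sample_ids),
            report.n_input,
        )

    assoc_df = stage("association")(
        association_report, cohort, config.correction, config.bh_adjust
    )
    assoc_path = os.path.join(config.output_dir, "association.csv")
    assoc_df.to_csv(assoc_path, index=False, float_format="%.6g")
    outputs["association"] = assoc_path
    logger.info("association report: %d rows -> %s", len(assoc_df), os.path.basename(assoc_path))

    have_phenotypes = any(s.phenotypes for s in cohort.samples)
    if config.quant_analyses and not have_phenotypes:
        logger.warning("no phenotype values loaded; quantitative stage skipped")
    elif config.quant_analyses:
        test_rows = []
        for spec in config.quant_analyses:
            groups = stage("quant")(
                _genotype_groups if spec.group_by == "genotype" else _stage_groups,
                cohort, spec,
            )
            if groups is None:
                logger.warning(
                    "%s by %s: fewer than 2 nonempty groups; skipped",
                    spec.phenotype, spec.group_by,
                )
                continue
            transform = quant.Transform.BOXCOX if spec.boxcox else quant.Transform.NONE
            anova = stage("quant")(quant.anova_oneway, groups, transform)
            lsd = stage("quant")(quant.fisher_lsd, groups, config.alpha)
            summary = quant.group_summary(groups)
            spath = os.path.join(
                config.output_dir, f"quant_{spec.phenotype}_{spec.group_by}_summary.csv"
            )
            summary.to_csv(spath, index=False, float_format="%.6g")
            outputs[f"summary:{spec.phenotype}:{spec.group_by}"] = spath

            contrast_res = None
            if spec.group_by == "stage" and groups.k >= 3:
                contrast_res = stage("quant")(quant.trend_by_ordinal, groups)
            elif spec.contrast:
                contrast_res = stage("quant")(
                    quant.linear_contrast, groups, quant.ContrastSpec(tuple(spec.contrast))
                )
            p_boot = contrast_p_boot = None
            if spec.bootstrap:
                p_boot = stage("quant")(
                    quant.bootstrap_f_pvalue, groups, "omnibus_F",
                    None, config.bootstrap_B, config.seed,
                )
                if contrast_res is not None:
                    weights = (
                        contrast_res and quant.ContrastSpec(
                            tuple(spec.contrast)
                            if spec.contrast
                            else tuple(
                                np.arange(groups.k, dtype=float)
                                - (groups.k - 1) / 2.0
                            )
                        )
                    )
                    contrast_p_boot = stage("quant")(
                        quant.bootstrap_f_pvalue, groups, "contrast_F",
                        weights, config.bootstrap_B, config.seed,
                    )
            test_rows.append(
                {
                    "phenotype": spec.phenotype,
                    "group_by": spec.group_by,
                    "snp": spec.snp or "",
                    "f": anova.f,
                    "df_between": anova.df_between,
                    "df_within": anova.df_within,
                    "p_param": anova.p_parametric,
                    "p_boot": p_boot,
                    "fligner_p": anova.variance_homogeneity_p,
                    "lambda": anova.boxcox_lambda,
                    "lsd_notation": lsd.notation,
                    "f_contrast": contrast_res.f_contrast if contrast_res else None,
                    "contrast_p_param": contrast_res.p_parametric if contrast_res else None,
                    "contrast_p_boot": contrast_p_boot,
                    "r_alerting": contrast_res.r_alerting if contrast_res else None,
                    "r_effect_size": contrast_res.r_effect_size if contrast_res else None,
                }
            )
            logger.info(
                "%s by %s: F=%.4g p=%.4g LSD %s",
                spec.phenotype, spec.group_by, anova.f, anova.p_parametric, lsd.notation,
            )
        if test_rows:
            tpath = os.path.join(config.output_dir, "quant_tests.csv")
            pd.DataFrame(test_rows, columns=QUANT_TEST_COLUMNS).to_csv(
                tpath, index=False, float_format="%.6g"
            )
            outputs["quant_tests"] = tpath
    return outputs
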