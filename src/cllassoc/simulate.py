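"""Synthetic cohort generator with known ground truth.

Generates case-control cohorts with exactly the statistical structure the
pipeline assumes, so every stage can be exercised against known parameters
without any external data:

* biallelic genotypes at a chosen minor-allele frequency ``q`` with a chosen
  Hardy-Weinberg departure ``f`` (the three genotype probabilities are the
  algebraic inverse of the departure coefficient);
* case genotype frequencies obtained by reweighting the control genotype
  probabilities with per-genotype odds ratios and renormalising — the exact
  genotype-level logistic-model correspondence, which makes odds-ratio
  recovery targets analytic;
* genotype-conditional phenotypes (normal or log-normal), optionally with a
  linear mean shift per ordinal clinical stage;
* a fraction of samples flagged as single-copy (hemizygous deletion) per
  gene, and per-SNP missing-genotype masking.

Randomness policy: one base seed per cohort; each SNP and each phenotype
uses its own substream keyed by the base seed and a stable hash of its
identifier, so adding a phenotype never perturbs the genotypes already
generated.
"""

from __future__ import annotations

import dataclasses
import enum
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, CohortError, Genotype, Sample, SnpDef, Status

__all__ = [
    "CohortSpec",
    "PhenotypeModel",
    "SnpSimSpec",
    "simulate_case_control",
    "simulate_genotypes",
    "simulate_phenotypes",
    "genotype_probs",
]


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Independent generator keyed by the base seed and stable name hashes."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


def genotype_probs(q: float, f: float) -> np.ndarray:
    """(ref-hom, het, alt-hom) probabilities for minor-allele frequency q, departure f."""
    if not 0.0 <= q <= 1.0:
        raise CohortError(f"allele frequency {q} outside [0,1]")
    probs = np.array(
        [
            (1.0 - q) ** 2 + f * q * (1.0 - q),
            2.0 * q * (1.0 - q) * (1.0 - f),
            q * q + f * q * (1.0 - q),
        ]
    )
    for name, p in zip(("ref-hom", "het", "alt-hom"), probs):
        if not -1e-12 <= p <= 1.0 + 1e-12:
            raise CohortError(f"(q={q}, f={f}) gives invalid P({name}) = {p:.4g}")
    return np.clip(probs, 0.0, 1.0)


class Family(str, enum.Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"


@dataclass(frozen=True)
class SnpSimSpec:
    """Simulation parameters for one SNP.

    ``odds_ratios`` are per-genotype disease odds ratios relative to the
    ref-hom class, ordered (ref-hom, het, alt-hom); when given they define
    the case genotype distribution by multiplicative reweighting of the
    control distribution.  When absent, cases are drawn directly at
    (q, f_case).
    """

    snp: SnpDef
    q: float
    f_ctrl: float = 0.0
    f_case: float = 0.0
    odds_ratios: tuple[float, float, float] | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        genotype_probs(self.q, self.f_ctrl)  # validate early
        if self.odds_ratios is None:
            genotype_probs(self.q, self.f_case)
        else:
            if self.odds_ratios[0] != 1.0:
                raise CohortError("odds_ratios are relative to ref-hom; first entry must be 1")
            if min(self.odds_ratios) <= 0:
                raise CohortError("odds ratios must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortError("missing_rate must be in [0,1)")

    def control_probs(self) -> np.ndarray:
        return genotype_probs(self.q, self.f_ctrl)

    def case_probs(self) -> np.ndarray:
        if self.odds_ratios is None:
            return genotype_probs(self.q, self.f_case)
        w = self.control_probs() * np.asarray(self.odds_ratios)
        return w / w.sum()


@dataclass(frozen=True)
class PhenotypeModel:
    """Genotype-conditional phenotype distribution, optionally stage-trending.

    For ``lognormal``, ``loc_by_genotype``/``scale`` are the mean and SD on
    the log scale.  ``stage_slope`` adds ``slope * stage`` to each case's
    (natural-scale) value after the family draw.  ``case_only`` restricts
    measurement to cases, as for tumour-cell phenotypes.
    """

    phenotype_id: str
    snp_id: str
    family: Family
    loc_by_genotype: tuple[float, float, float]
    scale: float
    units: str = ""
    stage_slope: float = 0.0
    case_only: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.scale < 0:
            raise CohortError(f"{self.phenotype_id}: negative scale")


@dataclass(frozen=True)
class CohortSpec:
    n_case: int
    n_ctrl: int
    snps: tuple[SnpSimSpec, ...]
    phenotypes: tuple[PhenotypeModel, ...] = ()
    #: probabilities of ordinal stages 0..4, assigned to cases
    stage_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: gene_id -> fraction of samples carrying a single copy
    single_copy_fraction: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_ctrl <= 0:
            raise CohortError("both arms must be nonempty")
        if len(self.stage_probs) != 5 or abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise CohortError("stage_probs must be 5 probabilities summing to 1")
        for g, frac in self.single_copy_fraction.items():
            if not 0.0 <= frac < 1.0:
                raise CohortError(f"single_copy_fraction[{g}] outside [0,1)")


def simulate_genotypes(n: int, q: float, f: float, seed_or_rng) -> np.ndarray:
    """Draw n genotypes coded 0/1/2 (minor-allele count) at frequency q, departure f."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    probs = genotype_probs(q, f)
    return rng.choice(3, size=n, p=probs)


def _codes_to_genotypes(codes: np.ndarray, snp: SnpDef) -> list[Genotype | None]:
    major, minor = snp.major_allele, snp.minor_allele
    lut = [Genotype(major, major), Genotype(major, minor), Genotype(minor, minor)]
    return [lut[c] for c in codes]


def simulate_case_control(spec: CohortSpec) -> Cohort:
    """Generate the genotype/CNV/stage layer of a synthetic cohort."""
    samples = [
        Sample(sample_id=f"case{i:06d}", status=Status.CASE) for i in range(spec.n_case)
    ] + [
        Sample(sample_id=f"ctrl{i:06d}", status=Status.CONTROL) for i in range(spec.n_ctrl)
    ]
    snp_defs: dict[str, SnpDef] = {}
    for pos0, snp_spec in enumerate(spec.snps):
        snp = snp_spec.snp
        if snp.pos == 0:
            snp = dataclasses.replace(snp, pos=10_000 + 1_000 * pos0)
        snp_defs[snp.snp_id] = snp
        rng = _substream(spec.seed, "genotypes", snp.snp_id)
        case_codes = rng.choice(3, size=spec.n_case, p=snp_spec.case_probs())
        ctrl_codes = rng.choice(3, size=spec.n_ctrl, p=snp_spec.control_probs())
        codes = np.concatenate([case_codes, ctrl_codes])
        gts = _codes_to_genotypes(codes, snp)
        if snp_spec.missing_rate > 0:
            mask = rng.random(len(samples)) < snp_spec.missing_rate
            gts = [None if m else g for g, m in zip(gts, mask)]
        for s, g in zip(samples, gts):
            s.genotypes[snp.snp_id] = g
    for gene, frac in spec.single_copy_fraction.items():
        rng = _substream(spec.seed, "cnv", gene)
        single = rng.random(len(samples)) < frac
        for s, one_copy in zip(samples, single):
            s.copy_numbers[gene] = 1 if one_copy else 2
    rng = _substream(spec.seed, "stage")
    stages = rng.choice(5, size=spec.n_case, p=np.asarray(spec.stage_probs))
    for s, st in zip(samples[: spec.n_case], stages):
        s.stage = int(st)
    return Cohort(samples=samples, snp_defs=snp_defs)


def simulate_phenotypes(cohort: Cohort, spec: CohortSpec) -> Cohort:
    """Attach genotype-conditional phenotype draws to an existing cohort."""
    for model in spec.phenotypes:
        if model.snp_id not in cohort.snp_defs:
            raise CohortError(f"{model.phenotype_id}: unknown conditioning SNP {model.snp_id}")
        snp = cohort.snp_defs[model.snp_id]
        minor = snp.minor_allele
        rng = _substream(spec.seed, "phenotype", model.phenotype_id)
        cohort.phenotype_units[model.phenotype_id] = model.units
        for s in cohort.samples:
            if model.case_only and s.status is not Status.CASE:
                continue
            gt = s.genotypes.get(model.snp_id)
            if gt is None:
                continue
            loc = model.loc_by_genotype[gt.count_allele(minor)]
            z = rng.standard_normal()
            if model.family is Family.NORMAL:
                value = loc + model.scale * z
            else:
                value = float(np.exp(loc + model.scale * z))
            if model.stage_slope and s.stage is not None:
                value += model.stage_slope * s.stage
            if model.units == "%":
                value = float(np.clip(value, 0.0, 100.0))
            s.phenotypes[model.phenotype_id] = float(value)
    return cohort


# ---------------------------------------------------------------------------
# File emission (three data TSVs + sample manifest + minimal VCF)
# ---------------------------------------------------------------------------

def write_cohort_files(cohort: Cohort, outdir) -> dict[str, str]:
    """Write samples/genotypes/phenotypes/cnv TSVs and a minimal GT-only VCF."""
    import os

    import pandas as pd

    from .cohort import write_genotype_table

    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, f"{name}") for name in (
        "samples.tsv", "genotypes.tsv", "phenotypes.tsv", "cnv.tsv", "cohort.vcf")}

    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "status": s.status.value if s.status else "",
                "stage": "" if s.stage is None else s.stage,
            }
            for s in cohort.samples
        ]
    ).to_csv(paths["samples.tsv"], sep="\t", index=False)

    write_genotype_table(cohort, paths["genotypes.tsv"])

    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "phenotype_id": pid,
                "value": val,
                "units": cohort.phenotype_units.get(pid, ""),
            }
            for s in cohort.samples
            for pid, val in s.phenotypes.items()
        ],
        columns=["sample_id", "phenotype_id", "value", "units"],
    ).to_csv(paths["phenotypes.tsv"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "gene_id": g, "copy_number": cn}
            for s in cohort.samples
            for g, cn in s.copy_numbers.items()
        ],
        columns=["sample_id", "gene_id", "copy_number"],
    ).to_csv(paths["cnv.tsv"], sep="\t", index=False)

    write_vcf(cohort, paths["cohort.vcf"])
    return paths


def write_vcf(cohort: Cohort, path) -> None:
    """Emit a minimal VCF v4.2 (GT field only, one record per biallelic SNP)."""
    sample_ids = [s.sample_id for s in cohort.samples]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for snp in sorted(cohort.snp_defs.values(), key=lambda d: (d.chrom, d.pos, d.snp_id)):
        calls = []
        for s in cohort.samples:
            gt = s.genotypes.get(snp.snp_id)
            if gt is None:
                calls.append("./.")
            else:
                k = gt.count_allele(snp.alt_allele)
                calls.append(("0/0", "0/1", "1/1")[k])
        lines.append(
            f"{snp.chrom}\t{max(snp.pos, 1)}\t{snp.snp_id}\t{snp.ref_allele}\t"
            f"{snp.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
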