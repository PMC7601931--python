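"""Cohort data model: samples, SNP definitions, genotype containers, file IO and QC.

A cohort bundles case/control samples with their biallelic SNP genotypes,
gene copy-number calls, quantitative phenotypes (flow-cytometry MFI,
percent-positive cells, plasma analytes, immunoglobulin levels) and an
optional ordinal clinical stage.  Everything downstream — Hardy-Weinberg
statistics, association tables, genotype-phenotype contrasts — consumes
these containers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: sentinel strings accepted as a missing genotype in the tab-separated format
MISSING_GENOTYPE_CODES = frozenset({"NA", "./.", ".", "NN"})


class CohortError(ValueError):
    """Raised for malformed cohort inputs or invalid cohort operations."""


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of single-character alleles.

    Alleles are stored sorted so that equality and hashing ignore input
    order ("GA" and "AG" are the same heterozygote).  Display order is a
    presentation concern handled by :meth:`display` given a SNP definition
    (reference/major allele printed first).
    """

    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        a, b = self.allele1.upper(), self.allele2.upper()
        for al in (a, b):
            if al not in VALID_BASES:
                raise CohortError(f"invalid allele {al!r}")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    def is_het(self) -> bool:
        return self.allele1 != self.allele2

    def count_allele(self, allele: str) -> int:
        return (self.allele1 == allele) + (self.allele2 == allele)

    def display(self, snp: "SnpDef") -> str:
        """Genotype string with the reference allele first, e.g. 'GA'."""
        if self.is_het():
            return snp.ref_allele + self.other_allele(snp.ref_allele)
        return self.allele1 + self.allele2

    def other_allele(self, allele: str) -> str:
        if self.allele1 == allele:
            return self.allele2
        return self.allele1


@dataclass(frozen=True)
class SnpDef:
    """Definition of a biallelic SNP: identity, gene and allele orientation.

    ``minor_allele`` fixes the orientation used by genotype tallies and all
    association statistics: the "alt" homozygote class is the homozygote of
    the minor allele (the convention used when a variant is written G>A by
    allele frequency).  Defaults to ``alt_allele``.
    """

    snp_id: str
    gene: str
    ref_allele: str
    alt_allele: str
    minor_allele: str = ""
    chrom: str = "17"
    pos: int = 0

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise CohortError(f"{self.snp_id}: alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise CohortError(f"{self.snp_id}: ref and alt alleles identical")
        if not self.minor_allele:
            object.__setattr__(self, "minor_allele", self.alt_allele)
        if self.minor_allele not in (self.ref_allele, self.alt_allele):
            raise CohortError(
                f"{self.snp_id}: minor allele {self.minor_allele!r} not in "
                f"{{{self.ref_allele}, {self.alt_allele}}}"
            )

    @property
    def major_allele(self) -> str:
        return self.alt_allele if self.minor_allele == self.ref_allele else self.ref_allele

    def validate_genotype(self, gt: Genotype) -> Genotype:
        declared = {self.ref_allele, self.alt_allele}
        if not set(gt.alleles) <= declared:
            raise CohortError(
                f"{self.snp_id}: allele(s) {gt.alleles} outside declared {sorted(declared)}"
            )
        return gt


@dataclass(frozen=True)
class GenotypeCounts:
    """Three-class genotype tally oriented to a SNP's minor allele.

    ``n_alt_hom`` counts homozygotes of the minor ("alt") allele — the
    genotype class whose frequency enters the Hardy-Weinberg departure
    coefficient.  ``n_ref_hom`` counts major-allele homozygotes.
    """

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise CohortError("genotype counts must be non-negative")
        if self.n == 0:
            raise CohortError("empty tally")

    @property
    def n(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def n_alleles(self) -> int:
        return 2 * self.n

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_alt_hom + self.n_het

    @property
    def alt_freq(self) -> float:
        return self.n_alt_alleles / self.n_alleles

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_ref_hom, self.n_het, self.n_alt_hom)


@dataclass
class Sample:
    sample_id: str
    status: Status | None = None
    genotypes: dict[str, Genotype | None] = field(default_factory=dict)
    copy_numbers: dict[str, int] = field(default_factory=dict)
    phenotypes: dict[str, float] = field(default_factory=dict)
    stage: int | None = None

    def __post_init__(self) -> None:
        if self.stage is not None and self.stage not in range(5):
            raise CohortError(f"{self.sample_id}: stage {self.stage} outside 0..4")


@dataclass
class Cohort:
    """A collection of samples plus the SNP definitions their genotypes reference."""

    samples: list[Sample] = field(default_factory=list)
    snp_defs: dict[str, SnpDef] = field(default_factory=dict)
    #: phenotype_id -> unit string ("MFI", "%", "g/L", "ng/mL", ...)
    phenotype_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise CohortError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def sample_map(self) -> dict[str, Sample]:
        return {s.sample_id: s for s in self.samples}

    def by_status(self, status: Status) -> list[Sample]:
        return [s for s in self.samples if s.status == status]

    def n_case(self) -> int:
        return len(self.by_status(Status.CASE))

    def n_control(self) -> int:
        return len(self.by_status(Status.CONTROL))


# ---------------------------------------------------------------------------
# Readers / writers.  All tabular formats are tab-separated with a header;
# outputs are CSV with a fixed, documented column order.
# ---------------------------------------------------------------------------

def parse_genotype_string(raw: str, snp: SnpDef) -> Genotype | None:
    """Parse a genotype string like 'GA'; missing codes map to None."""
    raw = raw.strip()
    if raw in MISSING_GENOTYPE_CODES:
        return None
    if len(raw) != 2:
        raise CohortError(f"{snp.snp_id}: cannot parse genotype {raw!r}")
    return snp.validate_genotype(Genotype(raw[0], raw[1]))


def read_genotype_table(path, snp_defs: list[SnpDef] | dict[str, SnpDef]) -> Cohort:
    """Read a long-format genotype TSV (sample_id, snp_id, genotype).

    Genotype strings are canonicalised as unordered allele pairs; missing
    entries ("NA" or "./.") are recorded as missing without dropping the
    sample.  Unknown SNP ids and alleles outside a SNP's declared pair are
    hard errors naming the offending row.
    """
    defs = snp_defs if isinstance(snp_defs, dict) else {d.snp_id: d for d in snp_defs}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "snp_id", "genotype"]
    if list(df.columns[:3]) != required:
        raise CohortError(f"genotype table must start with columns {required}, got {list(df.columns)}")
    samples: dict[str, Sample] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        snp = defs.get(row.snp_id)
        if snp is None:
            raise CohortError(f"{path}, line {i}: unknown snp_id {row.snp_id!r}")
        try:
            gt = parse_genotype_string(row.genotype, snp)
        except CohortError as exc:
            raise CohortError(f"{path}, line {i}: {exc}") from exc
        sample = samples.setdefault(row.sample_id, Sample(sample_id=row.sample_id))
        sample.genotypes[snp.snp_id] = gt
    return Cohort(samples=list(samples.values()), snp_defs=dict(defs))


def write_genotype_table(cohort: Cohort, path) -> None:
    rows = []
    for s in cohort.samples:
        for snp_id, gt in s.genotypes.items():
            snp = cohort.snp_defs[snp_id]
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "snp_id": snp_id,
                    "genotype": "NA" if gt is None else gt.display(snp),
                }
            )
    pd.DataFrame(rows, columns=["sample_id", "snp_id", "genotype"]).to_csv(
        path, sep="\t", index=False
    )


def read_vcf_subset(path) -> Cohort:
    """Read genotypes from a biallelic-SNP VCF via cyvcf2.

    Only the GT field is consumed.  Phased and unphased separators are
    equivalent; ``./.`` maps to missing.  Multi-allelic records are skipped
    with a warning; a record without GT is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    samples = {sid: Sample(sample_id=sid) for sid in sample_ids}
    snp_defs: dict[str, SnpDef] = {}
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            logger.warning(
                "skipping non-biallelic-SNP record %s at %s:%d",
                variant.ID, variant.CHROM, variant.POS,
            )
            continue
        if "GT" not in dict(variant.FORMAT or {}) and variant.gt_types is None:
            raise CohortError(f"record {variant.ID}: no GT field")
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp = SnpDef(
            snp_id=snp_id,
            gene=str(variant.INFO.get("GENE", "")) if variant.INFO.get("GENE") else "",
            ref_allele=variant.REF,
            alt_allele=variant.ALT[0],
            chrom=variant.CHROM,
            pos=variant.POS,
        )
        snp_defs[snp_id] = snp
        gt_types = variant.gt_types  # gts012: 0=ref-hom, 1=het, 2=alt-hom, 3=missing
        for sid, code in zip(sample_ids, gt_types):
            if code == 3:
                samples[sid].genotypes[snp_id] = None
            elif code == 0:
                samples[sid].genotypes[snp_id] = Genotype(snp.ref_allele, snp.ref_allele)
            elif code == 1:
                samples[sid].genotypes[snp_id] = Genotype(snp.ref_allele, snp.alt_allele)
            else:
                samples[sid].genotypes[snp_id] = Genotype(snp.alt_allele, snp.alt_allele)
    return Cohort(samples=list(samples.values()), snp_defs=snp_defs)


def read_samples_table(path) -> pd.DataFrame:
    """Read the sample manifest TSV (sample_id, status, stage)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "status" not in df.columns:
        raise CohortError("samples table needs sample_id and status columns")
    return df


def read_phenotype_table(path) -> pd.DataFrame:
    """Read the phenotype TSV (sample_id, phenotype_id, value, units)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "phenotype_id": str})
    required = {"sample_id", "phenotype_id", "value", "units"}
    if not required <= set(df.columns):
        raise CohortError(f"phenotype table needs columns {sorted(required)}")
    pct = df["units"] == "%"
    bad = df.loc[pct & ~df["value"].between(0, 100)]
    if len(bad):
        raise CohortError(f"percentage phenotype outside [0,100]: {bad.iloc[0].to_dict()}")
    return df


def read_cnv_table(path) -> pd.DataFrame:
    """Read the copy-number TSV (sample_id, gene_id, copy_number)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    required = {"sample_id", "gene_id", "copy_number"}
    if not required <= set(df.columns):
        raise CohortError(f"CNV table needs columns {sorted(required)}")
    if (df["copy_number"] < 0).any():
        raise CohortError("negative copy number")
    return df


def attach_tables(
    cohort: Cohort,
    samples_df: pd.DataFrame | None = None,
    phenotypes_df: pd.DataFrame | None = None,
    cnv_df: pd.DataFrame | None = None,
) -> Cohort:
    """Merge manifest / phenotype / CNV tables into an existing cohort in place."""
    smap = cohort.sample_map()
    if samples_df is not None:
        for row in samples_df.itertuples(index=False):
            s = smap.get(row.sample_id)
            if s is None:
                continue
            s.status = Status(row.status)
            stage = getattr(row, "stage", None)
            if stage is not None and not pd.isna(stage):
                s.stage = int(stage)
                if s.stage not in range(5):
                    raise CohortError(f"{s.sample_id}: stage {s.stage} outside 0..4")
    if phenotypes_df is not None:
        for row in phenotypes_df.itertuples(index=False):
            s = smap.get(row.sample_id)
            if s is None:
                continue
            s.phenotypes[row.phenotype_id] = float(row.value)
            cohort.phenotype_units[row.phenotype_id] = row.units
    if cnv_df is not None:
        for row in cnv_df.itertuples(index=False):
            s = smap.get(row.sample_id)
            if s is None:
                continue
            s.copy_numbers[row.gene_id] = int(row.copy_number)
    return cohort


# ---------------------------------------------------------------------------
# QC and tallies
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    removed_sample_ids: list[str]
    #: gene_id -> fraction of input samples with copy number below threshold
    single_copy_fraction: dict[str, float]
    n_input: int
    n_retained: int


def apply_cnv_exclusion(
    cohort: Cohort, genes: list[str], threshold: int = 2
) -> tuple[Cohort, ExclusionReport]:
    """Drop every sample with a copy number below ``threshold`` for ANY listed gene.

    Genes in a frequently deleted region (e.g. 17p in CLL) can lose one copy
    somatically, which would distort germline genotype frequencies, so such
    samples are removed from all downstream analyses.  A sample missing a
    copy-number call for a listed gene is retained with a logged warning:
    absence of the assay is a data defect, not evidence of deletion.
    """
    removed: list[str] = []
    below: dict[str, int] = {g: 0 for g in genes}
    kept: list[Sample] = []
    for s in cohort.samples:
        drop = False
        for g in genes:
            cn = s.copy_numbers.get(g)
            if cn is None:
                logger.warning("sample %s: no copy-number call for %s; retained", s.sample_id, g)
                continue
            if cn < threshold:
                below[g] += 1
                drop = True
        if drop:
            removed.append(s.sample_id)
        else:
            kept.append(s)
    n_in = len(cohort.samples)
    report = ExclusionReport(
        removed_sample_ids=removed,
        single_copy_fraction={g: (below[g] / n_in if n_in else 0.0) for g in genes},
        n_input=n_in,
        n_retained=len(kept),
    )
    return replace(cohort, samples=kept), report


def tally_genotypes(cohort: Cohort, snp: SnpDef | str, status: Status) -> GenotypeCounts:
    """Tally ref-hom / het / alt-hom genotypes for one arm at one SNP.

    Orientation follows the SNP's minor allele ("alt" = minor-allele
    homozygote).  Samples missing a genotype at this SNP are excluded from
    this tally only.
    """
    if isinstance(snp, str):
        snp = cohort.snp_defs[snp]
    minor = snp.minor_allele
    n_ref = n_het = n_alt = 0
    for s in cohort.by_status(status):
        gt = s.genotypes.get(snp.snp_id)
        if gt is None:
            continue
        k = gt.count_allele(minor)
        if k == 0:
            n_ref += 1
        elif k == 1:
            n_het += 1
        else:
            n_alt += 1
    if n_ref + n_het + n_alt == 0:
        raise CohortError(f"empty tally for {snp.snp_id} / {status.value}")
    return GenotypeCounts(n_ref, n_het, n_alt)


def count_missing(cohort: Cohort, snp_id: str, status: Status) -> int:
    return sum(1 for s in cohort.by_status(status) if s.genotypes.get(snp_id) is None)


def expand_counts(
    snp: SnpDef,
    counts: GenotypeCounts,
    status: Status,
    prefix: str = "S",
) -> list[Sample]:
    """Expand a genotype tally into explicit per-sample records.

    Lets a published count table be fed through the same pipeline as raw
    per-sample data: each tallied genotype becomes one synthetic sample
    carrying only that genotype.
    """
    minor, major = snp.minor_allele, snp.major_allele
    gts = (
        [Genotype(major, major)] * counts.n_ref_hom
        + [Genotype(major, minor)] * counts.n_het
        + [Genotype(minor, minor)] * counts.n_alt_hom
    )
    return [
        Sample(
            sample_id=f"{prefix}{status.value}{i:05d}",
            status=status,
            genotypes={snp.snp_id: gt},
        )
        for i, gt in enumerate(gts)
    ]


def cohort_from_counts(
    snp: SnpDef, case_counts: GenotypeCounts, control_counts: GenotypeCounts
) -> Cohort:
    """Build a two-arm cohort from published case and control genotype tallies."""
    samples = expand_counts(snp, case_counts, Status.CASE, prefix="C") + expand_counts(
        snp, control_counts, Status.CONTROL, prefix="H"
    )
    return Cohort(samples=samples, snp_defs={snp.snp_id: snp})
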