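"""Bundled example data: genotype tallies from a published CLL case-control study.

Two variants of the APRIL/TACI (TNFSF13/TNFRSF13B) axis, genotyped in 439
chronic lymphocytic leukaemia patients and 477 healthy controls after
copy-number QC.  Count tables like these are the natural unit of published
association results; :func:`cllassoc.cohort.cohort_from_counts` expands
them into per-sample cohorts so they can be pushed through the same
pipeline as raw data.
"""

from __future__ import annotations

from .cohort import Cohort, GenotypeCounts, SnpDef, cohort_from_counts

RS3803800 = SnpDef(
    snp_id="rs3803800", gene="TNFSF13",
    ref_allele="G", alt_allele="A", minor_allele="A",
    chrom="17", pos=7560838,
)
#: CLL arm (GG, GA, AA) and control arm genotype tallies at rs3803800
RS3803800_CASE = GenotypeCounts(n_ref_hom=261, n_het=142, n_alt_hom=36)
RS3803800_CTRL = GenotypeCounts(n_ref_hom=279, n_het=179, n_alt_hom=19)

RS4985726 = SnpDef(
    snp_id="rs4985726", gene="TNFRSF13B",
    ref_allele="C", alt_allele="G", minor_allele="G",
    chrom="17", pos=16852187,
)
#: CLL arm (CC, CG, GG) and control arm genotype tallies at rs4985726
RS4985726_CASE = GenotypeCounts(n_ref_hom=353, n_het=78, n_alt_hom=8)
RS4985726_CTRL = GenotypeCounts(n_ref_hom=353, n_het=117, n_alt_hom=7)


def cll_example_cohort() -> Cohort:
    """Two-SNP CLL case-control cohort expanded from the published tallies."""
    c1 = cohort_from_counts(RS3803800, RS3803800_CASE, RS3803800_CTRL)
    c2 = cohort_from_counts(RS4985726, RS4985726_CASE, RS4985726_CTRL)
    # merge: arms are the same individuals; pair sample records positionally
    for s1, s2 in zip(c1.samples, c2.samples):
        s1.genotypes.update(s2.genotypes)
    c1.snp_defs.update(c2.snp_defs)
    return c1
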