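# Synthetic cohort: one SNP with a recessive risk effect, one MFI-like
# phenotype conditional on genotype with a mild stage trend, and 5% of
# samples carrying a single-copy deletion of the genotyped gene.
n_case: 300
n_ctrl: 300
seed: 11
snps:
  - snp_id: rs1
    gene: GENE1
    ref: G
    alt: A
    q: 0.25            # minor-allele frequency in controls
    f_ctrl: 0.0        # controls at Hardy-Weinberg equilibrium
    odds_ratios: [1.0, 1.0, 2.0]   # (ref-hom, het, alt-hom) disease odds
phenotypes:
  - phenotype_id: mfi
    snp: rs1
    family: normal
    loc_by_genotype: [35, 43, 42]
    scale: 6
    units: MFI
    stage_slope: 1.5
single_copy_fraction:
  GENE1: 0.05
stage_probs: [0.3, 0.3, 0.2, 0.1, 0.1]
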