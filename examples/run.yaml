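# Full pipeline on the cohort produced by `cllassoc simulate --spec sim.yaml --out data/`.
inputs:
  samples: ../data/samples.tsv
  genotypes: ../data/genotypes.tsv
  phenotypes: ../data/phenotypes.tsv
  cnv: ../data/cnv.tsv
snps:
  - snp_id: rs1
    gene: GENE1
    ref: G
    alt: A
cnv_exclusion:
  genes: [GENE1]
  threshold: 2
quant:
  - phenotype: mfi
    group_by: genotype
    snp: rs1
    contrast: [-1, 0, 1]   # linear in minor-allele count
    bootstrap: true
  - phenotype: mfi
    group_by: stage
seed: 5
bootstrap_B: 1000
output_dir: ../out
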