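# Demo pipeline configuration: a small two-trait study with 15 planted
# pleiotropic (shared) eGenes.  All thresholds carry the analysis defaults:
# FDR alpha 0.05, cis window 1 Mb, coloc window 200 kb, bootstrap n 10,000,
# coloc priors p1 = p2 = 1e-4, p12 = 5e-5.
seed: 1
outdir: speqtl_demo_run
simulate:
  n_chroms: 2
  chrom_length: 1200000
  enzyme_motif: GATC
  cut_offset: 0
  n_genes: 60
  n_snps_per_trait: 80
  n_identical_snps: 12
  n_tissues: 3
  samples_per_tissue: 200
  n_planted_cis: 34
  n_planted_trans: 6
  afc_effect: 1.0
  noise_sd: 0.2
  maf_range: [0.1, 0.45]
  ld_block_size: 5
  contact_background_rate: 0.01
  n_shared_egenes: 15
  n_coloc_loci_per_flag: 2
  coloc_n_snps: 50
  coloc_gwas_n: 50000
digest:
  enzyme_motif: GATC
  cut_offset: 0
pairs:
  gene_anchor: tss
eqtl:
  alpha: 0.05
  min_samples: 10
  fdr_scope: global
overlap:
  n_boot: 10000
  exclude_genes: []
coloc:
  window: 200000
  p1: 1.0e-4
  p2: 1.0e-4
  p12: 5.0e-5
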