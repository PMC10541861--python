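# Genome-census fixture: 18 planted ZAM-style insertions across five
# simulated chromosome arms — 7 full-length (one shared with the reference
# annotation), 1 v1 (deleted 5'-UTR), 2 v3 (303-bp 5'-UTR deletion),
# 4 v2 (pol-end deletion 5494-6120), 4 with other internal deletions.
genome:
  chrom_length: 400000
  chroms: [chr2L, chr2R, chr3L, chr3R, chrX]
insertions:
  - {variant: fl, chrom: chrX, position: 60000, shared: true}
  - {variant: fl, chrom: chrX, position: 140000}
  - {variant: v2, chrom: chrX, position: 220000}
  - {variant: v1, chrom: chrX, position: 300000}
  - {variant: fl, chrom: chr2L, position: 60000}
  - {variant: v2, chrom: chr2L, position: 180000}
  - {variant: v3, chrom: chr2L, position: 300000}
  - {variant: fl, chrom: chr2R, position: 60000}
  - {variant: v2, chrom: chr2R, position: 180000}
  - {variant: other, chrom: chr2R, position: 300000, deletion: [2100, 3250]}
  - {variant: fl, chrom: chr3L, position: 60000}
  - {variant: other, chrom: chr3L, position: 140000, deletion: [3400, 4650]}
  - {variant: v3, chrom: chr3L, position: 220000}
  - {variant: v2, chrom: chr3L, position: 300000}
  - {variant: fl, chrom: chr3R, position: 60000}
  - {variant: other, chrom: chr3R, position: 180000, deletion: [2600, 4750]}
  - {variant: other, chrom: chr3R, position: 300000, deletion: [4000, 5150]}
  - {variant: fl, chrom: chr3R, position: 380000}
long_reads:
  depth: 25
  length_mean: 12000
  length_sd: 6000
  subst_rate: 0.02
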