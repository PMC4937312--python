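seed: 0
scaffold_id: scaffold_51S
scaffold_length: 20000
gene_offset: 10000
gene_id: NDtarget
exon_lengths:
- 560
- 175
- 175
- 145
- 145
- 175
intron_lengths:
- 25
- 25
- 25
- 25
- 25
coding_strand: +
antisense_intron:
- 640
- 665
transgene_id: pTI_dd
deletions:
- - 173
  - 529
- - 1340
  - 1500
replacements: []
linearization_offset: 120
region_prefix: ND
secondary_names:
- ND-1
- ND-2
secondary_fractions:
  ND-1: 0.05
  ND-2: 0.01
n_primary: 10000
n_junction: 1500
n_intron: 1500
n_background: 150000
n_structural: 10000
n_feeding: 15000
length_probs:
  17: 0.01
  18: 0.01
  19: 0.02
  20: 0.03
  21: 0.05
  22: 0.08
  23: 0.7
  24: 0.06
  25: 0.04
antisense_body: 0.9
antisense_5p: 0.25
antisense_secondary: 0.95
antisense_junction: 0.95
antisense_intron_reads: 0.5
n_long_reads: 20000
long_read_length: 100
intron_retention: 0.1
long_antisense_fraction: 0.15
antisense_intron_splice_prob: 0.8
structural_length: 2000
feeding_gene_length: 1200
at_fraction: 0.72
ct_bio_sd: 0.02
ct_tech_sd: 0.02
samples:
- sample_id: control_ICL7a
  role: control
  knockdown_gene: ICL7a
  multipliers: {}
- sample_id: RDR2_KD
  role: knockdown
  knockdown_gene: RDR2
  multipliers:
    primary_antisense: 0.2
    primary_sense: 0.5
    junction_antisense: 0.2
    junction_sense: 0.5
    intron_antisense: 0.2
    intron_sense: 0.5
    secondary_antisense: 0.3
    secondary_sense: 0.5
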