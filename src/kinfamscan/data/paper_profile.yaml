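# The benchmark ("paper profile") generator configuration: a diploid
# cotton-like dataset with 78 planted kinase-family genes in a 12 ZIK /
# 22 MEKK / 44 Raf split, 13 chromosomes, 12 duplication pairs, three
# tissue read sets (mature leaf, 0-DPA ovule, 3-DPA ovule) and exactly
# 60 of the 78 genes expressed.
n_zik: 12
n_mekk: 22
n_raf: 44
n_decoys: 200
near_miss_fraction: 0.25
n_unexpressed: 18
n_chromosomes: 13
read_length: 50
reads_per_sample: 30000
exon_count_range: [1, 23]
intron_length_range: [50, 300]
spacer_range: [3000, 8000]
duplication_pairs: 12
tandem_pairs: 2
mutation_rate: 0.25
duplication_divergence: 0.06
expression:
  raf_higher_0dpa: 11
  raf_higher_3dpa: 8
  rpkm_range: [5.0, 500.0]
  preference_ratio: 4.0
  tissue_dropout: 0.15
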