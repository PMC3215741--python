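# Desk-scale demo study: 8 tumor/normal pairs on a 2 x 5 Mb genome with a
# shared 60 kb CN=4 amplification in half the cohort.
genome:
  chromosomes:
    - {name: "1", length: 5000000}
    - {name: "2", length: 5000000}
  spacing: 1000
  snp_fraction: 0.5

noise:
  lrr_sd: 0.2
  baf_sd: 0.03
  het_fraction: 0.3

cohort:
  n_samples: 8
  carrier_fraction: 0.75
  private_lesions_per_sample: 3
  shared_lesion: {chrom: "1", start: 2000000, end: 2060000, cn: 4, loh: false}

segmentation:
  min_markers: 10
  split_alpha: 0.001
  merge_alpha: 0.001
  max_gap: 100000

mar:
  min_fraction: 0.5

mode: paired
seed: 11
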