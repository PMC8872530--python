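# Demonstration configuration: a small fully synthetic end-to-end run.
# Every stochastic stage carries its own seed; identical configs yield
# byte-identical headline reports.
stages: [kinship, sexing, mito]
panel:
  seed: 101
  n_sites: 60000
  freq_min: 0.05
  freq_max: 0.95
kinship:
  seed: 102
  relationship: same_individual
  n_covered_a: 3000
  n_covered_b: 6500
  overlap_correlation: 0.5
  error_rate: 0.01
  error_grid: [0.0, 0.005, 0.01, 0.02]
  n_replicates: 1000
sexing:
  seed: 103
  total_reads: 100000
mito:
  seed: 104
  reference_seed: 105
  reference_length: 16569
  haplotype: ["263G", "315.1C", "524.1A", "524.2C", "750G", "1438G", "3010A",
              "4137T", "4769G", "8860G", "15326G", "16111T", "16357C", "16519C"]
  depth_target: 40
  mean_length: 65
  deamination_rate: 0.0
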