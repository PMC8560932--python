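{
  "cysteine": {
    "Glu-D1x": {
      "gains": 0,
      "losses": 1
    },
    "Glu-D1y": {
      "gains": 0,
      "losses": 0
    }
  },
  "duplicate_groups": [
    [
      "L1_S000",
      "L1_S000_dup"
    ]
  ],
  "effects": {
    "Glu-D1x": {
      "coding": 24,
      "non_coding": 0,
      "nonsynonymous": 18,
      "synonymous": 6
    },
    "Glu-D1y": {
      "coding": 24,
      "non_coding": 0,
      "nonsynonymous": 20,
      "synonymous": 4
    }
  },
  "kmer": {
    "gene_call": "L3",
    "margin": 10.0,
    "n_assigned_bins": 5
  },
  "mantel": {
    "n_perm": 999,
    "p": 0.001,
    "r": 0.22835568503383613
  },
  "n_added_by_flanks": 0,
  "n_ambiguous_combined": 0,
  "n_combined_haplotypes": 11,
  "n_recombinants": 2,
  "n_samples": 47,
  "n_sites_filtered": 80,
  "n_sites_raw": 80,
  "n_x_haplotypes": 9,
  "n_y_haplotypes": 9,
  "recombinants": [
    "L2_S019",
    "L3_S005"
  ],
  "seed": 11
}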