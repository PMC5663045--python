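# Example cohort configuration for `gliomapairs simulate`.
# Fields mirror gliomapairs.simulate.CohortConfig; omitted fields keep
# their defaults (16 pairs, 7/7/2 group split, 69x coverage, one
# hypermutator pair with a 10x multiplier).
n_pairs: 6
group_spec:
  "H3/IDH1 mutant": 0.5
  "H3/IDH1 wildtype": 0.3333333333333333
  "NF1 germline": 0.16666666666666666
n_shared_passengers: 6
n_primary_private: 2
n_recurrence_private: 4
hypermutator_pairs:
  4: 10
mean_depth: 69
tumor_purity: 0.8
n_baf_sites: 1500
n_probes: 4000
seed: 7
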