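# Default thresholds for the FBP1 genotype-phenotype pipeline, v1.
# Each value traces either to the published exome-filter criteria / panel
# tables or to a calibration documented in docs/methods.md.

filter:
  min_depth: 8            # adopted candidate criterion: depth >= 8
  min_alt_reads: 4        # variant-supporting reads >= 4
  het_vaf_window: [0.4, 0.6]   # germline heterozygous VAF band
  hom_vaf_min: 0.95       # "VAF of 1" relaxed for finite read counts
  max_known_freq: 0.001   # exclude database variants with AF > 0.001
  apply_vaf_to_parents: true
  exclude_unidirectional: true
  exclude_indel_in_repeat: true
  exclude_synonymous: true
  exclude_known: true

hydropathy:
  theta: 3.0              # |delta hydropathy| counted as a change; smallest
                          # round value that admits G294V (4.6) and excludes
                          # V325A (2.4)

structure:
  pocket_radius: 16.0     # A; substrate-pocket proximity cutoff, calibrated on
                          # the 15-mutation panel (misfolding class <= 14.1 A,
                          # distant class >= 21.6 A)
  numbering_offset: 0

phenotype:
  expression_decreased_below: 0.7   # panel gap: 0.6 (decreased) vs 0.9 (kept)
  aggregated_pct_min: 40.0          # panel gap: 42.7 vs 33.6
  hsp_elevated_min: 3.0             # both chaperone ratios >= 3.0
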