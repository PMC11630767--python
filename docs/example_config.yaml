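# Example pipeline configuration for `rilqtl run-all --config ... --out runs/demo`.
# Omitted keys keep their defaults (1000 permutations, 10 permuted datasets,
# q = 0.05, 0.5 Mb bins, 1.5 drop, 3-sigma boundaries, Bonferroni 0.05).
seed: 1
panel:
  n_lines: 70
  n_markers: 500
architecture:
  n_spots: 2000
  cis_fraction: 0.10
  trans_hotspots:
    - [120, 50, [0.6, 0.1]]   # marker index, n target genes, [effect mean, sd]
  noise_sd: 0.3
il:
  interaction_spots: 25
eqtl:
  fdr_variant: plain          # or "paper" for the (m0/m)*q*ln(m) bound
  p_cut: 0.001                # trans-band flagging; 0.0001 for the stricter call
stages:
  power: false                # the power grid is the one slow stage
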