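# Complete default configuration for the regulon-screen pipeline.
# Each threshold is annotated with its provenance:
#   [published]  stated by the study design this pipeline reproduces
#   [package]    a quantification chosen by this package (configurable)
seed: 0
known_targets: []      # confirmed direct targets of the regulator
regulator_id: soxR
thresholds:
  tau_fc: 4.0          # [published] screen: fold change >= 4 (WT vs regulator-null)
  tau_q: 0.5           # [published] screen: q-value <= 0.5
  tau_act: 1.0         # [package]   elimination: time-course fold change <= 1
  tau_val: 4.0         # [published] qPCR validation: >= 4-fold
  tau_strong: 11.0     # [published] strong production dependence: >= 11-fold
  tau_comp: 4.0        # [package]   complementation restored: both folds >= 4
  efficiency: 2.0      # [package]   qPCR amplification efficiency (perfect doubling)
  theta_sense: 0.5     # [package]   antisense-dominant below this sense fraction
  theta_skew: 5.0      # [package]   read-through: 5'/3' half-depth ratio >= 5
  d_max: 500           # [package]   read-through: upstream neighbor within 500 bp
  floor: 1.0           # [package]   read-through: 3'-half mean depth <= 1
  min_len: 501         # [published] ORF scan: length > 500 bp (stop codon included)
  window: 1000         # [published] motif scan: 1 kb upstream window
  theta: 10.0          # [published] motif scan: log-odds > 10 (bits; base is [package])
screen:
  fixture: null        # published-table fixture TSV, or use counts_a/design_a etc.
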