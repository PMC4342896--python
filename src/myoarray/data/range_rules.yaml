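# Published interval rules: a disease is called when the bF1-ATPase/LDH-A
# ratio AND one additional marker both fall inside closed intervals
# (fold-of-control units). `reported_sensitivity` is the published value
# (TP / (TP + FP), percent) on the original biopsies, kept for reference.
rules:
  DMD:
    ratio_interval: [2.9, 4.1]
    extra_marker: PYGM
    extra_interval: [0.1, 0.3]
    reported_sensitivity: 100.0
  BMD:
    ratio_interval: [1.9, 3.5]
    extra_marker: GAPDH
    extra_interval: [0.6, 1.2]
    reported_sensitivity: 86.0
  NCL:
    ratio_interval: [1.5, 2.1]
    extra_marker: GPD1
    extra_interval: [0.4, 0.6]
    reported_sensitivity: 100.0
  LGMD2C:
    ratio_interval: [2.5, 3.9]
    extra_marker: SDH
    extra_interval: [0.5, 0.7]
    reported_sensitivity: 100.0
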