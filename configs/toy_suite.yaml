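# Pipeline configuration for the synthetic fixture suite: a class I and a
# class II toy complex, every analysis enabled.
structures:
  - id: toy-class-I
    synthetic: {kind: toy_pmhc, class_type: I}
  - id: toy-class-II
    synthetic: {kind: toy_pmhc, class_type: II, peptide_overhang: 2}
thresholds:
  sasa_points: 240
seed: 0
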