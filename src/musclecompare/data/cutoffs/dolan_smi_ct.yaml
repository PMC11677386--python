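# CT skeletal muscle index (L3-SMA / height^2) atrophy cut-offs,
# stratified by sex and BMI. Values strictly below a threshold are abnormal.
name: dolan_smi_ct
biomarker: smi_ct
citation: "Dolan et al., BMI-specific SMI cut-offs for CT-defined low muscle mass"
rules:
  - {sex: 1, bmi_max: 25.0, threshold: 45.0}
  - {sex: 1, bmi_min: 25.0, threshold: 53.0}
  - {sex: 0, bmi_max: 25.0, threshold: 39.0}
  - {sex: 0, bmi_min: 25.0, threshold: 41.0}
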