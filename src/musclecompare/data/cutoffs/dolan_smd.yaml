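# L3 skeletal muscle radiodensity (HU) myosteatosis cut-offs, BMI-stratified,
# identical in both sexes.
name: dolan_smd
biomarker: l3_smd
citation: "Dolan et al., BMI-specific radiodensity cut-offs for myosteatosis"
rules:
  - {bmi_max: 25.0, threshold: 34.0}
  - {bmi_min: 25.0, threshold: 32.0}
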