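# Ultrasound rectus femoris cross-sectional area (cm^2) cut-offs (DRECO).
name: dreco_rf_csa
biomarker: rf_csa
citation: "DRECO study (de Luis et al.), ultrasound RF-CSA cut-offs"
rules:
  - {sex: 1, threshold: 3.48}
  - {sex: 0, threshold: 2.4}
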