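# Ultrasound rectus femoris muscle thickness (mm) "confirmed sarcopenia"
# cut-offs from the DRECO study. Note the male threshold is printed below the
# female one in the source; shipped as printed.
name: dreco_rf_mt
biomarker: rf_mt
citation: "DRECO study (de Luis et al.), ultrasound RF-MT cut-offs"
rules:
  - {sex: 1, threshold: 9.66}
  - {sex: 0, threshold: 10.4}
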