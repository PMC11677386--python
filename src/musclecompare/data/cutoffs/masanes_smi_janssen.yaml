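# BIA skeletal muscle index (Janssen MM / height^2) cut-offs from a Spanish
# reference population.
name: masanes_smi_janssen
biomarker: smi_janssen
citation: "Masanes et al., Spanish BIA SMI reference cut-offs"
rules:
  - {sex: 1, threshold: 8.31}
  - {sex: 0, threshold: 6.68}
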