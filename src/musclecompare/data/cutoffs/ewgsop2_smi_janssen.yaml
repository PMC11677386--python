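# European consensus BIA skeletal muscle index cut-offs.
name: ewgsop2_smi_janssen
biomarker: smi_janssen
citation: "EWGSOP2 / GLIM European SMI cut-offs"
rules:
  - {sex: 1, threshold: 7.00}
  - {sex: 0, threshold: 5.50}
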