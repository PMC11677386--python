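# EDITABLE TEMPLATE — not populated. The Van Vugt age/sex/BMI-conditional
# cut-off table is published externally; fill in the rules below from that
# source before use. With no rules, every classification attempt raises an
# UnclassifiableError rather than silently defaulting.
name: vanvugt_template
biomarker: smi_ct
citation: "Van Vugt et al. (external table; user-supplied values required)"
rules: []
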