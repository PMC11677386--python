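# SYNTHETIC age/sex 10th-percentile handgrip strength table (kg).
# The published normative centile curves are not redistributable here, so this
# default ships plausible synthetic values with the same shape (declining with
# age, higher in males). Replace with the published table for clinical use via
# load_grip_table(path). Age bands are half-open [age_min, age_max).
name: synthetic_grip_p10
bands:
  1:  # male
    - {age_min: 50, age_max: 55, p10: 33.0}
    - {age_min: 55, age_max: 60, p10: 31.0}
    - {age_min: 60, age_max: 65, p10: 29.0}
    - {age_min: 65, age_max: 70, p10: 26.5}
    - {age_min: 70, age_max: 75, p10: 24.0}
    - {age_min: 75, age_max: 80, p10: 21.0}
    - {age_min: 80, age_max: 85, p10: 18.5}
    - {age_min: 85, age_max: 95, p10: 16.0}
  0:  # female
    - {age_min: 50, age_max: 55, p10: 20.0}
    - {age_min: 55, age_max: 60, p10: 19.0}
    - {age_min: 60, age_max: 65, p10: 17.5}
    - {age_min: 65, age_max: 70, p10: 16.0}
    - {age_min: 70, age_max: 75, p10: 14.5}
    - {age_min: 75, age_max: 80, p10: 13.0}
    - {age_min: 80, age_max: 85, p10: 11.5}
    - {age_min: 85, age_max: 95, p10: 10.0}
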