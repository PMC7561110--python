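# Demonstration configuration: a small synthetic study.
# Omitted generator settings keep their defaults (2006-2017 span,
# codeine-dominated drug mix, 5% messy records, variance components
# 0.01/0.05/0.25 for region/practice/prescriber).
simulate:
  seed: 1
  n_regions: 3
  practices_per_region: 4
  prescribers_per_practice: 3
  patients_per_prescriber: 25
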