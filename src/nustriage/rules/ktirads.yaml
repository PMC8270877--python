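# K-TIRADS rule table
# Provenance: Korean Society of Thyroid Radiology consensus recommendations
# (Shin et al., Korean J Radiol 2016). Category 1 (no nodule) is not
# representable: the cohort contains only actual nodules.
system: KTIRADS
version: "2016"
classes: ["2", "3", "4", "5"]
suspicious_features:
  margins: [irregular_or_blurred, lobulated, extrathyroidal_extension]
  echogenic_foci: [microcalcification_punctate]
  taller_than_wide: true
  markedly_hypoechoic: false
# FNA size thresholds, mm; strict=false means ">=", strict=true means ">".
fna_thresholds:
  "2": {min_mm: 20, strict: false}
  "3": {min_mm: 15, strict: false}
  "4": {min_mm: 10, strict: false}
  "5": {min_mm: 10, strict: false}
ordinal_ranks: {"2": 1, "3": 2, "4": 3, "5": 4}
# Class 4 sits in the high macro-risk group: its expected malignancy band
# (15-50%) overlaps the >20% high-risk area.
macro_risk: {"2": low, "3": intermediate, "4": high, "5": high}
sparing_excluded_classes: []
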