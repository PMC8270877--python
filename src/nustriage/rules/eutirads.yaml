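# EU-TIRADS rule table
# Provenance: European Thyroid Association guidelines for ultrasound
# malignancy risk stratification of thyroid nodules (Russ et al.,
# Eur Thyroid J 2017). Category 1 (no nodule) is not representable.
system: EUTIRADS
version: "2017"
classes: ["2", "3", "4", "5"]
suspicious_features:
  margins: [irregular_or_blurred, extrathyroidal_extension]
  echogenic_foci: [microcalcification_punctate]
  taller_than_wide: true
  markedly_hypoechoic: true
fna_thresholds:
  "2": null
  "3": {min_mm: 20, strict: true}
  "4": {min_mm: 15, strict: true}
  "5": {min_mm: 10, strict: true}
ordinal_ranks: {"2": 1, "3": 2, "4": 3, "5": 4}
macro_risk: {"2": low, "3": low, "4": intermediate, "5": high}
sparing_excluded_classes: []
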