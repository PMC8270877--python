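# ATA sonographic-pattern rule table
# Provenance: 2015 American Thyroid Association management guidelines for
# adult patients with thyroid nodules and differentiated thyroid cancer
# (Haugen et al., Thyroid 2016).
# Some feature bundles match none of the official patterns (isoechoic or
# hyperechoic solid nodules with suspicious features; mixed nodules with a
# doubtful eccentric solid portion): the classifier returns the
# UNCLASSIFIABLE sentinel for those.
system: ATA
version: "2015"
classes: [benign, very_low, low, intermediate, high]
suspicious_features:
  margins: [irregular_or_blurred, lobulated, extrathyroidal_extension]
  echogenic_foci: [microcalcification_punctate, rim_calcification_with_extrusion]
  taller_than_wide: true
  markedly_hypoechoic: false
fna_thresholds:
  benign: null
  very_low: {min_mm: 20, strict: false}
  low: {min_mm: 15, strict: false}
  intermediate: {min_mm: 10, strict: false}
  high: {min_mm: 10, strict: false}
ordinal_ranks: {benign: 1, very_low: 2, low: 3, intermediate: 4, high: 5}
macro_risk:
  benign: low
  very_low: low
  low: intermediate
  intermediate: intermediate
  high: high
# The benign class never indicates FNA; it is left out of the spared-FNA
# totals by default (include_benign_class toggles it back in).
sparing_excluded_classes: [benign]
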