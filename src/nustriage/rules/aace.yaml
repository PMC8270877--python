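# AACE/ACE-AME rule table
# Provenance: American Association of Clinical Endocrinologists / American
# College of Endocrinology / Associazione Medici Endocrinologi guidelines
# for the diagnosis and management of thyroid nodules (Gharib et al.,
# Endocr Pract 2016). Three-class system.
system: AACE
version: "2016"
classes: [low, intermediate, high]
suspicious_features:
  margins: [irregular_or_blurred, lobulated, extrathyroidal_extension]
  echogenic_foci: [microcalcification_punctate]
  taller_than_wide: true
  markedly_hypoechoic: true
fna_thresholds:
  low: {min_mm: 20, strict: true}
  intermediate: {min_mm: 20, strict: true}
  high: {min_mm: 10, strict: false}
ordinal_ranks: {low: 1, intermediate: 2, high: 3}
macro_risk: {low: low, intermediate: intermediate, high: high}
sparing_excluded_classes: []
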