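# ACR TI-RADS point table
# Provenance: American College of Radiology Thyroid Imaging, Reporting and
# Data System white paper (Tessler et al., J Am Coll Radiol 2017).
# Points are summed across the five feature categories; echogenic-foci
# points are additive across the foci present. Totals are capped at 14,
# the top of the reported scoring range.
system: ACRTIRADS
version: "2017"
classes: [TR1, TR2, TR3, TR4, TR5]
points:
  composition:
    cystic: 0
    spongiform: 0
    mixed: 1
    solid: 2
  echogenicity:
    anechoic: 0
    hyperechoic: 1
    isoechoic: 1
    slightly_hypoechoic: 2
    hypoechoic: 2
    markedly_hypoechoic: 3
  shape:
    wider_than_tall: 0
    taller_than_wide: 3
  margins:
    smooth: 0
    irregular_or_blurred: 2
    lobulated: 2
    extrathyroidal_extension: 3
  echogenic_foci:
    none: 0
    hyperechoic_spot_comet: 0
    macrocalcification: 1
    rim_calcification_with_extrusion: 2
    microcalcification_punctate: 3
max_points: 14
# Step function over total points. A total of 1 is unreachable under the
# canonical table but the band map must be total: it falls in TR1.
class_bands:
  - {class: TR1, min_points: 0, max_points: 1}
  - {class: TR2, min_points: 2, max_points: 2}
  - {class: TR3, min_points: 3, max_points: 3}
  - {class: TR4, min_points: 4, max_points: 6}
  - {class: TR5, min_points: 7, max_points: 14}
fna_thresholds:
  TR1: null
  TR2: null
  TR3: {min_mm: 25, strict: false}
  TR4: {min_mm: 15, strict: false}
  TR5: {min_mm: 10, strict: false}
ordinal_ranks: {TR1: 1, TR2: 2, TR3: 3, TR4: 4, TR5: 5}
macro_risk: {TR1: low, TR2: low, TR3: intermediate, TR4: intermediate, TR5: high}
sparing_excluded_classes: []
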