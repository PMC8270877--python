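# nustriage

Rule-based thyroid-nodule ultrasound risk stratification and FNA triage
analysis.

Thyroid nodules are extremely common and overwhelmingly benign, yet each
suspicious finding tends to trigger a fine-needle aspiration (FNA) and
sometimes surgery for an indolent cancer. Professional societies have
answered with *nodule ultrasound scores* (NUS): rule systems that map
sonographic features (composition, echogenicity, margins, shape, echogenic
foci) plus nodule size to a malignancy-risk class and an FNA recommendation.
`nustriage` implements five of them over a single harmonized feature lexicon
— **K-TIRADS** (2016), **ATA** (2015 patterns), **AACE/ACE-AME** (2016),
**EU-TIRADS** (2017) and **ACR-TIRADS** (2017 point system, 0–14 points
banded into TR1–TR5) — together with the cytology handling and
diagnostic-performance statistics needed to compare them on an FNA cohort.
It is aimed at endocrinologists, radiologists and biostatisticians auditing
how much cytology a given score would spare in their own practice.

## What it computes

For a cohort of nodules that underwent FNA:

- **Cytology dichotomization.** SIAPEC TIR categories (and British Thy
  categories before May 2014) collapse to *positive* (TIR3B/TIR4/TIR5,
  pre-2014 Thy3+; surgical referral) vs *negative* (TIR2, or TIR3A confirmed
  in two consecutive samples), with unresolved and nondiagnostic handled
  explicitly.
- **Per-class prevalence.** For each score class `c`, the observed positive
  rate `n⁺_c / (n⁺_c + n⁻_c)` against the class's expected-malignancy band.
- **FNA sparing.** With test-positive defined as "class + size indicate
  FNA", *expected* FNA = indicated nodules, *spared* = observed − expected,
  per class and in total.
- **Triage metrics.** Sens = TP/(TP+FN), Spec = TN/(TN+FP), PPV, NPV with
  Wald 95% intervals `p ± 1.96·√(p(1−p)/n)`.
- **Ordinal ROC/AUC.** Classes ranked 1–3 (AACE), 1–4 (K-TIRADS,
  EU-TIRADS), 1–5 (ATA, ACR); ACR total points additionally as a continuous
  score. AUC is the rank concordance (ties ½) with a Hanley–McNeil interval.
- **Interobserver agreement.** Unweighted Cohen's κ with Landis–Koch bands.
- **Macro-risk pooling.** Classes clustered into low (<5% expected
  malignancy), intermediate (5–20%) and high (>20%) groups across systems
  (K-TIRADS 4 pools high).

ATA pattern matching is deliberately partial: bundles matching no official
pattern (e.g. isoechoic solid nodules with microcalcifications, mixed
nodules with a doubtful eccentric solid portion) get an `UNCLASSIFIABLE`
sentinel and are excluded from ATA per-class statistics.

Because no patient-level data from the motivating cohort is public, the
package ships (a) the study tables' printed per-class counts as fixtures,
expandable into a count-weighted pseudo-cohort, and (b) a seeded synthetic
cohort generator built on sonographic archetypes, calibrated to the
K-TIRADS observed marginals (other systems' marginals are emergent).

## Worked example

Classify one suspicious nodule with all five systems:

```python
from nustriage import *

features = UltrasoundFeatures(
    composition=Composition.SOLID,
    echogenicity=Echogenicity.HYPOECHOIC,
    halo=Halo.ABSENT,
    margins=Margins.IRREGULAR_OR_BLURRED,
    taller_than_wide=False,
    echogenic_foci=frozenset({EchogenicFocus.MICROCALCIFICATION_PUNCTATE}),
    vascularization=Vascularization.MARKED_INTRANODULAR_OR_MIXED,
    diameters_mm=(18.0, 13.0, 11.0),
)
for system, a in classify_all(features).items():
    print(f"{system.value:10s} class={a.class_label:14s} rank={a.ordinal_rank} "
          f"points={a.acr_points} fna={a.fna_indicated} "
          f"macro={macro_group(system, a.class_label).value}")
```

```
KTIRADS    class=5              rank=4 points=None fna=True macro=high
ATA        class=high           rank=5 points=None fna=True macro=high
AACE       class=high           rank=3 points=None fna=True macro=high
EUTIRADS   class=5              rank=4 points=None fna=True macro=high
ACRTIRADS  class=TR5            rank=5 points=9 fna=True macro=high
```

All five agree: a hypoechoic solid 18-mm nodule with irregular margins and
punctate foci is high risk (ACR: 2+2+2+3 = 9 points → TR5) and FNA is
indicated at this size by every system.

Cohort-level analysis on the packaged printed counts:

```python
from nustriage import (NusSystem, table_fixture, sparing_report,
                       fna_triage_confusion, diagnostic_metrics)

obs = table_fixture().expand_observations(NusSystem.KTIRADS)
sp = sparing_report(obs)
print(f"K-TIRADS: spared {sp.n_spared_total} of {sp.n_observed_total} "
      f"FNA ({100*sp.spared_fraction:.1f}%)")
m = diagnostic_metrics(fna_triage_confusion(obs))
print(f"sensitivity {100*m['sensitivity'].value:.1f}%  "
      f"PPV {100*m['ppv'].value:.1f}% (+/- {100*m['ppv'].ci_half_width:.1f}%)")
```

```
K-TIRADS: spared 665 of 6474 FNA (10.3%)
sensitivity 94.5%  PPV 11.5% (+/- 0.8%)
```

Of 6474 FNAs, retrospective K-TIRADS triage would have spared 665 (10.3%);
the indication catches 94.5% of positive cytologies, but only 11.5% of
indicated nodules turn out positive — the familiar high-sensitivity /
low-PPV profile of ultrasound triage in a mostly benign population.

## Command line

```
nustriage simulate --output cohort.csv --n 6474 --seed 1
nustriage classify --input cohort.csv --output annotated.csv
nustriage evaluate --input cohort.csv --output report.json
nustriage agreement --input ratings.csv
nustriage reproduce-tables
```

Every run writes a manifest (seed, rule-table versions and SHA-256
checksums, input digests) sufficient to reproduce it. The guideline
criteria live in versioned YAML files under `src/nustriage/rules/`; each
carries a provenance header naming the guideline it transcribes.

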