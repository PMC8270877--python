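# Methods

## Cohort model and eligibility

The unit of analysis is a thyroid nodule that underwent fine-needle
aspiration (FNA). A record carries the harmonized sonographic lexicon
(composition; eccentricity of the solid portion for mixed nodules;
six-level echogenicity; halo; margins; taller-than-wide shape; a set of
echogenic foci; three-level vascularization; three diameters in mm), an
ordered cytology history, and optionally a surgical histology label.

Eligibility mirrors the study flowchart: nodules are excluded when the
maximum of the three diameters is strictly below 10 mm (exactly 10.0 mm is
eligible — the literal reading of "lower than 10 mm"), when the descriptive
lexicon is incomplete, or when the entire cytology history is
nondiagnostic (TIR1/Thy1). Each exclusion carries one primary reason with
precedence sub-centimetric > incomplete > no cytology > nondiagnostic. The
maximum diameter is also the size compared against every FNA threshold;
the guidelines the rule tables transcribe use the largest diameter.

## Cytology dichotomization

Outcome positive: any TIR3B, TIR4 or TIR5 — or, before May 2014, any Thy3,
Thy4 or Thy5 (the indeterminate Thy3 carried surgical referral in that
era). Outcome negative: a benign TIR2/Thy2, or the low-risk indeterminate
TIR3A confirmed in two consecutive adequate samples. A single unconfirmed
TIR3A is *unresolved*; only-inadequate histories are *nondiagnostic*.
Design choices, both surfaced as options:

- A single TIR2 suffices for a negative outcome. The confirmation
  requirement ("in at least two consecutive samples") is applied to TIR3A
  only; the stricter reading is available via
  `tir2_requires_confirmation=True`.
- "Consecutive" is evaluated after dropping nondiagnostic samples from the
  ordered history: an inadequate pass between two TIR3A results does not
  reset the confirmation.

A nodule with mixed-era cytology is classified by its most severe result
(positivity is order-invariant) and is dropped from the post-2014 subset,
which keeps only records whose entire history uses the SIAPEC scheme and —
in the uniformity sub-analysis mode — additionally drops any record
containing TIR3A or TIR3B. The sub-analysis *mode* is implemented; no
reference values are asserted for it.

## Rule tables

The five classifiers consume YAML rule files shipped as package data
(`rules/*.yaml`, versioned, SHA-256-checksummed at load, provenance header
naming the transcribed guideline). The files hold the FNA size thresholds
with per-entry strictness (e.g. K-TIRADS 3 indicates at ≥15 mm while
EU-TIRADS 3 requires >20 mm), the ordinal ranks, the macro-risk map, each
system's high-suspicion feature set, and the ACR point tables. The
branching skeleton (e.g. "suspicious features on a non-hypoechoic solid
nodule match no ATA pattern") stays in code.

Decisions taken where the published criteria leave room:

- **ACR points are capped at 14**, the top of the published 1–14 scoring
  range. The raw additive foci sum can reach 17 when macro-, rim- and
  punctate calcifications co-occur; the cap preserves monotonicity (a more
  suspicious feature never lowers the total). A total of 1 point is
  unreachable under the canonical table but maps to TR1 so the banding is
  total.
- **Benign patterns require the absence of high-suspicion features.** A
  nominally cystic or spongiform bundle carrying microcalcifications,
  taller-than-wide shape or extrathyroidal extension is not classified
  into a <5%-risk class by any system (K-TIRADS and EU-TIRADS route such
  bundles to their suspicious-feature classes; ATA returns the sentinel).
  This keeps the class maps clinically coherent and is audited by
  exhaustive enumeration of the finite feature lattice.
- K-TIRADS/EU-TIRADS class 1 ("no nodule") are not representable.
- Halo and vascularization are recorded but scored by none of the five
  systems; they remain available to the simulator and future rules.
- ATA `UNCLASSIFIABLE` is a first-class sentinel: excluded from ATA
  per-class statistics, sparing and ROC, reported as a pseudo-class, and a
  sensitivity mode drops those nodules from all five systems' analyses.

## FNA sparing and triage metrics

All cohort nodules underwent FNA (*observed*). A nodule is *expected* when
its class and size indicate FNA; *spared* = observed − expected. The ATA
benign class, which never indicates FNA, is excluded from the spared
totals by default (matching the published accounting) while the spared
fraction keeps the full classified denominator; EU-TIRADS 2 and ACR TR1–2,
although also never-indicating, are included, again following the
published totals.

Triage metrics use test-positive = "FNA indicated", outcome-positive =
"positive cytology". This dichotomy exactly reproduces the published
K-TIRADS row (sensitivity 94.5%, PPV 11.5%, Wald PPV half-width 0.8
points). The remaining published sensitivity/specificity/NPV rows, and the
macro-group metric table, could not be reconstructed from the printed
counts under any dichotomy tried; they are therefore covered by property
tests only (conservation, scale invariance, estimator–oracle equivalence)
and no alternative reconstruction is asserted. Confidence intervals are
Wald with z = 1.96, no continuity correction, each metric over its own
margin; degenerate margins report the metric as undefined rather than 0.

AUC uses the rank concordance estimator (ties ½) — algebraically the
Mann–Whitney statistic — with the Hanley–McNeil variance; the test suite
checks it against a brute-force pairwise oracle and an independent library
implementation. Cohen's κ is unweighted, SE √(p₀(1−p₀)/n)/(1−pₑ), with
Landis–Koch bands (≤0.20 slight … 0.81–1.0 almost perfect). The
chi-squared test is Pearson's without continuity correction. No
multiple-testing adjustment is applied anywhere.

## Packaged table fixtures

`fixtures/tables.json` stores the published per-class counts (expected /
observed FNA by cytology outcome, histology counts) and expands them into
a count-weighted pseudo-cohort. Spared counts are recomputed as observed −
expected componentwise; this reproduces every printed system total. Known
internal inconsistencies of the printed tables are stored verbatim with
flags rather than silently corrected:

- the ACR TR4 spared row prints 667 where its own components give 677 (the
  printed per-class spared sum is 1314 against a printed total of 1324,
  which matches observed − expected);
- the EU-TIRADS 2 spared row prints a negative count of 8 against a row
  total of 49;
- the ACR TR5 positive count prints 193, inconsistent with its row total
  and percentage (16.7% of 2227); the reconstruction 371 restores the row,
  the system totals and the cohort-wide 709 positive cytologies that every
  other system's column sums to;
- never-indicating classes (EU-TIRADS 2, ACR TR1–2) carry small nonzero
  printed expected-FNA counts — an observed-practice artifact the
  expansion keeps verbatim, while rule-based indication for those classes
  remains "never".

The fixture regression (`nustriage reproduce-tables`, 52 checks) pushes
the expansion through `class_summary` and `sparing_report` and compares
every reproducible printed cell exactly.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
patient data. A cohort is a mixture of sonographic **archetypes** — fixed
descriptive bundles (pure cyst, spongiform, mixed with eccentric/doubtful
solid portion, isoechoic solid with/without microcalcifications,
hypoechoic solid plain/suspicious, markedly hypoechoic taller-than-wide) —
so one nodule is classified differently by different systems, as in real
cohorts. Per nodule: a truncated log-normal maximum diameter on
[10 mm, ∞) (inverse-CDF sampling; archetype-specific medians 15–24 mm,
σ_log 0.40), two subordinate diameters as uniform fractions, Bernoulli
truth with the archetype's `malignancy_prob`, then a cytology category
conditional on truth: benign → TIR2, or a confirmed TIR3A pair with
probability `indeterminate_given_benign` (0.13; pre-2014 era → Thy2);
malignant → TIR3B/Thy3 with probability `indeterminate_given_malignant`
(0.72, the published indeterminate share among referrals), else TIR4 vs
TIR5 at 129:70. Era is pre-2014 with probability 0.5 (the study spans
2008–2018 with the scheme change mid-way). Histology labels are drawn for
malignant nodules from the published surgical-series mix (papillary
classic 46.8%, …). Only rule-inert features (halo, vascularization) and
demographics are jittered, so each archetype's class under every system is
deterministic.

Because benign truth never yields a positive category and malignant truth
always does, an archetype's positive-cytology rate equals its
`malignancy_prob` exactly. **Default calibration** therefore is
closed-form rather than a search: archetype weights are the published
K-TIRADS observed class shares split within class by fixed proportions
(chosen once so the emergent ATA-unclassifiable share lands near the
study's 7%), and each archetype's `malignancy_prob` is its K-TIRADS
class's observed positive rate. K-TIRADS margins match the targets in
expectation exactly (within ±2 points in realized draws at n = 6474);
the other four systems' margins are emergent, mirroring the real
data-generating process, and are reported rather than forced.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: benign-truth high-risk cytology
(false-positive TIR3B on benign nodules), operator-level feature noise
(so κ studies need the separate perturbation path in the agreement
workflow), within-archetype feature correlation beyond the discrete
bundles, and any size–malignancy dependence. Randomness uses one seed with
fixed per-stage sub-streams (`default_rng([stage, seed])`), so adding a
stage never perturbs earlier draws; identical configurations reproduce
byte-identical cohorts.

## Problem sizes

The test suite generates cohorts of up to 10⁴ nodules for parameter
recovery (3-binomial-SE envelopes) and 100 000 histology draws; the
exhaustive lattice audits enumerate all 4352 valid feature bundles. The
acceptance script uses the study-sized cohort (n = 6474) for the
simulation-derived quantities. The full suite runs in well under a minute
on one CPU.

## Known limitations

- Rule-table fidelity is to the five published guidelines; any unpublished
  adaptation the motivating study made in its supplementary summary cannot
  be captured.
- The Wald intervals and the κ standard error are large-sample
  approximations; no bootstrap or exact intervals are provided.
- The published AUCs (≈0.6) and κ range (0.50–0.73) require patient-level
  data and are not reproduced; estimator correctness is established
  against oracles instead.
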