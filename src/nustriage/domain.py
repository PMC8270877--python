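"""Nodule data model, cohort eligibility filtering and cytology dichotomization.

The study cohort consists of thyroid nodules that underwent fine-needle
aspiration (FNA). Each nodule carries a harmonized sonographic description
(the feature lexicon consumed by all five ultrasound scoring systems), an
ordered cytology history (British Thy categories before May 2014, Italian
SIAPEC TIR categories afterwards), and optionally a surgical histology label.

Cytology is dichotomized into the study's operational outcome:

* **positive** — any TIR3B/TIR4/TIR5 (or pre-2014 Thy3/Thy4/Thy5) result;
  these nodules are referred for surgical consideration.
* **negative** — a benign result (TIR2/Thy2), or a low-risk indeterminate
  TIR3A confirmed in two consecutive samples.
* **unresolved** — a single unconfirmed TIR3A and nothing else informative.
* **nondiagnostic** — only inadequate samples (TIR1/Thy1).
"""

from __future__ import annotations

import csv
import enum
import io
from typing import Iterable, Optional, Sequence, TextIO, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Composition(str, enum.Enum):
    CYSTIC = "cystic"
    SPONGIFORM = "spongiform"
    MIXED = "mixed"
    SOLID = "solid"


class Echogenicity(str, enum.Enum):
    ANECHOIC = "anechoic"
    HYPERECHOIC = "hyperechoic"
    ISOECHOIC = "isoechoic"
    SLIGHTLY_HYPOECHOIC = "slightly_hypoechoic"
    HYPOECHOIC = "hypoechoic"
    MARKEDLY_HYPOECHOIC = "markedly_hypoechoic"


class Halo(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    DISCONTINUOUS_OR_THICK = "discontinuous_or_thick"


class Margins(str, enum.Enum):
    SMOOTH = "smooth"
    IRREGULAR_OR_BLURRED = "irregular_or_blurred"
    LOBULATED = "lobulated"
    EXTRATHYROIDAL_EXTENSION = "extrathyroidal_extension"


class EchogenicFocus(str, enum.Enum):
    NONE = "none"
    HYPERECHOIC_SPOT_COMET = "hyperechoic_spot_comet"
    MACROCALCIFICATION = "macrocalcification"
    MICROCALCIFICATION_PUNCTATE = "microcalcification_punctate"
    RIM_CALCIFICATION_WITH_EXTRUSION = "rim_calcification_with_extrusion"


class Vascularization(str, enum.Enum):
    ABSENT = "absent"
    PERINODULAR_SLIGHT_INTRANODULAR = "perinodular_slight_intranodular"
    MARKED_INTRANODULAR_OR_MIXED = "marked_intranodular_or_mixed"


class CytologySystem(str, enum.Enum):
    BTA = "BTA"
    SIAPEC = "SIAPEC"


class CytologyEra(str, enum.Enum):
    PRE2014 = "pre2014"
    POST2014 = "post2014"


BTA_CATEGORIES = frozenset({"Thy1", "Thy2", "Thy3", "Thy4", "Thy5"})
SIAPEC_CATEGORIES = frozenset({"TIR1", "TIR2", "TIR3A", "TIR3B", "TIR4", "TIR5"})

#: Categories that dichotomize as positive cytology (surgical referral).
POSITIVE_CATEGORIES = frozenset({"TIR3B", "TIR4", "TIR5", "Thy3", "Thy4", "Thy5"})
#: Benign categories: a single occurrence suffices for a negative outcome.
BENIGN_CATEGORIES = frozenset({"TIR2", "Thy2"})
#: Inadequate samples.
NONDIAGNOSTIC_CATEGORIES = frozenset({"TIR1", "Thy1"})
#: Low-risk indeterminate needing confirmation in two consecutive samples.
LOW_RISK_INDETERMINATE = "TIR3A"
#: Indeterminate categories (either risk tier) for the post-2014 sub-analysis.
INDETERMINATE_CATEGORIES = frozenset({"TIR3A", "TIR3B"})


class CytologyOutcomeValue(str, enum.Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    UNRESOLVED = "unresolved"
    NONDIAGNOSTIC = "nondiagnostic"


class HistologyLabel(str, enum.Enum):
    PAPILLARY_CLASSIC = "papillary_classic"
    FOLLICULAR_VARIANT_PAPILLARY = "follicular_variant_papillary"
    MEDULLARY = "medullary"
    OTHER_WELL_DIFFERENTIATED = "other_well_differentiated"
    INSULAR = "insular"
    OTHER_POORLY_DIFFERENTIATED = "other_poorly_differentiated"
    METASTASIS_OTHER_CANCER = "metastasis_other_cancer"


class ExclusionReason(str, enum.Enum):
    SUBCENTIMETER = "subcentimeter"
    INCOMPLETE_FEATURES = "incomplete_features"
    NO_CYTOLOGY = "no_cytology"
    NONDIAGNOSTIC = "nondiagnostic"


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class UltrasoundFeatures(BaseModel):
    """Per-nodule sonographic lexicon shared by all five scoring systems.

    Categorical fields are optional so that an incompletely described nodule
    can still be represented (and then excluded by :func:`eligibility_filter`);
    the three diameters are always required.
    """

    model_config = ConfigDict(frozen=True)

    composition: Optional[Composition] = None
    solid_portion_eccentric: Optional[bool] = None
    echogenicity: Optional[Echogenicity] = None
    halo: Optional[Halo] = None
    margins: Optional[Margins] = None
    taller_than_wide: Optional[bool] = None
    echogenic_foci: Optional[frozenset[EchogenicFocus]] = None
    vascularization: Optional[Vascularization] = None
    diameters_mm: tuple[float, float, float]

    @field_validator("diameters_mm")
    @classmethod
    def _positive_diameters(cls, v):
        if any(d <= 0 for d in v):
            raise ValueError("all diameters must be > 0 mm")
        return v

    @model_validator(mode="after")
    def _cross_field(self):
        if self.solid_portion_eccentric is not None and self.composition is not Composition.MIXED:
            raise ValueError("solid_portion_eccentric applies to mixed nodules only")
        if self.echogenicity is Echogenicity.ANECHOIC and self.composition not in (
            Composition.CYSTIC, Composition.MIXED, None,
        ):
            raise ValueError("anechoic echogenicity requires cystic or mixed composition")
        if self.echogenic_foci is not None and EchogenicFocus.NONE in self.echogenic_foci \
                and len(self.echogenic_foci) > 1:
            raise ValueError('echogenic_foci containing "none" must contain nothing else')
        return self

    @property
    def max_diameter_mm(self) -> float:
        return max(self.diameters_mm)

    @property
    def is_complete(self) -> bool:
        """Whether every scored descriptive field is present.

        ``solid_portion_eccentric`` may legitimately be unknown ("doubtful"
        eccentric solid portion) without the description being incomplete.
        """
        return None not in (
            self.composition, self.echogenicity, self.halo, self.margins,
            self.taller_than_wide, self.echogenic_foci, self.vascularization,
        )

    def has_focus(self, focus: EchogenicFocus) -> bool:
        return self.echogenic_foci is not None and focus in self.echogenic_foci


class CytologyResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    system: CytologySystem
    category: str
    era: CytologyEra

    @model_validator(mode="after")
    def _consistent(self):
        if self.system is CytologySystem.BTA:
            if self.category not in BTA_CATEGORIES:
                raise ValueError(f"{self.category!r} is not a BTA Thy category")
            if self.era is not CytologyEra.PRE2014:
                raise ValueError("BTA cytology implies the pre-2014 era")
        else:
            if self.category not in SIAPEC_CATEGORIES:
                raise ValueError(f"{self.category!r} is not a SIAPEC TIR category")
            if self.era is not CytologyEra.POST2014:
                raise ValueError("SIAPEC cytology implies the post-2014 era")
        return self


class CytologyOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)
    value: CytologyOutcomeValue


class NoduleRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    nodule_id: str
    patient_id: str
    features: UltrasoundFeatures
    cytology_history: tuple[CytologyResult, ...] = ()
    fna_performed: bool = True
    histology: Optional[HistologyLabel] = None
    sex: Optional[str] = None
    age_years: Optional[float] = None

    @model_validator(mode="after")
    def _fna_implies_cytology(self):
        if self.fna_performed and not self.cytology_history:
            raise ValueError("fna_performed requires a non-empty cytology history")
        return self

    @property
    def max_diameter_mm(self) -> float:
        return self.features.max_diameter_mm


# ---------------------------------------------------------------------------
# Cytology dichotomization
# ---------------------------------------------------------------------------

def dichotomize_cytology(
    history: Sequence[CytologyResult],
    *,
    tir2_requires_confirmation: bool = False,
) -> CytologyOutcome:
    """Collapse an ordered cytology history to the study outcome.

    Any high-risk category (TIR3B/TIR4/TIR5, or pre-2014 Thy3/Thy4/Thy5)
    makes the outcome positive regardless of order. A benign result (TIR2 or
    Thy2) makes it negative — by default a single occurrence suffices, while
    the low-risk indeterminate TIR3A must appear in two consecutive samples
    (nondiagnostic results in between are skipped, as the confirmation refers
    to consecutive adequate samples). ``tir2_requires_confirmation`` extends
    the two-consecutive rule to TIR2/Thy2 for the stricter reading of the
    confirmation requirement.
    """
    if not history:
        raise ValueError("cytology history must be non-empty")
    cats = [r.category for r in history]
    if any(c in POSITIVE_CATEGORIES for c in cats):
        return CytologyOutcome(value=CytologyOutcomeValue.POSITIVE)

    adequate = [c for c in cats if c not in NONDIAGNOSTIC_CATEGORIES]
    if not adequate:
        return CytologyOutcome(value=CytologyOutcomeValue.NONDIAGNOSTIC)

    if tir2_requires_confirmation:
        negative = any(
            a in BENIGN_CATEGORIES | {LOW_RISK_INDETERMINATE}
            and b in BENIGN_CATEGORIES | {LOW_RISK_INDETERMINATE}
            for a, b in zip(adequate, adequate[1:])
        )
    else:
        negative = any(c in BENIGN_CATEGORIES for c in adequate) or any(
            a == LOW_RISK_INDETERMINATE and b == LOW_RISK_INDETERMINATE
            for a, b in zip(adequate, adequate[1:])
        )
    if negative:
        return CytologyOutcome(value=CytologyOutcomeValue.NEGATIVE)
    return CytologyOutcome(value=CytologyOutcomeValue.UNRESOLVED)


def post2014_subset(
    records: Iterable[NoduleRecord],
    exclude_indeterminate: bool = False,
) -> list[NoduleRecord]:
    """Restrict to nodules whose entire cytology uses the post-May-2014
    SIAPEC classification; optionally drop indeterminate (TIR3A/TIR3B)
    cytology for the uniformity sub-analysis."""
    out = []
    for rec in records:
        if not rec.cytology_history:
            continue
        if any(r.era is not CytologyEra.POST2014 for r in rec.cytology_history):
            continue
        if exclude_indeterminate and any(
            r.category in INDETERMINATE_CATEGORIES for r in rec.cytology_history
        ):
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Eligibility filtering (study flowchart)
# ---------------------------------------------------------------------------

MIN_ELIGIBLE_DIAMETER_MM = 10.0


def eligibility_filter(
    records: Iterable[NoduleRecord],
) -> tuple[list[NoduleRecord], list[tuple[NoduleRecord, ExclusionReason]]]:
    """Partition records into the analysis cohort and exclusions.

    Excludes sub-centimetric nodules (max diameter strictly below 10 mm;
    exactly 10.0 mm is eligible), incompletely described nodules, nodules
    without any cytology, and nodules whose entire history is nondiagnostic.
    Each excluded record carries exactly one primary reason, assigned in that
    order of precedence.
    """
    eligible: list[NoduleRecord] = []
    excluded: list[tuple[NoduleRecord, ExclusionReason]] = []
    for rec in records:
        if rec.max_diameter_mm < MIN_ELIGIBLE_DIAMETER_MM:
            excluded.append((rec, ExclusionReason.SUBCENTIMETER))
        elif not rec.features.is_complete:
            excluded.append((rec, ExclusionReason.INCOMPLETE_FEATURES))
        elif not rec.cytology_history:
            excluded.append((rec, ExclusionReason.NO_CYTOLOGY))
        elif dichotomize_cytology(rec.cytology_history).value is CytologyOutcomeValue.NONDIAGNOSTIC:
            excluded.append((rec, ExclusionReason.NONDIAGNOSTIC))
        else:
            eligible.append(rec)
    return eligible, excluded


# ---------------------------------------------------------------------------
# CSV parsing
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = (
    "nodule_id", "patient_id", "composition", "echogenicity", "halo",
    "margins", "taller_than_wide", "echogenic_foci", "vascularization",
    "diam1_mm", "diam2_mm", "diam3_mm", "cytology", "fna_performed",
)
OPTIONAL_COLUMNS = ("solid_portion_eccentric", "histology", "sex", "age_years")
ALL_COLUMNS = MANDATORY_COLUMNS[:2] + ("composition", "solid_portion_eccentric") + \
    MANDATORY_COLUMNS[3:] + ("histology", "sex", "age_years")

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class SchemaError(ValueError):
    """Raised when the input table violates the documented schema."""


class Reject(BaseModel):
    row: int  # 1-based data row number (header = row 0)
    reason: str


class ParseResult(BaseModel):
    records: list[NoduleRecord]
    rejects: list[Reject]


def _parse_bool(token: str, field: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{field}: cannot parse boolean token {token!r}")


def _parse_optional_enum(token: str, enum_cls, field: str):
    t = token.strip()
    if not t:
        return None
    try:
        return enum_cls(t)
    except ValueError:
        raise ValueError(f"{field}: unknown token {t!r}") from None


def parse_cytology_field(token: str) -> tuple[CytologyResult, ...]:
    """Parse semicolon-joined ``system:category:era`` triples."""
    t = token.strip()
    if not t:
        return ()
    results = []
    for part in t.split(";"):
        bits = part.strip().split(":")
        if len(bits) != 3:
            raise ValueError(f"cytology: expected system:category:era, got {part!r}")
        results.append(CytologyResult(
            system=CytologySystem(bits[0]), category=bits[1], era=CytologyEra(bits[2]),
        ))
    return tuple(results)


def format_cytology_field(history: Sequence[CytologyResult]) -> str:
    return ";".join(f"{r.system.value}:{r.category}:{r.era.value}" for r in history)


def _row_to_record(row: dict[str, str]) -> NoduleRecord:
    diam = tuple(float(row[c]) for c in ("diam1_mm", "diam2_mm", "diam3_mm"))
    foci_tok = row.get("echogenic_foci", "").strip()
    foci = None
    if foci_tok:
        foci = frozenset(EchogenicFocus(p.strip()) for p in foci_tok.split(";") if p.strip())
    ecc_tok = row.get("solid_portion_eccentric", "").strip()
    ecc = _parse_bool(ecc_tok, "solid_portion_eccentric") if ecc_tok else None
    ttw_tok = row.get("taller_than_wide", "").strip()
    features = UltrasoundFeatures(
        composition=_parse_optional_enum(row.get("composition", ""), Composition, "composition"),
        solid_portion_eccentric=ecc,
        echogenicity=_parse_optional_enum(row.get("echogenicity", ""), Echogenicity, "echogenicity"),
        halo=_parse_optional_enum(row.get("halo", ""), Halo, "halo"),
        margins=_parse_optional_enum(row.get("margins", ""), Margins, "margins"),
        taller_than_wide=_parse_bool(ttw_tok, "taller_than_wide") if ttw_tok else None,
        echogenic_foci=foci,
        vascularization=_parse_optional_enum(
            row.get("vascularization", ""), Vascularization, "vascularization"),
        diameters_mm=diam,
    )
    hist_tok = row.get("histology", "").strip()
    age_tok = row.get("age_years", "").strip()
    return NoduleRecord(
        nodule_id=row["nodule_id"].strip(),
        patient_id=row["patient_id"].strip(),
        features=features,
        cytology_history=parse_cytology_field(row.get("cytology", "")),
        fna_performed=_parse_bool(row["fna_performed"], "fna_performed"),
        histology=HistologyLabel(hist_tok) if hist_tok else None,
        sex=row.get("sex", "").strip() or None,
        age_years=float(age_tok) if age_tok else None,
    )


def parse_nodule_table(source: Union[str, TextIO]) -> ParseResult:
    """Parse the documented nodule CSV into typed records.

    Rows that violate the schema or a model invariant are collected into the
    rejects report (with their 1-based data row number) rather than dropped
    silently; a missing mandatory column is a hard :class:`SchemaError`.
    """
    stream: TextIO = io.StringIO(source) if isinstance(source, str) else source
    reader = csv.DictReader(stream)
    header = reader.fieldnames or []
    for col in MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(f"missing mandatory column: {col!r}")
    records: list[NoduleRecord] = []
    rejects: list[Reject] = []
    for i, row in enumerate(reader, start=1):
        try:
            records.append(_row_to_record(row))
        except (ValueError, KeyError, TypeError, AttributeError) as exc:
            rejects.append(Reject(row=i, reason=str(exc)))
    return ParseResult(records=records, rejects=rejects)


def write_rejects_report(rejects: Sequence[Reject], stream: TextIO) -> None:
    w = csv.writer(stream)
    w.writerow(["row", "reason"])
    for r in rejects:
        w.writerow([r.row, r.reason])


def record_to_row(rec: NoduleRecord) -> dict[str, str]:
    """Inverse of row parsing, for writing the standard nodule CSV."""
    f = rec.features
    foci = ""
    if f.echogenic_foci is not None:
        foci = ";".join(sorted(x.value for x in f.echogenic_foci))

    def opt(v):
        return "" if v is None else (v.value if isinstance(v, enum.Enum) else str(v).lower()
                                     if isinstance(v, bool) else str(v))

    return {
        "nodule_id": rec.nodule_id,
        "patient_id": rec.patient_id,
        "composition": opt(f.composition),
        "solid_portion_eccentric": opt(f.solid_portion_eccentric),
        "echogenicity": opt(f.echogenicity),
        "halo": opt(f.halo),
        "margins": opt(f.margins),
        "taller_than_wide": opt(f.taller_than_wide),
        "echogenic_foci": foci,
        "vascularization": opt(f.vascularization),
        "diam1_mm": repr(f.diameters_mm[0]),
        "diam2_mm": repr(f.diameters_mm[1]),
        "diam3_mm": repr(f.diameters_mm[2]),
        "cytology": format_cytology_field(rec.cytology_history),
        "fna_performed": str(rec.fna_performed).lower(),
        "histology": opt(rec.histology),
        "sex": opt(rec.sex),
        "age_years": "" if rec.age_years is None else repr(rec.age_years),
    }


def write_nodule_table(records: Sequence[NoduleRecord], stream: TextIO) -> None:
    cols = list(MANDATORY_COLUMNS[:2]) + ["composition", "solid_portion_eccentric"] + \
        list(MANDATORY_COLUMNS[3:]) + ["histology", "sex", "age_years"]
    # composition appears once
    cols = list(dict.fromkeys(cols))
    w = csv.DictWriter(stream, fieldnames=cols)
    w.writeheader()
    for rec in records:
        w.writerow(record_to_row(rec))
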