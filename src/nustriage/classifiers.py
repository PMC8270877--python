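"""The five rule-based nodule ultrasound scoring systems.

Each classifier maps the harmonized sonographic lexicon to the system's risk
class, the FNA-indication size threshold for that class, the ordinal rank
used for ROC analysis (AACE 1-3; K-TIRADS and EU-TIRADS 1-4; ATA and
ACR-TIRADS 1-5), and the macro-risk group (low <5%, intermediate 5-20%,
high >20% expected malignancy; K-TIRADS 4 sits in the high group because of
its broad 15-50% expected-malignancy band).

The guideline criteria themselves live in versioned YAML rule files shipped
as package data (one per system, each with a provenance header); this module
holds only the pattern-branching skeleton that consumes them. ATA pattern
matching is partial by design: bundles matching no official pattern (for
example isoechoic solid nodules with microcalcifications, or mixed nodules
with a doubtful eccentric solid portion) receive the ``UNCLASSIFIABLE``
sentinel, never an error.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

from .domain import (
    Composition,
    Echogenicity,
    EchogenicFocus,
    Margins,
    UltrasoundFeatures,
)


class NusSystem(str, enum.Enum):
    KTIRADS = "KTIRADS"
    ATA = "ATA"
    AACE_ACE_AME = "AACE"
    EUTIRADS = "EUTIRADS"
    ACRTIRADS = "ACRTIRADS"


class MacroRisk(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


#: Sentinel class label for ATA pattern-match failures.
UNCLASSIFIABLE = "UNCLASSIFIABLE"

_HYPOECHOIC_GROUP = frozenset({
    Echogenicity.SLIGHTLY_HYPOECHOIC,
    Echogenicity.HYPOECHOIC,
    Echogenicity.MARKEDLY_HYPOECHOIC,
})

_RULE_FILES = {
    NusSystem.KTIRADS: "ktirads.yaml",
    NusSystem.ATA: "ata.yaml",
    NusSystem.AACE_ACE_AME: "aace.yaml",
    NusSystem.EUTIRADS: "eutirads.yaml",
    NusSystem.ACRTIRADS: "acrtirads.yaml",
}


class UnclassifiableError(ValueError):
    """Raised when an operation needs a concrete class but got the sentinel."""


@dataclass(frozen=True)
class FnaThreshold:
    min_mm: float
    strict: bool  # True: diameter must exceed min_mm; False: >= suffices

    def indicated(self, max_diameter_mm: float) -> bool:
        return max_diameter_mm > self.min_mm if self.strict \
            else max_diameter_mm >= self.min_mm


@dataclass(frozen=True)
class SystemRules:
    """One system's rule table, loaded from its YAML data file."""

    system: NusSystem
    version: str
    classes: tuple[str, ...]
    suspicious_margins: frozenset[Margins]
    suspicious_foci: frozenset[EchogenicFocus]
    suspicious_taller_than_wide: bool
    suspicious_marked_hypoechoic: bool
    fna_thresholds: dict[str, Optional[FnaThreshold]]
    ordinal_ranks: dict[str, int]
    macro_risk: dict[str, MacroRisk]
    sparing_excluded_classes: frozenset[str]
    checksum: str
    # ACR-TIRADS only:
    points: Optional[dict[str, dict[str, int]]] = None
    max_points: Optional[int] = None
    class_bands: Optional[tuple[tuple[str, int, int], ...]] = None

    def is_suspicious(self, f: UltrasoundFeatures) -> bool:
        """Whether the bundle carries any of this system's high-suspicion features."""
        if f.margins in self.suspicious_margins:
            return True
        if f.echogenic_foci and any(x in self.suspicious_foci for x in f.echogenic_foci):
            return True
        if self.suspicious_taller_than_wide and f.taller_than_wide:
            return True
        if self.suspicious_marked_hypoechoic and \
                f.echogenicity is Echogenicity.MARKEDLY_HYPOECHOIC:
            return True
        return False


def _load_system_rules(system: NusSystem) -> SystemRules:
    ref = resources.files("nustriage.rules") / _RULE_FILES[system]
    raw = ref.read_bytes()
    data = yaml.safe_load(raw)
    susp = data.get("suspicious_features", {})
    thresholds = {}
    for cls, t in data["fna_thresholds"].items():
        thresholds[str(cls)] = None if t is None else \
            FnaThreshold(min_mm=float(t["min_mm"]), strict=bool(t["strict"]))
    bands = None
    if "class_bands" in data:
        bands = tuple(
            (b["class"], int(b["min_points"]), int(b["max_points"]))
            for b in data["class_bands"]
        )
    return SystemRules(
        system=system,
        version=str(data["version"]),
        classes=tuple(str(c) for c in data["classes"]),
        suspicious_margins=frozenset(Margins(m) for m in susp.get("margins", [])),
        suspicious_foci=frozenset(EchogenicFocus(x) for x in susp.get("echogenic_foci", [])),
        suspicious_taller_than_wide=bool(susp.get("taller_than_wide", False)),
        suspicious_marked_hypoechoic=bool(susp.get("markedly_hypoechoic", False)),
        fna_thresholds=thresholds,
        ordinal_ranks={str(k): int(v) for k, v in data["ordinal_ranks"].items()},
        macro_risk={str(k): MacroRisk(v) for k, v in data["macro_risk"].items()},
        sparing_excluded_classes=frozenset(
            str(c) for c in data.get("sparing_excluded_classes", [])),
        checksum=hashlib.sha256(raw).hexdigest(),
        points={k: {str(t): int(p) for t, p in v.items()}
                for k, v in data["points"].items()} if "points" in data else None,
        max_points=int(data["max_points"]) if "max_points" in data else None,
        class_bands=bands,
    )


class RuleSet:
    """All five systems' rule tables; loaded once from package data."""

    def __init__(self, rules: dict[NusSystem, SystemRules]):
        self._rules = rules

    def __getitem__(self, system: NusSystem) -> SystemRules:
        return self._rules[system]

    @property
    def checksums(self) -> dict[str, str]:
        return {s.value: r.checksum for s, r in self._rules.items()}

    @property
    def versions(self) -> dict[str, str]:
        return {s.value: r.version for s, r in self._rules.items()}

    @staticmethod
    @lru_cache(maxsize=1)
    def default() -> "RuleSet":
        return RuleSet({s: _load_system_rules(s) for s in NusSystem})


@dataclass(frozen=True)
class NusAssignment:
    """One scoring system's verdict for a nodule."""

    system: NusSystem
    class_label: str
    ordinal_rank: Optional[int]
    fna_indicated: Optional[bool]
    acr_points: Optional[int] = None

    @property
    def is_classifiable(self) -> bool:
        return self.class_label != UNCLASSIFIABLE


def _require_complete(features: UltrasoundFeatures) -> None:
    if not features.is_complete:
        raise ValueError("classification requires a complete ultrasound description")


def _make(system: NusSystem, label: str, features: UltrasoundFeatures,
          ruleset: RuleSet, acr_points: Optional[int] = None) -> NusAssignment:
    if label == UNCLASSIFIABLE:
        return NusAssignment(system=system, class_label=label,
                             ordinal_rank=None, fna_indicated=None,
                             acr_points=acr_points)
    rules = ruleset[system]
    return NusAssignment(
        system=system,
        class_label=label,
        ordinal_rank=rules.ordinal_ranks[label],
        fna_indicated=fna_indicated(system, label, features.max_diameter_mm, ruleset),
        acr_points=acr_points,
    )


# ---------------------------------------------------------------------------
# Per-system classifiers
# ---------------------------------------------------------------------------

def classify_ktirads(features: UltrasoundFeatures,
                     ruleset: Optional[RuleSet] = None) -> NusAssignment:
    """K-TIRADS: composition/echogenicity lattice with three suspicious
    features (microcalcifications, nonparallel orientation, irregular or
    lobulated margins, plus extrathyroidal extension)."""
    _require_complete(features)
    ruleset = ruleset or RuleSet.default()
    rules = ruleset[NusSystem.KTIRADS]
    hypo = features.echogenicity in _HYPOECHOIC_GROUP
    solid = features.composition is Composition.SOLID
    if rules.is_suspicious(features):
        label = "5" if (solid and hypo) else "4"
    elif features.composition in (Composition.CYSTIC, Composition.SPONGIFORM):
        label = "2"
    elif not solid or not hypo:
        # partially cystic, or iso-/hyperechoic solid, without suspicious features
        label = "3"
    else:
        label = "4"  # solid hypoechoic without suspicious features
    return _make(NusSystem.KTIRADS, label, features, ruleset)


def classify_ata(features: UltrasoundFeatures,
                 ruleset: Optional[RuleSet] = None) -> NusAssignment:
    """ATA sonographic patterns; partial by design (see module docstring)."""
    _require_complete(features)
    ruleset = ruleset or RuleSet.default()
    rules = ruleset[NusSystem.ATA]
    hypo = features.echogenicity in _HYPOECHOIC_GROUP
    comp = features.composition
    if rules.is_suspicious(features):
        # High suspicion requires a hypoechoic solid nodule or hypoechoic
        # solid component; suspicious features on any other pattern match
        # no official class.
        if hypo and comp in (Composition.SOLID, Composition.MIXED):
            label = "high"
        else:
            label = UNCLASSIFIABLE
    elif comp is Composition.CYSTIC:
        label = "benign"
    elif comp is Composition.SPONGIFORM:
        label = "very_low"
    elif comp is Composition.MIXED:
        if features.solid_portion_eccentric is None:
            label = UNCLASSIFIABLE  # doubtful eccentric solid portion
        elif features.solid_portion_eccentric:
            label = "low"  # partially cystic with eccentric solid areas
        else:
            label = "very_low"
    else:  # solid
        label = "intermediate" if hypo else "low"
    return _make(NusSystem.ATA, label, features, ruleset)


def classify_aace(features: UltrasoundFeatures,
                  ruleset: Optional[RuleSet] = None) -> NusAssignment:
    """AACE/ACE-AME three-class system: high needs at least one high-risk
    feature; low covers cystic/spongiform patterns; everything else is
    intermediate."""
    _require_complete(features)
    ruleset = ruleset or RuleSet.default()
    rules = ruleset[NusSystem.AACE_ACE_AME]
    if rules.is_suspicious(features):
        label = "high"
    elif features.composition in (Composition.CYSTIC, Composition.SPONGIFORM):
        label = "low"
    else:
        label = "intermediate"
    return _make(NusSystem.AACE_ACE_AME, label, features, ruleset)


def classify_eutirads(features: UltrasoundFeatures,
                      ruleset: Optional[RuleSet] = None) -> NusAssignment:
    """EU-TIRADS: class 5 for any high-risk feature (marked hypoechogenicity,
    non-oval shape, irregular margins, microcalcifications); class 2 for
    benign patterns; mild hypoechogenicity separates 4 from 3."""
    _require_complete(features)
    ruleset = ruleset or RuleSet.default()
    rules = ruleset[NusSystem.EUTIRADS]
    if rules.is_suspicious(features):
        label = "5"
    elif features.composition in (Composition.CYSTIC, Composition.SPONGIFORM):
        label = "2"
    elif features.echogenicity in (Echogenicity.SLIGHTLY_HYPOECHOIC,
                                   Echogenicity.HYPOECHOIC):
        label = "4"
    else:
        label = "3"
    return _make(NusSystem.EUTIRADS, label, features, ruleset)


def classify_acr(features: UltrasoundFeatures,
                 ruleset: Optional[RuleSet] = None) -> NusAssignment:
    """ACR TI-RADS additive point system (0-14), banded into TR1-TR5."""
    _require_complete(features)
    ruleset = ruleset or RuleSet.default()
    rules = ruleset[NusSystem.ACRTIRADS]
    assert rules.points is not None and rules.class_bands is not None
    pts = rules.points["composition"][features.composition.value]
    pts += rules.points["echogenicity"][features.echogenicity.value]
    pts += rules.points["shape"][
        "taller_than_wide" if features.taller_than_wide else "wider_than_tall"]
    pts += rules.points["margins"][features.margins.value]
    assert features.echogenic_foci is not None
    pts += sum(rules.points["echogenic_foci"][x.value] for x in features.echogenic_foci)
    pts = min(pts, rules.max_points or pts)
    label = next(c for c, lo, hi in rules.class_bands if lo <= pts <= hi)
    return _make(NusSystem.ACRTIRADS, label, features, ruleset, acr_points=pts)


_CLASSIFIERS = {
    NusSystem.KTIRADS: classify_ktirads,
    NusSystem.ATA: classify_ata,
    NusSystem.AACE_ACE_AME: classify_aace,
    NusSystem.EUTIRADS: classify_eutirads,
    NusSystem.ACRTIRADS: classify_acr,
}


def classify(features: UltrasoundFeatures, system: NusSystem,
             ruleset: Optional[RuleSet] = None) -> NusAssignment:
    return _CLASSIFIERS[system](features, ruleset)


def classify_all(features: UltrasoundFeatures,
                 ruleset: Optional[RuleSet] = None) -> dict[NusSystem, NusAssignment]:
    return {s: classify(features, s, ruleset) for s in NusSystem}


# ---------------------------------------------------------------------------
# Class-level lookups
# ---------------------------------------------------------------------------

def _check_classifiable(class_label: str, op: str) -> None:
    if class_label == UNCLASSIFIABLE:
        raise UnclassifiableError(f"{op} is undefined for the UNCLASSIFIABLE sentinel")


def fna_indicated(system: NusSystem, class_label: str, max_diameter_mm: float,
                  ruleset: Optional[RuleSet] = None) -> bool:
    """Whether the system recommends FNA for this class at this size.

    Threshold strictness is per-entry: for example EU-TIRADS 3 requires a
    diameter strictly above 20 mm, while K-TIRADS 3 includes 15 mm exactly.
    Classes with no threshold entry never indicate FNA.
    """
    _check_classifiable(class_label, "fna_indicated")
    rules = (ruleset or RuleSet.default())[system]
    if class_label not in rules.fna_thresholds:
        raise KeyError(f"unknown {system.value} class {class_label!r}")
    threshold = rules.fna_thresholds[class_label]
    if threshold is None:
        return False
    return threshold.indicated(max_diameter_mm)


def macro_group(system: NusSystem, class_label: str,
                ruleset: Optional[RuleSet] = None) -> MacroRisk:
    """Map a system class to the pooled macro-risk group."""
    _check_classifiable(class_label, "macro_group")
    return (ruleset or RuleSet.default())[system].macro_risk[class_label]


def ordinal_rank(system: NusSystem, class_label: str,
                 ruleset: Optional[RuleSet] = None) -> int:
    """Increasing-risk rank used as the ROC score."""
    _check_classifiable(class_label, "ordinal_rank")
    return (ruleset or RuleSet.default())[system].ordinal_ranks[class_label]
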