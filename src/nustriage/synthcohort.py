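"""Synthetic-cohort generation and packaged printed-count fixtures.

No patient-level data from the source cohort is available, so the package
ships two substitutes:

* a seeded generator that emulates the statistical structure the analysis
  assumes — a mixture of sonographic *archetypes* (feature bundles that the
  five scoring systems classify differently), class-conditional positive-
  cytology probabilities, a truncated log-normal size distribution on
  [10 mm, inf), and a cytology-noise layer producing the Thy/TIR category
  stream the dichotomization rule consumes;
* the printed per-class counts of the study's histology and FNA tables,
  expandable into a count-weighted pseudo-cohort for the metrics module
  (the central fixture regression).

The cytology model is deliberately clean: benign-truth nodules always draw a
negative category (TIR2, confirmed TIR3A pair, or pre-2014 Thy2) and
malignant-truth nodules always a positive one (TIR3B/Thy3 with the
indeterminate probability, otherwise TIR4/TIR5), so an archetype's
positive-cytology rate equals its ``malignancy_prob`` exactly and the
default calibration is closed-form.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy import stats

from .classifiers import NusSystem, RuleSet, UNCLASSIFIABLE, classify_ktirads
from .domain import (
    Composition,
    CytologyEra,
    CytologyResult,
    CytologySystem,
    Echogenicity,
    EchogenicFocus,
    Halo,
    HistologyLabel,
    Margins,
    NoduleRecord,
    UltrasoundFeatures,
    Vascularization,
)
from .metrics import SystemObservations

MIN_SIZE_MM = 10.0


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

class Archetype(BaseModel):
    """A sonographic phenotype with a fixed descriptive feature bundle.

    Only features unused by every rule table (halo, vascularization) are
    jittered at sampling time, so an archetype's class under each scoring
    system is deterministic.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    composition: Composition
    solid_portion_eccentric: Optional[bool] = None
    echogenicity: Echogenicity
    margins: Margins
    taller_than_wide: bool
    echogenic_foci: tuple[EchogenicFocus, ...]
    malignancy_prob: float
    size_median_mm: float = 20.0
    size_sigma_log: float = 0.40

    @field_validator("malignancy_prob")
    @classmethod
    def _prob(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("malignancy_prob must be in [0, 1]")
        return v

    def template_features(self, diameters=(20.0, 15.0, 12.0)) -> UltrasoundFeatures:
        return UltrasoundFeatures(
            composition=self.composition,
            solid_portion_eccentric=self.solid_portion_eccentric,
            echogenicity=self.echogenicity,
            halo=Halo.ABSENT,
            margins=self.margins,
            taller_than_wide=self.taller_than_wide,
            echogenic_foci=frozenset(self.echogenic_foci),
            vascularization=Vascularization.ABSENT,
            diameters_mm=diameters,
        )


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_nodules: int
    seed: int
    archetypes: tuple[Archetype, ...]
    archetype_weights: tuple[float, ...]
    #: P(low-risk indeterminate TIR3A, confirmed pair | benign, post-2014 era)
    indeterminate_given_benign: float = 0.13
    #: P(high-risk indeterminate TIR3B or pre-2014 Thy3 | malignant)
    indeterminate_given_malignant: float = 0.72
    #: share of nodules whose cytology predates May 2014 (BTA Thy categories)
    era_pre2014_frac: float = 0.5
    #: P(TIR4 | malignant and not indeterminate); remainder is TIR5
    tir4_frac_of_severe: float = 0.648
    histology_mix: dict[HistologyLabel, float] = None  # type: ignore[assignment]

    @model_validator(mode="before")
    @classmethod
    def _default_histology(cls, data):
        if isinstance(data, dict) and data.get("histology_mix") is None:
            data["histology_mix"] = default_histology_mix()
        return data

    @model_validator(mode="after")
    def _validate(self):
        if len(self.archetypes) != len(self.archetype_weights):
            raise ValueError("one weight per archetype required")
        for w in self.archetype_weights:
            if w < 0:
                raise ValueError("weights must be non-negative")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ValueError("archetype weights must sum to 1")
        if abs(sum(self.histology_mix.values()) - 1.0) > 1e-9:
            raise ValueError("histology mix must sum to 1")
        for p in (self.indeterminate_given_benign, self.indeterminate_given_malignant,
                  self.era_pre2014_frac, self.tir4_frac_of_severe):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

class TableFixture:
    """The printed per-class counts of the study's tables."""

    def __init__(self, data: dict):
        self._data = data

    @property
    def histology_counts(self) -> dict[HistologyLabel, int]:
        return {HistologyLabel(k): v
                for k, v in self._data["table1_histology"]["counts"].items()}

    @property
    def histology_total(self) -> int:
        return int(self._data["table1_histology"]["total"])

    @property
    def flags(self) -> list[str]:
        return list(self._data["flags"])

    def system_table(self, system: NusSystem) -> dict:
        return self._data["table2"][system.value]

    def printed_totals(self, system: NusSystem) -> dict[str, int]:
        return dict(self._data["table2"][system.value]["printed_totals"])

    def expand_observations(self, system: NusSystem,
                            ruleset: Optional[RuleSet] = None) -> SystemObservations:
        """Count-weighted pseudo-cohort for one system.

        Expected-FNA counts become indicated observations; spared
        observations are observed minus expected, componentwise (the
        arithmetic consistent with every printed system total). ATA
        unclassifiable nodules populate the pseudo-class bucket.
        """
        rules = (ruleset or RuleSet.default())[system]
        obs = SystemObservations(system=system)
        tab = self.system_table(system)
        for cls, row in tab["classes"].items():
            rank = rules.ordinal_ranks[cls]
            for outcome_key, positive in (("neg", False), ("pos", True)):
                n_exp = row["expected"][outcome_key]
                n_obs = row["observed"][outcome_key]
                if n_obs < n_exp:
                    raise ValueError(f"{system.value} {cls}: observed < expected")
                for _ in range(n_exp):
                    obs.add(cls, positive, True, rank)
                for _ in range(n_obs - n_exp):
                    obs.add(cls, positive, False, rank)
        unc = tab.get("unclassifiable")
        if unc:
            n_pos = int(unc["n_positive_reconstructed"])
            obs.unclassifiable_outcomes.extend([True] * n_pos)
            obs.unclassifiable_outcomes.extend([False] * (int(unc["n"]) - n_pos))
        return obs


@lru_cache(maxsize=1)
def table_fixture() -> TableFixture:
    raw = (resources.files("nustriage.fixtures") / "tables.json").read_text()
    return TableFixture(json.loads(raw))


def default_histology_mix() -> dict[HistologyLabel, float]:
    """Histology label proportions from the printed surgical-series counts."""
    fx = table_fixture()
    total = fx.histology_total
    return {k: v / total for k, v in fx.histology_counts.items()}


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def histology_sampler(rng: np.random.Generator,
                      mix: Optional[dict[HistologyLabel, float]] = None) -> HistologyLabel:
    """Categorical draw of a surgical histology label."""
    mix = mix if mix is not None else default_histology_mix()
    if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("histology mix must be a simplex")
    labels = list(mix.keys())
    probs = np.array([mix[k] for k in labels])
    return labels[rng.choice(len(labels), p=probs)]


def _truncated_lognormal(rng: np.random.Generator, median_mm: float,
                         sigma: float, n: int) -> np.ndarray:
    """Log-normal sizes truncated at >= 10 mm by inverse-CDF sampling."""
    mu = np.log(median_mm)
    lo = stats.norm.cdf((np.log(MIN_SIZE_MM) - mu) / sigma)
    u = lo + (1.0 - lo) * rng.random(n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _draw_cytology(rng: np.random.Generator, malignant: bool, pre2014: bool,
                   cfg: SimulationConfig) -> tuple[CytologyResult, ...]:
    if pre2014:
        def bta(cat):
            return CytologyResult(system=CytologySystem.BTA, category=cat,
                                  era=CytologyEra.PRE2014)
        if not malignant:
            return (bta("Thy2"),)
        if rng.random() < cfg.indeterminate_given_malignant:
            return (bta("Thy3"),)
        return (bta("Thy4" if rng.random() < cfg.tir4_frac_of_severe else "Thy5"),)

    def tir(cat):
        return CytologyResult(system=CytologySystem.SIAPEC, category=cat,
                              era=CytologyEra.POST2014)
    if not malignant:
        if rng.random() < cfg.indeterminate_given_benign:
            return (tir("TIR3A"), tir("TIR3A"))  # confirmed low-risk indeterminate
        return (tir("TIR2"),)
    if rng.random() < cfg.indeterminate_given_malignant:
        return (tir("TIR3B"),)
    return (tir("TIR4" if rng.random() < cfg.tir4_frac_of_severe else "TIR5"),)


def generate_cohort(config: SimulationConfig) -> list[NoduleRecord]:
    """Draw a fully reproducible synthetic FNA cohort.

    Independent sub-streams (derived from the seed by fixed offsets) drive
    archetype choice, sizes, demographics, cytology and histology, so adding
    a sampling stage never perturbs earlier draws.
    """
    rng_arch = np.random.default_rng([1, config.seed])
    rng_size = np.random.default_rng([2, config.seed])
    rng_demo = np.random.default_rng([3, config.seed])
    rng_cyto = np.random.default_rng([4, config.seed])
    rng_hist = np.random.default_rng([5, config.seed])

    weights = np.asarray(config.archetype_weights)
    # re-validated here because pydantic copies with update skip validation
    if len(weights) != len(config.archetypes) or weights.min() < 0 \
            or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("archetype weights must form a simplex")
    n = config.n_nodules
    if n == 0:
        return []
    arch_idx = rng_arch.choice(len(config.archetypes), size=n, p=weights)
    records: list[NoduleRecord] = []
    for i in range(n):
        arch = config.archetypes[arch_idx[i]]
        d1 = float(_truncated_lognormal(rng_size, arch.size_median_mm,
                                        arch.size_sigma_log, 1)[0])
        f2 = rng_size.uniform(0.6, 0.95)
        f3 = rng_size.uniform(0.4, f2)
        halo = Halo.PRESENT if rng_demo.random() < 0.3 else Halo.ABSENT
        vasc = list(Vascularization)[rng_demo.choice(3)]
        sex = "F" if rng_demo.random() < 0.78 else "M"
        age = float(np.clip(rng_demo.normal(55.0, 14.0), 18.0, 90.0))
        pre = rng_cyto.random() < config.era_pre2014_frac
        malignant = rng_cyto.random() < arch.malignancy_prob
        history = _draw_cytology(rng_cyto, malignant, pre, config)
        histology = histology_sampler(rng_hist, config.histology_mix) \
            if malignant else None
        features = UltrasoundFeatures(
            composition=arch.composition,
            solid_portion_eccentric=arch.solid_portion_eccentric,
            echogenicity=arch.echogenicity,
            halo=halo,
            margins=arch.margins,
            taller_than_wide=arch.taller_than_wide,
            echogenic_foci=frozenset(arch.echogenic_foci),
            vascularization=vasc,
            diameters_mm=(d1, d1 * f2, d1 * f3),
        )
        records.append(NoduleRecord(
            nodule_id=f"N{i:05d}",
            patient_id=f"P{i:05d}",
            features=features,
            cytology_history=history,
            fna_performed=True,
            histology=histology,
            sex=sex,
            age_years=round(age, 1),
        ))
    return records


# ---------------------------------------------------------------------------
# Default calibration
# ---------------------------------------------------------------------------

#: within-K-TIRADS-class mixture of archetypes (chosen once; the doubtful
#: mixed and isoechoic-with-microcalcifications shares make the emergent
#: ATA-unclassifiable fraction come out near the study's 7%).
_WITHIN_CLASS_SPLITS: dict[str, dict[str, float]] = {
    "2": {"pure_cyst": 0.45, "spongiform": 0.55},
    "3": {"mixed_eccentric": 0.40, "mixed_doubtful": 0.09, "iso_solid_smooth": 0.51},
    "4": {"iso_solid_microcalc": 0.075, "hypo_solid_plain": 0.925},
    "5": {"hypo_solid_suspicious": 0.75, "markedly_hypo_ttw": 0.25},
}


def _archetype_bundle(name, composition, echogenicity, margins=Margins.SMOOTH,
                      taller=False, foci=(EchogenicFocus.NONE,), eccentric=None,
                      p=0.1, median=20.0):
    return Archetype(
        name=name, composition=composition, solid_portion_eccentric=eccentric,
        echogenicity=echogenicity, margins=margins, taller_than_wide=taller,
        echogenic_foci=tuple(foci), malignancy_prob=p, size_median_mm=median,
    )


def default_archetypes() -> list[Archetype]:
    """Eight phenotypes spanning the benign-to-suspicious spectrum."""
    return [
        _archetype_bundle("pure_cyst", Composition.CYSTIC, Echogenicity.ANECHOIC,
                          median=24.0),
        _archetype_bundle("spongiform", Composition.SPONGIFORM, Echogenicity.ISOECHOIC,
                          median=22.0),
        _archetype_bundle("mixed_eccentric", Composition.MIXED, Echogenicity.ISOECHOIC,
                          eccentric=True, median=22.0),
        _archetype_bundle("mixed_doubtful", Composition.MIXED, Echogenicity.ISOECHOIC,
                          eccentric=None, median=22.0),
        _archetype_bundle("iso_solid_smooth", Composition.SOLID, Echogenicity.ISOECHOIC,
                          median=20.0),
        _archetype_bundle("iso_solid_microcalc", Composition.SOLID,
                          Echogenicity.ISOECHOIC,
                          foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,),
                          median=18.0),
        _archetype_bundle("hypo_solid_plain", Composition.SOLID,
                          Echogenicity.HYPOECHOIC, median=18.0),
        _archetype_bundle("hypo_solid_suspicious", Composition.SOLID,
                          Echogenicity.HYPOECHOIC,
                          margins=Margins.IRREGULAR_OR_BLURRED,
                          foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,),
                          median=16.0),
        _archetype_bundle("markedly_hypo_ttw", Composition.SOLID,
                          Echogenicity.MARKEDLY_HYPOECHOIC, taller=True,
                          foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,),
                          median=15.0),
    ]


def default_calibration(n_nodules: int = 6474, seed: int = 20140501) -> SimulationConfig:
    """Archetype mixture calibrated to the study's K-TIRADS margins.

    Each archetype's K-TIRADS class is computed by classifying its template;
    archetype weights are the printed observed K-TIRADS class shares split
    within class by fixed proportions, and each archetype's malignancy
    probability is its class's printed positive-cytology rate. Because the
    cytology-noise model maps truth to outcome one-to-one, the generated
    per-class positive rates match the targets in expectation exactly;
    marginals of the other four systems are emergent, not forced.
    """
    fx = table_fixture()
    tab = fx.system_table(NusSystem.KTIRADS)["classes"]
    observed = {cls: row["observed"]["neg"] + row["observed"]["pos"]
                for cls, row in tab.items()}
    total = sum(observed.values())
    rates = {cls: row["observed"]["pos"] / observed[cls] for cls, row in tab.items()}

    archetypes = []
    weights = []
    for arch in default_archetypes():
        kt_class = classify_ktirads(arch.template_features()).class_label
        split = _WITHIN_CLASS_SPLITS[kt_class]
        if arch.name not in split:
            continue
        archetypes.append(arch.model_copy(update={"malignancy_prob": rates[kt_class]}))
        weights.append(observed[kt_class] / total * split[arch.name])
    weights = [w / sum(weights) for w in weights]
    return SimulationConfig(
        n_nodules=n_nodules, seed=seed,
        archetypes=tuple(archetypes), archetype_weights=tuple(weights),
    )
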