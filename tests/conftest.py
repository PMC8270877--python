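import itertools

import pytest

from nustriage.domain import (
    Composition,
    CytologyEra,
    CytologyResult,
    CytologySystem,
    Echogenicity,
    EchogenicFocus,
    Halo,
    Margins,
    NoduleRecord,
    UltrasoundFeatures,
    Vascularization,
)


def make_features(
    composition=Composition.SOLID,
    echogenicity=Echogenicity.ISOECHOIC,
    margins=Margins.SMOOTH,
    taller_than_wide=False,
    foci=(EchogenicFocus.NONE,),
    eccentric=None,
    halo=Halo.ABSENT,
    vascularization=Vascularization.ABSENT,
    diameters=(20.0, 15.0, 12.0),
) -> UltrasoundFeatures:
    return UltrasoundFeatures(
        composition=composition,
        solid_portion_eccentric=eccentric,
        echogenicity=echogenicity,
        halo=halo,
        margins=margins,
        taller_than_wide=taller_than_wide,
        echogenic_foci=frozenset(foci),
        vascularization=vascularization,
        diameters_mm=diameters,
    )


def tir(category: str) -> CytologyResult:
    return CytologyResult(system=CytologySystem.SIAPEC, category=category,
                          era=CytologyEra.POST2014)


def thy(category: str) -> CytologyResult:
    return CytologyResult(system=CytologySystem.BTA, category=category,
                          era=CytologyEra.PRE2014)


def make_record(nodule_id="N1", features=None, history=(("TIR2", "post"),),
                **kwargs) -> NoduleRecord:
    cyto = tuple(tir(c) if era == "post" else thy(c) for c, era in history)
    return NoduleRecord(
        nodule_id=nodule_id, patient_id=f"P-{nodule_id}",
        features=features or make_features(),
        cytology_history=cyto, fna_performed=bool(cyto), **kwargs)


def enumerate_feature_lattice():
    """Every valid complete feature bundle (halo/vascularization fixed: no
    rule table scores them). Small enough for exhaustive audits."""
    real_foci = [f for f in EchogenicFocus if f is not EchogenicFocus.NONE]
    foci_options = [frozenset({EchogenicFocus.NONE})]
    for r in range(1, len(real_foci) + 1):
        foci_options.extend(frozenset(c) for c in itertools.combinations(real_foci, r))
    bundles = []
    for comp in Composition:
        ecc_options = [None, True, False] if comp is Composition.MIXED else [None]
        for echo in Echogenicity:
            if echo is Echogenicity.ANECHOIC and comp not in (
                    Composition.CYSTIC, Composition.MIXED):
                continue
            for ecc, margins, ttw, foci in itertools.product(
                    ecc_options, Margins, (False, True), foci_options):
                bundles.append(make_features(
                    composition=comp, echogenicity=echo, margins=margins,
                    taller_than_wide=ttw, foci=foci, eccentric=ecc))
    return bundles


@pytest.fixture(scope="session")
def feature_lattice():
    return enumerate_feature_lattice()
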