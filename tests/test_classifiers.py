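"""The five scoring systems: worked examples and exhaustive lattice audits."""

import pytest

from nustriage.classifiers import (
    MacroRisk,
    NusSystem,
    RuleSet,
    UNCLASSIFIABLE,
    UnclassifiableError,
    classify,
    classify_aace,
    classify_acr,
    classify_all,
    classify_ata,
    classify_eutirads,
    classify_ktirads,
    fna_indicated,
    macro_group,
    ordinal_rank,
)
from nustriage.domain import (
    Composition,
    Echogenicity,
    EchogenicFocus,
    Margins,
    UltrasoundFeatures,
)

from conftest import make_features

CYST = dict(composition=Composition.CYSTIC, echogenicity=Echogenicity.ANECHOIC)


class TestAcr:
    def test_pure_cyst_zero_points_tr1(self):
        a = classify_acr(make_features(**CYST))
        assert (a.acr_points, a.class_label) == (0, "TR1")

    def test_maximum_attainable_total_is_14(self):
        a = classify_acr(make_features(
            echogenicity=Echogenicity.MARKEDLY_HYPOECHOIC,
            margins=Margins.EXTRATHYROIDAL_EXTENSION, taller_than_wide=True,
            foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,)))
        assert (a.acr_points, a.class_label) == (14, "TR5")

    def test_hand_summed_example(self):
        # solid 2 + isoechoic 1 + wider 0 + smooth 0 + macrocalcification 1 = 4
        a = classify_acr(make_features(foci=(EchogenicFocus.MACROCALCIFICATION,)))
        assert (a.acr_points, a.class_label) == (4, "TR4")

    def test_foci_points_are_additive(self):
        a = classify_acr(make_features(foci=(
            EchogenicFocus.MACROCALCIFICATION,
            EchogenicFocus.MICROCALCIFICATION_PUNCTATE)))
        assert a.acr_points == 2 + 1 + 1 + 3  # composition+echo+macro+punctate

    def test_comet_tail_scores_zero(self):
        a = classify_acr(make_features(foci=(EchogenicFocus.HYPERECHOIC_SPOT_COMET,)))
        assert a.acr_points == 3  # solid 2 + isoechoic 1


class TestAta:
    def test_isoechoic_solid_with_microcalcifications_unclassifiable(self):
        a = classify_ata(make_features(
            foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,)))
        assert a.class_label == UNCLASSIFIABLE
        assert a.ordinal_rank is None and a.fna_indicated is None

    def test_isoechoic_solid_irregular_margins_unclassifiable(self):
        a = classify_ata(make_features(margins=Margins.IRREGULAR_OR_BLURRED))
        assert a.class_label == UNCLASSIFIABLE

    def test_mixed_doubtful_eccentric_unclassifiable(self):
        a = classify_ata(make_features(composition=Composition.MIXED, eccentric=None))
        assert a.class_label == UNCLASSIFIABLE

    def test_pure_cyst_benign(self):
        assert classify_ata(make_features(**CYST)).class_label == "benign"

    def test_hypoechoic_solid_irregular_margins_high(self):
        a = classify_ata(make_features(echogenicity=Echogenicity.HYPOECHOIC,
                                       margins=Margins.IRREGULAR_OR_BLURRED))
        assert a.class_label == "high"

    @pytest.mark.parametrize("eccentric,expected", [(True, "low"), (False, "very_low")])
    def test_mixed_patterns(self, eccentric, expected):
        a = classify_ata(make_features(composition=Composition.MIXED,
                                       eccentric=eccentric))
        assert a.class_label == expected


class TestAace:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(composition=Composition.SPONGIFORM), "low"),
        (dict(), "intermediate"),
        (dict(foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,)), "high"),
        (dict(echogenicity=Echogenicity.MARKEDLY_HYPOECHOIC), "high"),
    ])
    def test_patterns(self, kwargs, expected):
        assert classify_aace(make_features(**kwargs)).class_label == expected


class TestEutirads:
    @pytest.mark.parametrize("kwargs,expected", [
        (CYST, "2"),
        (dict(), "3"),
        (dict(echogenicity=Echogenicity.SLIGHTLY_HYPOECHOIC), "4"),
        (dict(echogenicity=Echogenicity.HYPOECHOIC, taller_than_wide=True), "5"),
        (dict(echogenicity=Echogenicity.MARKEDLY_HYPOECHOIC), "5"),
    ])
    def test_patterns(self, kwargs, expected):
        assert classify_eutirads(make_features(**kwargs)).class_label == expected


class TestKtirads:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(composition=Composition.SPONGIFORM), "2"),
        (CYST, "2"),
        (dict(composition=Composition.MIXED, eccentric=True), "3"),
        (dict(), "3"),
        (dict(echogenicity=Echogenicity.HYPOECHOIC), "4"),
        (dict(echogenicity=Echogenicity.HYPOECHOIC,
              foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,)), "5"),
        (dict(foci=(EchogenicFocus.MICROCALCIFICATION_PUNCTATE,)), "4"),
    ])
    def test_patterns(self, kwargs, expected):
        assert classify_ktirads(make_features(**kwargs)).class_label == expected


class TestFnaIndication:
    @pytest.mark.parametrize("system,cls,diam,expected", [
        (NusSystem.KTIRADS, "3", 15.0, True),
        (NusSystem.KTIRADS, "2", 19.9, False),
        (NusSystem.ACRTIRADS, "TR3", 24.0, False),
        (NusSystem.ACRTIRADS, "TR3", 25.0, True),
        (NusSystem.EUTIRADS, "2", 50.0, False),   # benign class never indicates
        (NusSystem.EUTIRADS, "3", 20.0, False),   # strict > 20
        (NusSystem.EUTIRADS, "3", 20.1, True),
        (NusSystem.AACE_ACE_AME, "low", 20.0, False),  # strict > 20
        (NusSystem.AACE_ACE_AME, "high", 10.0, True),
        (NusSystem.ATA, "benign", 60.0, False),
        (NusSystem.ATA, "very_low", 20.0, True),
    ])
    def test_threshold_strictness(self, system, cls, diam, expected):
        assert fna_indicated(system, cls, diam) is expected

    def test_unclassifiable_is_hard_error(self):
        with pytest.raises(UnclassifiableError):
            fna_indicated(NusSystem.ATA, UNCLASSIFIABLE, 20.0)
        with pytest.raises(UnclassifiableError):
            macro_group(NusSystem.ATA, UNCLASSIFIABLE)
        with pytest.raises(UnclassifiableError):
            ordinal_rank(NusSystem.ATA, UNCLASSIFIABLE)

    def test_monotone_in_diameter_and_rank(self):
        ruleset = RuleSet.default()
        diameters = [10.0, 12.5, 15.0, 20.0, 20.5, 25.0, 40.0]
        for system in NusSystem:
            rules = ruleset[system]
            ordered = sorted(rules.classes, key=lambda c: rules.ordinal_ranks[c])
            for cls in ordered:
                flags = [fna_indicated(system, cls, d) for d in diameters]
                assert flags == sorted(flags)  # monotone in diameter
            at25 = [fna_indicated(system, cls, 25.0) for cls in ordered]
            assert at25 == sorted(at25)  # monotone in rank at >= 25 mm


class TestMacroAndRanks:
    @pytest.mark.parametrize("system,cls,expected", [
        (NusSystem.KTIRADS, "4", MacroRisk.HIGH),
        (NusSystem.EUTIRADS, "3", MacroRisk.LOW),
        (NusSystem.ACRTIRADS, "TR4", MacroRisk.INTERMEDIATE),
        (NusSystem.ATA, "very_low", MacroRisk.LOW),
        (NusSystem.AACE_ACE_AME, "intermediate", MacroRisk.INTERMEDIATE),
    ])
    def test_macro_map(self, system, cls, expected):
        assert macro_group(system, cls) is expected

    @pytest.mark.parametrize("system,cls,expected", [
        (NusSystem.AACE_ACE_AME, "high", 3),
        (NusSystem.KTIRADS, "2", 1),
        (NusSystem.KTIRADS, "5", 4),
        (NusSystem.ATA, "high", 5),
        (NusSystem.EUTIRADS, "5", 4),
        (NusSystem.ACRTIRADS, "TR1", 1),
        (NusSystem.ACRTIRADS, "TR5", 5),
    ])
    def test_ordinal_ranks(self, system, cls, expected):
        assert ordinal_rank(system, cls) == expected

    def test_rank_ranges_match_class_counts(self):
        ruleset = RuleSet.default()
        for system, top in [(NusSystem.AACE_ACE_AME, 3), (NusSystem.KTIRADS, 4),
                            (NusSystem.EUTIRADS, 4), (NusSystem.ATA, 5),
                            (NusSystem.ACRTIRADS, 5)]:
            ranks = sorted(ruleset[system].ordinal_ranks.values())
            assert ranks == list(range(1, top + 1))


# ---------------------------------------------------------------------------
# Exhaustive feature-lattice audits
# ---------------------------------------------------------------------------

SUSPICIOUS_TRIO = (EchogenicFocus.MICROCALCIFICATION_PUNCTATE,)


def _has_macro_low_blocker(f: UltrasoundFeatures) -> bool:
    return (f.has_focus(EchogenicFocus.MICROCALCIFICATION_PUNCTATE)
            or bool(f.taller_than_wide)
            or f.margins is Margins.EXTRATHYROIDAL_EXTENSION)


class TestLatticeAudits:
    def test_total_functions_except_ata(self, feature_lattice):
        ruleset = RuleSet.default()
        for f in feature_lattice:
            for system in NusSystem:
                a = classify(f, system, ruleset)
                if system is NusSystem.ATA:
                    assert a.class_label in ruleset[system].classes + (UNCLASSIFIABLE,)
                else:
                    assert a.class_label in ruleset[system].classes

    def test_ata_unclassifiable_covers_quoted_patterns(self, feature_lattice):
        unc = {id(f): f for f in feature_lattice
               if classify_ata(f).class_label == UNCLASSIFIABLE}
        assert any(f.composition is Composition.SOLID
                   and f.echogenicity is Echogenicity.ISOECHOIC
                   and f.has_focus(EchogenicFocus.MICROCALCIFICATION_PUNCTATE)
                   for f in unc.values())
        assert any(f.composition is Composition.MIXED
                   and f.solid_portion_eccentric is None
                   for f in unc.values())

    def test_no_suspicious_bundle_lands_in_macro_low(self, feature_lattice):
        ruleset = RuleSet.default()
        for f in feature_lattice:
            if not _has_macro_low_blocker(f):
                continue
            for system, a in classify_all(f, ruleset).items():
                if not a.is_classifiable:
                    continue
                assert macro_group(system, a.class_label, ruleset) is not MacroRisk.LOW, \
                    (system, a.class_label, f)

    def test_acr_points_bounded_and_class_monotone_in_points(self, feature_lattice):
        seen = {}
        for f in feature_lattice:
            a = classify_acr(f)
            assert 0 <= a.acr_points <= 14
            seen.setdefault(a.acr_points, set()).add(a.class_label)
        # each point total maps to exactly one class, ordered by points
        order = ["TR1", "TR2", "TR3", "TR4", "TR5"]
        last = 0
        for pts in sorted(seen):
            (cls,) = seen[pts]
            assert order.index(cls) >= last
            last = order.index(cls)

    def test_acr_single_feature_upgrade_never_decreases_points(self, feature_lattice):
        echo_ladder = [Echogenicity.ANECHOIC, Echogenicity.HYPERECHOIC,
                       Echogenicity.ISOECHOIC, Echogenicity.SLIGHTLY_HYPOECHOIC,
                       Echogenicity.HYPOECHOIC, Echogenicity.MARKEDLY_HYPOECHOIC]
        margin_ladder = [Margins.SMOOTH, Margins.LOBULATED,
                         Margins.IRREGULAR_OR_BLURRED,
                         Margins.EXTRATHYROIDAL_EXTENSION]
        comp_ladder = [Composition.CYSTIC, Composition.SPONGIFORM,
                       Composition.MIXED, Composition.SOLID]

        def upgrade(f: UltrasoundFeatures, **kw):
            data = dict(composition=f.composition,
                        solid_portion_eccentric=f.solid_portion_eccentric,
                        echogenicity=f.echogenicity, halo=f.halo,
                        margins=f.margins, taller_than_wide=f.taller_than_wide,
                        echogenic_foci=f.echogenic_foci,
                        vascularization=f.vascularization,
                        diameters_mm=f.diameters_mm)
            data.update(kw)
            if data["composition"] is not Composition.MIXED:
                data["solid_portion_eccentric"] = None
            try:
                return UltrasoundFeatures(**data)
            except ValueError:
                return None  # upgrade leaves the valid lattice; skip

        for f in feature_lattice:
            base = classify_acr(f).acr_points
            for ladder, field in [(echo_ladder, "echogenicity"),
                                  (margin_ladder, "margins"),
                                  (comp_ladder, "composition")]:
                i = ladder.index(getattr(f, field))
                if i + 1 < len(ladder):
                    g = upgrade(f, **{field: ladder[i + 1]})
                    if g is not None:
                        assert classify_acr(g).acr_points >= base
            if not f.taller_than_wide:
                g = upgrade(f, taller_than_wide=True)
                assert classify_acr(g).acr_points >= base
            if not f.has_focus(EchogenicFocus.MICROCALCIFICATION_PUNCTATE):
                foci = (f.echogenic_foci - {EchogenicFocus.NONE}) | \
                    {EchogenicFocus.MICROCALCIFICATION_PUNCTATE}
                g = upgrade(f, echogenic_foci=frozenset(foci))
                assert classify_acr(g).acr_points >= base

    def test_incomplete_features_rejected(self):
        incomplete = UltrasoundFeatures(diameters_mm=(15.0, 10.0, 8.0))
        for system in NusSystem:
            with pytest.raises(ValueError):
                classify(incomplete, system)


def test_rule_files_expose_versions_and_checksums():
    ruleset = RuleSet.default()
    assert set(ruleset.versions) == {s.value for s in NusSystem}
    assert all(len(c) == 64 for c in ruleset.checksums.values())
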