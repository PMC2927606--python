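"""Stage 2: the priority cascade, its variants, the oracle, and agreement."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aismarshall import (
    DEFAULT_CONFIG,
    EquivalentClass,
    EvacuationSemantics,
    MarshallClass,
    SelectorConfig,
    Subtag,
    UnclassifiedMode,
    ViiPosition,
    classify_record,
    cross_tabulate_assignments,
    oracle_select,
    select_marshall_class,
)

from conftest import AIS2005, record

EQ = EquivalentClass
MC = MarshallClass

SUBSTANTIVE = [EQ.PENETRATING, EQ.EQ_V_VI, EQ.EQ_IV, EQ.EQ_III, EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_II, EQ.EQ_I]
ALL_SUBSETS = [
    frozenset(c)
    for r in range(len(SUBSTANTIVE) + 1)
    for c in itertools.combinations(SUBSTANTIVE, r)
]
ALL_CONFIGS = SelectorConfig.all_variants()

subset_strategy = st.frozensets(st.sampled_from(SUBSTANTIVE), max_size=7)


class TestCascade:
    def test_worked_example_brainstem_plus_evacuated_mass_lesion(self):
        """Brain-stem/cerebellar injury + mass lesion with surgical evacuation -> VI."""
        a = select_marshall_class({EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_V_VI}, evacuated=True)
        assert a.final is MC.VI and a.fired_step == "mass_lesion_evacuated"

    def test_non_evacuated_mass_lesion_is_class_v(self):
        a = select_marshall_class({EQ.EQ_V_VI}, evacuated=False)
        assert a.final is MC.V

    def test_penetrating_stops_the_algorithm(self):
        """The Marshall system covers blunt injury: penetrating -> VIII, stop."""
        a = select_marshall_class({EQ.PENETRATING, EQ.EQ_IV}, evacuated=False)
        assert a.final is MC.VIII and a.fired_step == "penetrating"

    def test_single_class_sets(self):
        assert select_marshall_class({EQ.EQ_I}, False).final is MC.I
        assert select_marshall_class({EQ.EQ_II}, False).final is MC.II

    def test_higher_priority_class_wins(self):
        assert select_marshall_class({EQ.EQ_III, EQ.EQ_I}, False).final is MC.III

    def test_crush_forces_vi_without_evacuation(self):
        a = select_marshall_class({EQ.EQ_V_VI}, evacuated=False, crush_present=True)
        assert a.final is MC.VI and a.fired_step == "mass_lesion_crush"

    def test_empty_set_yields_sentinel_or_raises_in_strict(self):
        assert select_marshall_class(frozenset(), False).final is MC.NO_TBI
        with pytest.raises(ValueError):
            select_marshall_class(frozenset(), False, config=SelectorConfig(strict=True))

    def test_sentinel_labels_rejected(self):
        with pytest.raises(ValueError):
            select_marshall_class({EQ.UNMAPPED}, False)

    def test_evacuation_without_mass_lesion_warns(self):
        a = select_marshall_class({EQ.EQ_II}, evacuated=True)
        assert a.final is MC.II and any("ignored" in w for w in a.warnings)


class TestEvacuationSemantics:
    def test_table1_convention_swaps_v_and_vi(self):
        cfg = SelectorConfig(evacuation_semantics=EvacuationSemantics.MARSHALL_TABLE1)
        assert select_marshall_class({EQ.EQ_V_VI}, True, config=cfg).final is MC.V
        assert select_marshall_class({EQ.EQ_V_VI}, False, config=cfg).final is MC.VI

    def test_crush_forces_vi_under_both_conventions(self):
        for sem in EvacuationSemantics:
            cfg = SelectorConfig(evacuation_semantics=sem)
            for evac in (True, False):
                a = select_marshall_class({EQ.EQ_V_VI}, evac, crush_present=True, config=cfg)
                assert a.final is MC.VI


class TestViiPosition:
    def test_default_vii_sits_between_iii_and_ii(self):
        assert select_marshall_class({EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_II}, False).final is MC.VII
        assert select_marshall_class({EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_III}, False).final is MC.III

    def test_after_penetrating_outranks_mass_lesion(self):
        cfg = SelectorConfig(vii_position=ViiPosition.AFTER_PENETRATING)
        assert select_marshall_class({EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_V_VI}, True, config=cfg).final is MC.VII
        assert select_marshall_class({EQ.PENETRATING, EQ.BRAINSTEM_CEREBELLAR}, False, config=cfg).final is MC.VIII

    def test_before_class_i_is_outranked_by_ii(self):
        cfg = SelectorConfig(vii_position=ViiPosition.BEFORE_CLASS_I)
        assert select_marshall_class({EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_II}, False, config=cfg).final is MC.II
        assert select_marshall_class({EQ.BRAINSTEM_CEREBELLAR, EQ.EQ_I}, False, config=cfg).final is MC.VII

    def test_variant_sensitivity_confined_to_brainstem_sets(self):
        """Changing the VII slot only ever matters when the set contains the
        brain-stem/cerebellar label."""
        for classes in ALL_SUBSETS:
            if EQ.BRAINSTEM_CEREBELLAR in classes:
                continue
            per_evac = {
                evac: {
                    select_marshall_class(classes, evac, config=SelectorConfig(vii_position=vp)).final
                    for vp in ViiPosition
                }
                for evac in (True, False)
            }
            assert all(len(v) == 1 for v in per_evac.values()), classes


class TestUnclassifiedMode:
    def test_merged_relabels_both_extension_classes(self):
        cfg = SelectorConfig(unclassified_mode=UnclassifiedMode.MERGED)
        a = select_marshall_class({EQ.PENETRATING}, False, config=cfg)
        b = select_marshall_class({EQ.BRAINSTEM_CEREBELLAR}, False, config=cfg)
        assert (a.label, b.label) == ("unclassified", "unclassified")
        assert (a.final, b.final) == (MC.VIII, MC.VII)  # audit value unchanged
        c = select_marshall_class({EQ.EQ_II}, False, config=cfg)
        assert c.label == "II"

    def test_subtag_mode_reports_anatomy(self):
        cfg = SelectorConfig(unclassified_mode=UnclassifiedMode.SPLIT_SUBTAG)
        a = select_marshall_class(
            {EQ.BRAINSTEM_CEREBELLAR}, False, config=cfg, subtags={Subtag.BRAINSTEM}
        )
        assert a.label == "VII (brainstem)"
        b = select_marshall_class(
            {EQ.BRAINSTEM_CEREBELLAR}, False, config=cfg,
            subtags={Subtag.BRAINSTEM, Subtag.CEREBELLAR},
        )
        assert "brainstem" in b.label and "cerebellar" in b.label


class TestOracleEquivalence:
    @pytest.mark.parametrize("config", ALL_CONFIGS, ids=lambda c: (
        f"{c.vii_position.value}-{c.evacuation_semantics.value}-{c.unclassified_mode.value}"
    ))
    def test_exhaustive_agreement_with_independent_route(self, config):
        """Cascade == priority-order oracle on all 2^7 subsets x evacuation."""
        for classes in ALL_SUBSETS:
            for evac in (True, False):
                got = select_marshall_class(classes, evac, config=config).final
                want = oracle_select(classes, evac, config=config)
                assert got is want, (classes, evac)

    def test_agreement_with_crush_modifier(self):
        for config in ALL_CONFIGS:
            for classes in ALL_SUBSETS:
                if EQ.EQ_V_VI not in classes:
                    continue
                for evac in (True, False):
                    got = select_marshall_class(classes, evac, True, config).final
                    assert got is oracle_select(classes, evac, True, config)


class TestExhaustiveness:
    def test_every_nonempty_subset_yields_exactly_one_real_class(self):
        """Mutual exclusivity: one class per record, never zero, never the
        sentinel when any mappable pathology is present."""
        for classes in ALL_SUBSETS:
            a = select_marshall_class(classes, False)
            assert isinstance(a.final, MarshallClass)
            if classes:
                assert a.final is not MC.NO_TBI
            else:
                assert a.final is MC.NO_TBI

    @given(subset_strategy, st.booleans(), st.sampled_from(ALL_CONFIGS))
    def test_monotone_dominance(self, classes, evac, config):
        """Adding a class that outranks the fired one raises the result to
        that class; adding a lower-ranked class never changes it."""
        base = select_marshall_class(classes, evac, config=config)
        order = _priority_order(config)
        fired_rank = min((order.index(c) for c in classes), default=len(order))
        for extra in SUBSTANTIVE:
            if extra in classes:
                continue
            grown = select_marshall_class(classes | {extra}, evac, config=config)
            if order.index(extra) < fired_rank:
                assert grown.final is oracle_select({extra}, evac, config=config)
            else:
                assert grown.final is base.final


def _priority_order(config):
    order = [EQ.PENETRATING]
    if config.vii_position is ViiPosition.AFTER_PENETRATING:
        order.append(EQ.BRAINSTEM_CEREBELLAR)
    order += [EQ.EQ_V_VI, EQ.EQ_IV, EQ.EQ_III]
    if config.vii_position is ViiPosition.BEFORE_CLASS_II:
        order.append(EQ.BRAINSTEM_CEREBELLAR)
    order.append(EQ.EQ_II)
    if config.vii_position is ViiPosition.BEFORE_CLASS_I:
        order.append(EQ.BRAINSTEM_CEREBELLAR)
    order.append(EQ.EQ_I)
    return order


class TestClassifyRecord:
    def test_hypoxia_only_record_is_class_i(self):
        a = classify_record(record("140701", version=AIS2005))
        assert a.final is MC.I

    def test_hypoxia_with_severe_swelling_is_class_iv(self):
        """Secondary swelling outranks the clear-CT hypoxia allocation."""
        a = classify_record(record("140701", "140666.5", version=AIS2005))
        assert a.final is MC.IV

    def test_crush_record_maps_to_vi_even_without_evacuation(self):
        a = classify_record(record("113000.6", evacuated=False))
        assert a.final is MC.VI

    def test_non_tbi_only_record_yields_sentinel_with_warning(self):
        a = classify_record(record("116002"))
        assert a.final is MC.NO_TBI
        assert any("NO_TBI" in w for w in a.warnings)

    def test_order_invariance_of_code_list(self):
        raws = ["140204.5", "140608.4", "150200", "140602.3"]
        a = classify_record(record(*raws, evacuated=True))
        b = classify_record(record(*reversed(raws), evacuated=True))
        assert a.final is b.final and a.fired_step == b.fired_step


class TestAgreement:
    def test_identical_lists_agree_perfectly(self):
        xs = [MC.I, MC.II, MC.VI, MC.VII, MC.I]
        rep = cross_tabulate_assignments(xs, xs)
        assert rep.agreement == 1.0 and rep.kappa == 1.0
        assert rep.table.to_numpy().sum() == 5

    def test_disjoint_single_class_lists(self):
        rep = cross_tabulate_assignments([MC.I] * 4, [MC.II] * 4)
        assert rep.agreement == 0.0

    def test_kappa_matches_hand_computed_value(self):
        # counts: a=(I,I,I,II), b=(I,I,II,II): po=3/4,
        # pe = 0.75*0.5 + 0.25*0.5 = 0.5, kappa = (0.75-0.5)/(1-0.5) = 0.5
        rep = cross_tabulate_assignments(
            [MC.I, MC.I, MC.I, MC.II], [MC.I, MC.I, MC.II, MC.II]
        )
        assert rep.kappa == pytest.approx(0.5)
        assert rep.agreement == pytest.approx(0.75)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate_assignments([MC.I], [MC.I, MC.II])
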