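"""Stage 2: resolve a set of equivalent classes into one Marshall class.

The Marshall system is mutually exclusive — each patient gets exactly one
class — while AIS coding assigns one code per injury. The published
resolution is an ordinal priority algorithm: screen the patient's
equivalent classes in a fixed order and stop at the first hit.

Default step order::

    penetrating -> VIII (stop: the Marshall system covers blunt injury only)
    mass lesion (V/VI) -> VI if evacuated else V   [crush 113000 forces VI]
    shift -> IV
    swelling -> III
    brain stem / cerebellar -> VII
    diffuse injury -> II
    no visible pathology -> I
    nothing mappable -> NO_TBI sentinel

The position of the VII step is deliberately flexible (three published
variants), the V-vs-VI evacuation convention has two readings (the
prose-and-worked-example reading, the default, allocates VI to an
*evacuated* lesion; the classic class-definition table says the opposite),
and the extension classes VII/VIII can be reported split, split by
anatomical subtag, or merged as "unclassified". All of that lives in
:class:`SelectorConfig`.

:func:`oracle_select` recomputes the answer by a structurally different
route (a total priority order plus a per-label outcome map) and exists so
tests can cross-validate the step cascade exhaustively.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .codes import DictionaryVersion
from .crosswalk import (
    EquivalentClass,
    StageOneResult,
    Subtag,
    assign_equivalent_classes,
    builtin_table,
)
from .registry import PatientRecord

__all__ = [
    "MarshallClass",
    "ViiPosition",
    "EvacuationSemantics",
    "UnclassifiedMode",
    "SelectorConfig",
    "MarshallAssignment",
    "AgreementReport",
    "select_marshall_class",
    "oracle_select",
    "classify_record",
    "classify_records",
    "cross_tabulate_assignments",
]

logger = logging.getLogger(__name__)


class MarshallClass(enum.Enum):
    """Final Marshall CT class, including the two extension classes.

    I no visible pathology; II diffuse injury; III swelling (compressed or
    absent cisterns); IV shift (> 5 mm); V evacuated mass lesion; VI
    non-evacuated mass lesion > 25 cc; VII brain-stem/cerebellar injury and
    VIII penetrating injury (extension classes); NO_TBI is a sentinel for
    records with no mappable brain-injury code — deliberately distinct from
    class I, which asserts a *normal CT*, not an absent one.
    """

    I = "I"  # noqa: E741 - Roman numeral, the field's own notation
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    NO_TBI = "NO_TBI"

    @property
    def number(self) -> int:
        """Numeric class (1..8); 0 for the NO_TBI sentinel."""
        order = ("NO_TBI", "I", "II", "III", "IV", "V", "VI", "VII", "VIII")
        return order.index(self.name)


class ViiPosition(enum.Enum):
    """Where the brain-stem/cerebellar (class VII) step sits in the cascade."""

    BEFORE_CLASS_II = "before_class_II"
    AFTER_PENETRATING = "after_penetrating"
    BEFORE_CLASS_I = "before_class_I"


class EvacuationSemantics(enum.Enum):
    """Which class an evacuated vs non-evacuated mass lesion receives.

    ``PAPER`` (default): evacuated -> VI, otherwise V — the convention the
    method's prose states twice, including its worked example.
    ``MARSHALL_TABLE1``: evacuated -> V, non-evacuated -> VI — the classic
    class-definition table ("V: any lesion surgically evacuated; VI:
    lesion > 25 cc not surgically evacuated"). The two sources genuinely
    contradict each other; both behaviours are offered.
    """

    PAPER = "paper"
    MARSHALL_TABLE1 = "marshall_table1"


class UnclassifiedMode(enum.Enum):
    """How the extension classes VII/VIII are reported."""

    SPLIT = "split"                # VII and VIII as-is (default)
    SPLIT_SUBTAG = "split_subtag"  # VII annotated brain stem vs cerebellar
    MERGED = "merged"              # VII and VIII both reported "unclassified"


@dataclass(frozen=True)
class SelectorConfig:
    """Algorithm-variant switches for the Stage-2 selector."""

    vii_position: ViiPosition = ViiPosition.BEFORE_CLASS_II
    evacuation_semantics: EvacuationSemantics = EvacuationSemantics.PAPER
    unclassified_mode: UnclassifiedMode = UnclassifiedMode.SPLIT
    strict: bool = False

    @classmethod
    def all_variants(cls, strict: bool = False) -> list["SelectorConfig"]:
        """Every combination of the 3 x 2 x 3 enum switches (18 configs)."""
        return [
            cls(vp, ev, um, strict)
            for vp, ev, um in itertools.product(ViiPosition, EvacuationSemantics, UnclassifiedMode)
        ]


DEFAULT_CONFIG = SelectorConfig()

#: Equivalent-class sets reaching the selector may only contain these.
_SELECTABLE = frozenset(
    {
        EquivalentClass.EQ_I,
        EquivalentClass.EQ_II,
        EquivalentClass.EQ_III,
        EquivalentClass.EQ_IV,
        EquivalentClass.EQ_V_VI,
        EquivalentClass.BRAINSTEM_CEREBELLAR,
        EquivalentClass.PENETRATING,
    }
)


@dataclass(frozen=True)
class MarshallAssignment:
    """The single Marshall class assigned to a record, with an audit trail."""

    final: MarshallClass
    label: str                       # as reported under the unclassified mode
    fired_step: str                  # name of the algorithm step that decided
    equivalent_classes: frozenset[EquivalentClass]
    evacuated: bool
    warnings: tuple[str, ...] = field(default=(), compare=False)


def _report_label(
    final: MarshallClass,
    config: SelectorConfig,
    subtags: frozenset[Subtag],
) -> str:
    if final in (MarshallClass.VII, MarshallClass.VIII):
        if config.unclassified_mode is UnclassifiedMode.MERGED:
            return "unclassified"
        if config.unclassified_mode is UnclassifiedMode.SPLIT_SUBTAG and final is MarshallClass.VII:
            names = sorted(s.value for s in subtags) or ["brainstem/cerebellar"]
            return f"VII ({'/'.join(names)})"
    return final.value


def _mass_lesion_class(
    evacuated: bool, crush_present: bool, semantics: EvacuationSemantics
) -> tuple[MarshallClass, str]:
    if crush_present:
        # Crush (massive destruction of cranium and brain) is mapped to the
        # most severe class outright; the evacuation flag is irrelevant.
        return MarshallClass.VI, "mass_lesion_crush"
    if semantics is EvacuationSemantics.PAPER:
        return (MarshallClass.VI, "mass_lesion_evacuated") if evacuated else (
            MarshallClass.V,
            "mass_lesion_not_evacuated",
        )
    return (MarshallClass.V, "mass_lesion_evacuated") if evacuated else (
        MarshallClass.VI,
        "mass_lesion_not_evacuated",
    )


def select_marshall_class(
    classes: Iterable[EquivalentClass],
    evacuated: bool,
    crush_present: bool = False,
    config: SelectorConfig = DEFAULT_CONFIG,
    subtags: Iterable[Subtag] = (),
) -> MarshallAssignment:
    """Run the priority cascade over a record's equivalent-class set.

    *classes* must already be filtered of the NON_TBI/UNMAPPED sentinels
    (Stage 1 does this). The empty set yields the NO_TBI sentinel, or raises
    in strict mode.
    """
    present = frozenset(classes)
    bad = present - _SELECTABLE
    if bad:
        raise ValueError(f"unselectable labels reached the selector: {sorted(l.name for l in bad)}")
    subtag_set = frozenset(subtags)
    warnings: list[str] = []
    if evacuated and EquivalentClass.EQ_V_VI not in present:
        warnings.append("evacuation flag set but no mass-lesion (V/VI) code present; ignored")
        logger.warning("%s", warnings[-1])

    def done(final: MarshallClass, step: str) -> MarshallAssignment:
        return MarshallAssignment(
            final=final,
            label=_report_label(final, config, subtag_set),
            fired_step=step,
            equivalent_classes=present,
            evacuated=evacuated,
            warnings=tuple(warnings),
        )

    bsc = EquivalentClass.BRAINSTEM_CEREBELLAR in present

    if EquivalentClass.PENETRATING in present:
        # The Marshall system is designed for blunt injury: stop here.
        return done(MarshallClass.VIII, "penetrating")
    if config.vii_position is ViiPosition.AFTER_PENETRATING and bsc:
        return done(MarshallClass.VII, "brainstem_cerebellar")
    if EquivalentClass.EQ_V_VI in present:
        final, step = _mass_lesion_class(evacuated, crush_present, config.evacuation_semantics)
        return done(final, step)
    if EquivalentClass.EQ_IV in present:
        return done(MarshallClass.IV, "shift")
    if EquivalentClass.EQ_III in present:
        return done(MarshallClass.III, "swelling")
    if config.vii_position is ViiPosition.BEFORE_CLASS_II and bsc:
        return done(MarshallClass.VII, "brainstem_cerebellar")
    if EquivalentClass.EQ_II in present:
        return done(MarshallClass.II, "diffuse_injury")
    if config.vii_position is ViiPosition.BEFORE_CLASS_I and bsc:
        return done(MarshallClass.VII, "brainstem_cerebellar")
    if EquivalentClass.EQ_I in present:
        return done(MarshallClass.I, "no_visible_pathology")
    if config.strict:
        raise ValueError("empty equivalent-class set in strict mode")
    return done(MarshallClass.NO_TBI, "no_mappable_codes")


def oracle_select(
    classes: Iterable[EquivalentClass],
    evacuated: bool,
    crush_present: bool = False,
    config: SelectorConfig = DEFAULT_CONFIG,
) -> MarshallClass:
    """Independent re-derivation of the cascade's answer.

    Builds the total priority order the config implies, maps each present
    label to its outcome class (with the evacuation/crush modifiers
    applied), and returns the outcome of the highest-priority label
    present. Structurally different from :func:`select_marshall_class` on
    purpose: the two must agree on every input, and tests enforce that
    exhaustively.
    """
    present = frozenset(classes)
    if not present:
        return MarshallClass.NO_TBI

    order: list[EquivalentClass] = [EquivalentClass.PENETRATING]
    if config.vii_position is ViiPosition.AFTER_PENETRATING:
        order.append(EquivalentClass.BRAINSTEM_CEREBELLAR)
    order += [EquivalentClass.EQ_V_VI, EquivalentClass.EQ_IV, EquivalentClass.EQ_III]
    if config.vii_position is ViiPosition.BEFORE_CLASS_II:
        order.append(EquivalentClass.BRAINSTEM_CEREBELLAR)
    order.append(EquivalentClass.EQ_II)
    if config.vii_position is ViiPosition.BEFORE_CLASS_I:
        order.append(EquivalentClass.BRAINSTEM_CEREBELLAR)
    order.append(EquivalentClass.EQ_I)

    outcome = {
        EquivalentClass.PENETRATING: MarshallClass.VIII,
        EquivalentClass.BRAINSTEM_CEREBELLAR: MarshallClass.VII,
        EquivalentClass.EQ_V_VI: _mass_lesion_class(
            evacuated, crush_present, config.evacuation_semantics
        )[0],
        EquivalentClass.EQ_IV: MarshallClass.IV,
        EquivalentClass.EQ_III: MarshallClass.III,
        EquivalentClass.EQ_II: MarshallClass.II,
        EquivalentClass.EQ_I: MarshallClass.I,
    }
    priority = {label: i for i, label in enumerate(order)}
    top = min(present, key=priority.__getitem__)
    return outcome[top]


def classify_record(
    record: PatientRecord,
    version: Optional[DictionaryVersion] = None,
    config: SelectorConfig = DEFAULT_CONFIG,
) -> MarshallAssignment:
    """Full two-stage classification of one registry record.

    Stage 1 maps every code to its equivalent class via the embedded
    crosswalk for the record's dictionary version; Stage 2 runs the
    priority cascade. Records containing only the non-TBI code 116002,
    unmapped codes and/or non-head codes yield the NO_TBI sentinel with a
    warning.
    """
    table = builtin_table(version or record.version)
    stage1: StageOneResult = assign_equivalent_classes(
        record.codes, table, strict=config.strict
    )
    assignment = select_marshall_class(
        stage1.classes,
        record.evacuated,
        crush_present=stage1.crush_present,
        config=config,
        subtags=stage1.subtags,
    )
    extra = list(record.warnings)
    if not stage1.classes and (record.codes or stage1.ignored_non_head):
        extra.append("no mappable brain-injury codes; NO_TBI sentinel assigned")
    n_unmapped = stage1.tally.get(EquivalentClass.UNMAPPED, 0)
    if n_unmapped:
        extra.append(f"{n_unmapped} unmapped head-region code(s) ignored")
    if extra:
        assignment = MarshallAssignment(
            final=assignment.final,
            label=assignment.label,
            fired_step=assignment.fired_step,
            equivalent_classes=assignment.equivalent_classes,
            evacuated=assignment.evacuated,
            warnings=tuple(extra) + assignment.warnings,
        )
    return assignment


def classify_records(
    records: Sequence[PatientRecord],
    version: Optional[DictionaryVersion] = None,
    config: SelectorConfig = DEFAULT_CONFIG,
) -> list[MarshallAssignment]:
    """Vector form of :func:`classify_record`, preserving input order."""
    return [classify_record(r, version, config) for r in records]


# ---------------------------------------------------------------------------
# Agreement between two sets of assignments (validation-study plumbing).

_CLASS_ORDER = [m.value for m in MarshallClass]


@dataclass(frozen=True)
class AgreementReport:
    """Contingency table and chance-corrected agreement of two raters."""

    table: pd.DataFrame          # 9 x 9 over all MarshallClass values
    agreement: float             # overall fraction of identical assignments
    kappa: float                 # Cohen's kappa
    n: int


def _class_values(
    assignments: Sequence[Union[MarshallAssignment, MarshallClass]]
) -> list[str]:
    return [
        (a.final if isinstance(a, MarshallAssignment) else a).value for a in assignments
    ]


def cross_tabulate_assignments(
    a: Sequence[Union[MarshallAssignment, MarshallClass]],
    b: Sequence[Union[MarshallAssignment, MarshallClass]],
) -> AgreementReport:
    """Compare two aligned assignment lists (e.g. AIS-derived vs CT-read).

    Returns the full 9x9 contingency table over Marshall classes, the
    overall percent agreement as a fraction, and Cohen's kappa. Kappa is
    defined as 1.0 under perfect agreement even when a single class
    dominates both lists (the chance-correction denominator vanishes
    there).
    """
    if len(a) != len(b):
        raise ValueError(f"assignment lists differ in length: {len(a)} vs {len(b)}")
    va, vb = _class_values(a), _class_values(b)
    cat = pd.CategoricalDtype(categories=_CLASS_ORDER)
    table = pd.crosstab(
        pd.Series(va, dtype=cat, name="a"),
        pd.Series(vb, dtype=cat, name="b"),
        dropna=False,
    )
    n = len(va)
    agreement = float(np.mean([x == y for x, y in zip(va, vb)])) if n else float("nan")
    if n and agreement == 1.0:
        kappa = 1.0
    else:
        kappa = float(cohen_kappa_score(va, vb, labels=_CLASS_ORDER))
    return AgreementReport(table=table, agreement=agreement, kappa=kappa, n=n)
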