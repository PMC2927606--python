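"""Stage 1: map AIS codes to "Equivalent to Marshall Class" labels.

The Marshall CT Classification grades traumatic brain injury by the CT
features that drive the risk of raised intracranial pressure: mass lesions
(25 cc cut-off), basal cistern status and midline shift (5 mm cut-off), and
whether a mass lesion was surgically evacuated. AIS codes describe the same
pathology anatomically, with their own size cut-offs (e.g. 30/50 cc for
cerebral contusion). The published expert-consensus cross-tabulation
pre-compiles those differences into a per-code allocation; this module
embeds that allocation and applies it. The volume cut-offs are therefore
documentation only — nothing here recomputes lesion sizes.

Codes with no Marshall equivalent (brain-stem, cerebellar and penetrating
injuries) get their own labels so the Stage-2 selector can route them to
the extension classes VII/VIII or report them as "unclassified".
"""

from __future__ import annotations

import csv
import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from . import _tables
from .codes import AISCode, DictionaryVersion

__all__ = [
    "EquivalentClass",
    "Subtag",
    "ClassLabel",
    "MappingEntry",
    "MappingTable",
    "StageOneResult",
    "UnmappedCodeError",
    "builtin_table",
    "check_table_consistency",
    "lookup_equivalent_class",
    "assign_equivalent_classes",
    "export_table",
    "import_table",
]

logger = logging.getLogger(__name__)


class EquivalentClass(enum.Enum):
    """Stage-1 label: the Marshall class(es) a single AIS code can attract."""

    EQ_I = "I"
    EQ_II = "II"
    EQ_III = "III"
    EQ_IV = "IV"
    EQ_V_VI = "V/VI"
    BRAINSTEM_CEREBELLAR = "brainstem/cerebellar"
    PENETRATING = "penetrating"
    NON_TBI = "non-TBI"          # superficial penetrating scalp wound, 116002
    UNMAPPED = "unmapped"        # head-region code absent from the tables


#: The seven labels that can actually reach the Stage-2 selector.
SUBSTANTIVE_CLASSES: tuple[EquivalentClass, ...] = (
    EquivalentClass.EQ_I,
    EquivalentClass.EQ_II,
    EquivalentClass.EQ_III,
    EquivalentClass.EQ_IV,
    EquivalentClass.EQ_V_VI,
    EquivalentClass.BRAINSTEM_CEREBELLAR,
    EquivalentClass.PENETRATING,
)


class Subtag(enum.Enum):
    """Anatomical split of the merged brain-stem/cerebellar label."""

    BRAINSTEM = "brainstem"
    CEREBELLAR = "cerebellar"


@dataclass(frozen=True)
class ClassLabel:
    """An equivalent-class label with its optional anatomical subtag."""

    label: EquivalentClass
    subtag: Optional[Subtag] = None

    def __post_init__(self) -> None:
        if self.subtag is not None and self.label is not EquivalentClass.BRAINSTEM_CEREBELLAR:
            raise ValueError("subtag is only valid on the brain-stem/cerebellar label")


@dataclass(frozen=True)
class MappingEntry:
    """One row of the crosswalk: a predot and everything printed about it."""

    predot: str
    equivalent_class: EquivalentClass
    canonical_severity: Optional[int]
    subtag: Optional[Subtag]
    provenance: str  # "Table 2" | "Table 3" | "Appendix"


@dataclass(frozen=True)
class MappingTable:
    """Immutable per-version crosswalk from predot to equivalent class.

    ``entries`` maps each 6-digit predot to its :class:`MappingEntry`. The
    25 cc / 5 mm Marshall cut-offs and the AIS 30/50 cc size cut-offs are
    already baked into these allocations and are never recomputed here.
    """

    version: DictionaryVersion
    entries: Mapping[str, MappingEntry] = field(repr=False)

    def grouped(self) -> dict[EquivalentClass, frozenset[str]]:
        """Predot sets per equivalent class (the grouped 'Table 4' view)."""
        groups: dict[EquivalentClass, set[str]] = {}
        for entry in self.entries.values():
            groups.setdefault(entry.equivalent_class, set()).add(entry.predot)
        return {k: frozenset(v) for k, v in groups.items()}


# printed allocation string -> (class, subtag)
_ALLOCATION = {
    "I": (EquivalentClass.EQ_I, None),
    "II": (EquivalentClass.EQ_II, None),
    "III": (EquivalentClass.EQ_III, None),
    "IV": (EquivalentClass.EQ_IV, None),
    "V/VI": (EquivalentClass.EQ_V_VI, None),
    "Brain stem injury": (EquivalentClass.BRAINSTEM_CEREBELLAR, Subtag.BRAINSTEM),
    "Cerebellar injury": (EquivalentClass.BRAINSTEM_CEREBELLAR, Subtag.CEREBELLAR),
    "Penetrating injury": (EquivalentClass.PENETRATING, None),
}


def _entry_from_row(printed_code: str, printed_class: str, provenance: str) -> MappingEntry:
    predot, _, post = printed_code.partition(".")
    eq, subtag = _ALLOCATION[printed_class]
    return MappingEntry(
        predot=predot,
        equivalent_class=eq,
        canonical_severity=int(post) if post else None,
        subtag=subtag,
        provenance=provenance,
    )


@lru_cache(maxsize=None)
def builtin_table(version: DictionaryVersion) -> MappingTable:
    """The embedded crosswalk for *version*.

    The 1998 table holds every row of the published per-code
    cross-tabulation plus the appendix addition (cerebral NFS, 140999, to
    class II). The 2005 table is a strict superset: the 2005 dictionary
    update only added codes, it changed no existing allocation.
    """
    entries: dict[str, MappingEntry] = {}
    for code, cls in _tables.TABLE2_ROWS:
        e = _entry_from_row(code, cls, "Table 2")
        entries[e.predot] = e
    for code, cls in _tables.APPENDIX_ROWS:
        e = _entry_from_row(code, cls, "Appendix")
        entries[e.predot] = e
    if version is DictionaryVersion.AIS2005:
        for code, cls in _tables.TABLE3_ROWS:
            e = _entry_from_row(code, cls, "Table 3")
            entries.setdefault(e.predot, e)  # 140686 already present from 1998
    return MappingTable(version=version, entries=entries)


_GROUP_HEADINGS = {
    "Equivalent to Marshall Class I": EquivalentClass.EQ_I,
    "Equivalent to Marshall Class II": EquivalentClass.EQ_II,
    "Equivalent to Marshall Class III": EquivalentClass.EQ_III,
    "Equivalent to Marshall Class IV": EquivalentClass.EQ_IV,
    "Equivalent to Marshall Class V/VI": EquivalentClass.EQ_V_VI,
    "Cerebellar/brain stem injuries": EquivalentClass.BRAINSTEM_CEREBELLAR,
    "Penetrating injury": EquivalentClass.PENETRATING,
}


def check_table_consistency() -> list[str]:
    """Audit the two independently transcribed views of the 1998 crosswalk.

    Compares, class by class, the grouping derived from the per-code table
    against the separately transcribed grouped table (the brain-stem and
    cerebellar columns of the per-code table are compared jointly against
    the single merged row of the grouped table). Entries whose provenance is
    the appendix rather than the per-code table (cerebral NFS, 140999) are
    checked for presence but excluded from the set comparison, because the
    grouped table predates that addition too.

    Returns a list of human-readable discrepancy strings; empty on the
    shipped tables.
    """
    problems: list[str] = []
    table = builtin_table(DictionaryVersion.AIS98)
    from_table2: dict[EquivalentClass, set[str]] = {eq: set() for eq in _GROUP_HEADINGS.values()}
    for entry in table.entries.values():
        if entry.provenance == "Table 2":
            from_table2[entry.equivalent_class].add(entry.predot)
    for heading, eq in _GROUP_HEADINGS.items():
        expected = _tables.TABLE4_GROUPS[heading]
        got = frozenset(from_table2[eq])
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            problems.append(
                f"{heading}: per-code table disagrees with grouped table"
                f" (missing {missing}, extra {extra})"
            )
    for code, printed in _tables.APPENDIX_ROWS:
        predot = code.partition(".")[0]
        entry = table.entries.get(predot)
        if entry is None or entry.equivalent_class is not _ALLOCATION[printed][0]:
            problems.append(f"appendix addition {predot} -> {printed} missing from built table")
    return problems


class UnmappedCodeError(LookupError):
    """Strict-mode failure: a head-region code has no crosswalk entry."""


def lookup_equivalent_class(
    code: AISCode,
    table: Optional[MappingTable] = None,
    *,
    strict: bool = False,
) -> ClassLabel:
    """Stage-1 lookup for a single code.

    116002 (superficial penetrating scalp wound) is, by definition, not
    accompanied by brain injury and returns the ``NON_TBI`` sentinel. Any
    other head-region code absent from the table — cranial-nerve codes,
    unconsciousness codes (deliberately excluded from the published
    cross-tabulation), or codes from dictionary editions the tables do not
    cover — returns ``UNMAPPED`` (or raises in strict mode).
    """
    if table is None:
        table = builtin_table(code.dict_version)
    if code.predot == _tables.NON_TBI_PREDOT:
        return ClassLabel(EquivalentClass.NON_TBI)
    entry = table.entries.get(code.predot)
    if entry is None:
        if strict:
            raise UnmappedCodeError(
                f"AIS code {code} has no entry in the {table.version.value} crosswalk"
            )
        logger.warning("unmapped head-region AIS code %s (dictionary %s)", code, table.version.value)
        return ClassLabel(EquivalentClass.UNMAPPED)
    return ClassLabel(entry.equivalent_class, entry.subtag)


@dataclass(frozen=True)
class StageOneResult:
    """Deduplicated Stage-1 outcome for one patient record."""

    classes: frozenset[EquivalentClass]
    subtags: frozenset[Subtag]
    tally: Mapping[EquivalentClass, int]
    crush_present: bool
    ignored_non_head: int = 0


def assign_equivalent_classes(
    codes: Iterable[AISCode],
    table: Optional[MappingTable] = None,
    *,
    strict: bool = False,
) -> StageOneResult:
    """Map every code of a record and collapse to the distinct class set.

    Duplicate codes collapse: the Marshall classes reflect the presence of
    pathology types, not their counts. Non-head codes (leading digit other
    than 1) are outside the head section of the dictionary and are ignored
    with a debug log line. ``NON_TBI`` and ``UNMAPPED`` lookups are counted
    in the tally but excluded from the returned class set. ``crush_present``
    flags the crush code 113000, which the Stage-2 selector must force to
    class VI regardless of evacuation.
    """
    tally: Counter[EquivalentClass] = Counter()
    classes: set[EquivalentClass] = set()
    subtags: set[Subtag] = set()
    crush = False
    ignored = 0
    for code in codes:
        if not code.is_head_region:
            logger.debug("ignoring non-head AIS code %s", code)
            ignored += 1
            continue
        label = lookup_equivalent_class(code, table, strict=strict)
        tally[label.label] += 1
        if label.label in (EquivalentClass.NON_TBI, EquivalentClass.UNMAPPED):
            continue
        classes.add(label.label)
        if label.subtag is not None:
            subtags.add(label.subtag)
        if code.predot == _tables.CRUSH_PREDOT:
            crush = True
    return StageOneResult(
        classes=frozenset(classes),
        subtags=frozenset(subtags),
        tally=dict(tally),
        crush_present=crush,
        ignored_non_head=ignored,
    )


# ---------------------------------------------------------------------------
# Rule-file export/import, so the crosswalk is auditable as plain text.

_EXPORT_COLUMNS = ("predot", "severity", "equivalent_class", "subtag", "provenance")


def export_table(table: MappingTable, path: Union[str, Path]) -> None:
    """Write the crosswalk as delimited text (one row per predot)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXPORT_COLUMNS)
        for predot in sorted(table.entries):
            e = table.entries[predot]
            writer.writerow(
                (
                    e.predot,
                    "" if e.canonical_severity is None else e.canonical_severity,
                    e.equivalent_class.name,
                    "" if e.subtag is None else e.subtag.value,
                    e.provenance,
                )
            )


def import_table(path: Union[str, Path], version: DictionaryVersion) -> MappingTable:
    """Read a crosswalk previously written by :func:`export_table`."""
    entries: dict[str, MappingEntry] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_EXPORT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"crosswalk file {path} lacks columns: {sorted(missing)}")
        for row in reader:
            predot = row["predot"].strip()
            if predot in entries:
                raise ValueError(f"duplicate predot {predot} in {path}")
            entries[predot] = MappingEntry(
                predot=predot,
                equivalent_class=EquivalentClass[row["equivalent_class"].strip()],
                canonical_severity=int(row["severity"]) if row["severity"].strip() else None,
                subtag=Subtag(row["subtag"].strip()) if row["subtag"].strip() else None,
                provenance=row["provenance"].strip(),
            )
    return MappingTable(version=version, entries=entries)
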