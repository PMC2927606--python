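"""Registry extract I/O: delimited text in, classified assignments out.

No published trauma-registry export schema exists for this task, so the
schema here is this package's own: a UTF-8 CSV with a header row and
columns ``patient_id``, ``ais_codes``, ``evacuated`` and optionally
``dict_version``. ``ais_codes`` is a semicolon-separated list of AIS codes
in dotted (``140666.5``) or undotted (``140666``) form — comma as the field
delimiter and semicolon inside the code list avoids quoting in the common
case; both are configurable.

Lenient mode is the default: registry extracts are messy, and the
classification method tolerates unknown codes by ignoring them. Strict mode
exists for audits and turns parse failures and unmapped codes into errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence, Union

import pandas as pd

from .codes import AISCode, AISCodeError, DictionaryVersion, parse_ais_code

if TYPE_CHECKING:  # pragma: no cover
    from .selector import MarshallAssignment

__all__ = ["PatientRecord", "RegistryFormatError", "read_records", "write_assignments"]

logger = logging.getLogger(__name__)

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


class RegistryFormatError(ValueError):
    """Raised for schema violations in a registry extract."""


@dataclass(frozen=True)
class PatientRecord:
    """One registry row: a patient with zero or more head-injury AIS codes.

    ``evacuated`` records whether a mass lesion was surgically evacuated
    (registries capture this as a neurosurgical-intervention field); it
    decides between Marshall classes V and VI downstream. An empty code
    list is legal and yields the NO_TBI sentinel.
    """

    patient_id: str
    codes: tuple[AISCode, ...]
    evacuated: bool
    version: DictionaryVersion = DictionaryVersion.AIS98
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise RegistryFormatError("patient_id must be non-empty")


def _parse_evacuated(token: object, row_label: str) -> bool:
    text = str(token).strip().lower()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise RegistryFormatError(
        f"row {row_label}: unrecognized evacuated token {token!r}"
        " (expected one of 0/1/true/false/yes/no)"
    )


def read_records(
    path: Union[str, Path],
    default_version: DictionaryVersion = DictionaryVersion.AIS98,
    *,
    strict: bool = False,
    delimiter: str = ",",
    code_separator: str = ";",
) -> list[PatientRecord]:
    """Read a registry extract into :class:`PatientRecord` objects.

    A per-row ``dict_version`` value overrides *default_version*. In lenient
    mode an unparseable code is dropped with a warning attached to the
    record (rows are never dropped); in strict mode it raises. An
    unrecognized ``evacuated`` token is always an error — guessing a
    surgery flag is not acceptable.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = {"patient_id", "ais_codes", "evacuated"}
    missing = required - set(frame.columns)
    if missing:
        raise RegistryFormatError(f"{path}: missing required column(s): {sorted(missing)}")
    has_version = "dict_version" in frame.columns

    records: list[PatientRecord] = []
    for idx, row in frame.iterrows():
        pid = str(row["patient_id"]).strip()
        row_label = f"{idx + 2} (patient_id={pid or '?'})"  # +2: header + 1-based
        version = default_version
        if has_version and str(row["dict_version"]).strip():
            version = DictionaryVersion.from_tag(row["dict_version"])
        evacuated = _parse_evacuated(row["evacuated"], row_label)
        codes: list[AISCode] = []
        warnings: list[str] = []
        for item in str(row["ais_codes"]).split(code_separator):
            item = item.strip()
            if not item:
                continue
            try:
                codes.append(parse_ais_code(item, version))
            except AISCodeError as exc:
                if strict:
                    raise RegistryFormatError(f"row {row_label}: {exc}") from exc
                warnings.append(f"dropped unparseable code {item!r}")
                logger.warning("row %s: dropped unparseable code %r", row_label, item)
        records.append(
            PatientRecord(
                patient_id=pid,
                codes=tuple(codes),
                evacuated=evacuated,
                version=version,
                warnings=tuple(warnings),
            )
        )
    return records


def write_assignments(
    records: Sequence[PatientRecord],
    assignments: Sequence["MarshallAssignment"],
    path: Union[str, Path],
    *,
    delimiter: str = ",",
) -> None:
    """Write classified output, one row per input record, byte-stable.

    Columns: ``patient_id``, ``marshall_class`` (as reported under the
    active unclassified mode), ``fired_step``, ``equivalent_classes``
    (semicolon-joined Stage-1 labels) and ``warnings``.
    """
    if len(records) != len(assignments):
        raise ValueError(
            f"records ({len(records)}) and assignments ({len(assignments)}) differ in length"
        )
    rows = []
    for rec, asg in zip(records, assignments):
        rows.append(
            {
                "patient_id": rec.patient_id,
                "marshall_class": asg.label,
                "fired_step": asg.fired_step,
                "equivalent_classes": ";".join(
                    sorted(c.value for c in asg.equivalent_classes)
                ),
                "warnings": "; ".join(asg.warnings),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "marshall_class", "fired_step", "equivalent_classes", "warnings"],
    )
    frame.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
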