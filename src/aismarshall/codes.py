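"""Parsing and validation of Abbreviated Injury Scale (AIS) codes.

An AIS code as recorded in a trauma registry is a 6-digit identifier,
optionally followed by a decimal point and a single post-decimal severity
digit in 1..6 (1 = minimal, 6 = maximal), e.g. ``"140666.5"``. The 6-digit
part (the *predot*) identifies the injury; the severity digit scores it.
Codes whose predot ends in ``99`` are "Not Further Specified" (NFS) codes,
used when the injury detail is not adequately documented.

Codes are kept as digit strings throughout: converting to integers would
silently drop leading digits and hide the 6-digit invariant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "AISCode",
    "AISCodeError",
    "DictionaryVersion",
    "SeverityCheck",
    "parse_ais_code",
    "is_nfs",
    "validate_severity",
]


class AISCodeError(ValueError):
    """Raised when a raw registry string cannot be parsed as an AIS code."""


class DictionaryVersion(enum.Enum):
    """AIS dictionary edition a code was assigned under."""

    AIS98 = "1998"
    AIS2005 = "2005"

    @classmethod
    def from_tag(cls, tag: str) -> "DictionaryVersion":
        """Resolve a registry tag such as ``"1998"``, ``"2005"``, ``"AIS98"``."""
        t = str(tag).strip().lower()
        if t in {"1998", "98", "ais98", "ais1998"}:
            return cls.AIS98
        if t in {"2005", "ais2005", "ais05"}:
            return cls.AIS2005
        raise AISCodeError(f"unknown AIS dictionary version tag: {tag!r}")


@dataclass(frozen=True)
class AISCode:
    """A parsed AIS code: 6-digit identifier, optional severity, dictionary.

    Attributes
    ----------
    predot : str
        Exactly six digits, preserved verbatim from the input.
    severity : int or None
        Post-decimal severity score in 1..6, or ``None`` when the registry
        recorded the code without a severity digit.
    dict_version : DictionaryVersion
        Which AIS dictionary edition the code belongs to.
    """

    predot: str
    severity: Optional[int]
    dict_version: DictionaryVersion

    def __post_init__(self) -> None:
        if len(self.predot) != 6 or not self.predot.isdigit():
            raise AISCodeError(f"predot must be exactly 6 digits, got {self.predot!r}")
        if self.severity is not None and not 1 <= self.severity <= 6:
            raise AISCodeError(f"severity must be in 1..6, got {self.severity!r}")

    @property
    def is_nfs(self) -> bool:
        """True for Not-Further-Specified codes (predot ending in ``99``)."""
        return self.predot.endswith("99")

    @property
    def is_head_region(self) -> bool:
        """True when the code belongs to the head section (leading digit 1)."""
        return self.predot.startswith("1")

    def __str__(self) -> str:
        if self.severity is None:
            return self.predot
        return f"{self.predot}.{self.severity}"


def parse_ais_code(raw: str, dict_version: DictionaryVersion) -> AISCode:
    """Parse a registry string like ``"140666.5"`` or ``"150200"``.

    Surrounding whitespace is trimmed; internal whitespace, non-digits,
    a predot that is not exactly 6 digits, or a severity outside 1..6 all
    raise :class:`AISCodeError` naming the offending input.
    """
    text = raw.strip() if isinstance(raw, str) else ""
    if not text:
        raise AISCodeError(f"empty AIS code string: {raw!r}")
    predot, dot, post = text.partition(".")
    if not predot.isdigit() or len(predot) != 6:
        raise AISCodeError(f"malformed AIS code {raw!r}: expected 6 digits before any decimal point")
    severity: Optional[int] = None
    if dot:
        if not (len(post) == 1 and post.isdigit()):
            raise AISCodeError(f"malformed AIS code {raw!r}: severity must be a single digit")
        severity = int(post)
        if not 1 <= severity <= 6:
            raise AISCodeError(f"malformed AIS code {raw!r}: severity {severity} outside 1..6")
    return AISCode(predot=predot, severity=severity, dict_version=dict_version)


def is_nfs(code: AISCode) -> bool:
    """Whether *code* is a Not-Further-Specified code (predot ends in "99")."""
    return code.is_nfs


class SeverityCheck(enum.Enum):
    """Outcome of comparing a code's severity digit against the canonical one."""

    OK = "ok"
    WARNING = "warning"


def validate_severity(code: AISCode) -> SeverityCheck:
    """Advisory check of the severity digit against the embedded crosswalk.

    The Stage-1 mapping is keyed on the predot alone, so a mismatching
    severity never changes the class a code maps to — but it usually means
    a transcription slip in the registry, so it is worth flagging.

    Returns ``WARNING`` when the code carries a severity digit that differs
    from the canonical severity printed for its predot in the embedded table
    for its dictionary version; ``OK`` otherwise (equal severity, severity
    absent, code absent from the table, or no canonical severity recorded).
    """
    from .crosswalk import builtin_table  # local import: avoid cycle at load

    if code.severity is None:
        return SeverityCheck.OK
    entry = builtin_table(code.dict_version).entries.get(code.predot)
    if entry is None or entry.canonical_severity is None:
        return SeverityCheck.OK
    if code.severity != entry.canonical_severity:
        return SeverityCheck.WARNING
    return SeverityCheck.OK
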