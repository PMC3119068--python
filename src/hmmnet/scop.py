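"""SCOP domain identifiers and the four-level classification hierarchy.

SCOP organizes protein domains into a strict hierarchy of class, fold,
superfamily, and family.  Each domain carries a stable identifier (sid,
e.g. ``d1bg6a2``) and a concise classification string (sccs, e.g.
``c.2.1.6`` = class c, fold 2, superfamily 1, family 6).  Everything
downstream — network labels, conservation censuses, ROC positives — is
phrased in terms of these two records and the level at which two
classifications agree.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ScopParseError",
    "ScopSid",
    "ScopClassification",
    "HmmRecord",
    "HierarchyLevel",
    "parse_sid",
    "parse_sccs",
    "shared_level",
]


class ScopParseError(ValueError):
    """Raised when a sid or sccs string does not match the expected grammar."""


class HierarchyLevel(enum.IntEnum):
    """SCOP hierarchy levels, ordered deepest-first (family > ... > class).

    The integer value is the depth: agreement at a deeper level implies
    agreement at every shallower one, so levels compare naturally.
    """

    CLASS = 1
    FOLD = 2
    SUPERFAMILY = 3
    FAMILY = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "HierarchyLevel":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown hierarchy level {label!r}; expected one of "
                f"{[m.label for m in cls]}"
            ) from None


# sid grammar: "d" + 4-char PDB code + chain char + domain char, where either
# suffix position may be "_" (no chain / whole chain).  This covers every sid
# form used by SCOP 1.75 without implementing the full historical grammar.
_SID_RE = re.compile(r"^d([0-9a-z]{4})([0-9a-z_])([0-9a-z_])$")

_SCCS_RE = re.compile(r"^([a-g])\.(\d+)\.(\d+)\.(\d+)$")


@dataclass(frozen=True)
class ScopSid:
    """A parsed SCOP stable domain identifier."""

    raw: str
    pdb_code: str
    chain_and_region: str

    def __post_init__(self) -> None:
        if self.raw != "d" + self.pdb_code + self.chain_and_region:
            raise ScopParseError(
                f"inconsistent sid parts for {self.raw!r}: "
                f"{self.pdb_code!r} + {self.chain_and_region!r}"
            )

    def __str__(self) -> str:
        return self.raw


@dataclass(frozen=True, order=True)
class ScopClassification:
    """A SCOP concise classification string (sccs), e.g. ``c.2.1.6``."""

    cls: str
    fold: int
    superfamily: int
    family: int

    def __post_init__(self) -> None:
        if self.cls not in "abcdefg" or len(self.cls) != 1:
            raise ScopParseError(f"class letter must be one of a-g, got {self.cls!r}")
        for name in ("fold", "superfamily", "family"):
            if getattr(self, name) < 1:
                raise ScopParseError(f"{name} index must be positive")

    def __str__(self) -> str:
        return f"{self.cls}.{self.fold}.{self.superfamily}.{self.family}"

    def prefix(self, level: HierarchyLevel) -> str:
        """The classification truncated to *level* (e.g. superfamily -> ``c.2.1``)."""
        parts = (self.cls, str(self.fold), str(self.superfamily), str(self.family))
        return ".".join(parts[: int(level)])


@dataclass(frozen=True)
class HmmRecord:
    """One profile HMM in the library: its domain sid and classification."""

    sid: ScopSid
    sccs: ScopClassification


def parse_sid(text: str) -> ScopSid:
    """Parse a SCOP sid such as ``d1bg6a2`` or ``d1hdoa_``.

    Raises
    ------
    ScopParseError
        If *text* does not start with ``d`` or does not have the
        7-character sid shape.
    """
    if not text:
        raise ScopParseError("empty sid")
    m = _SID_RE.match(text)
    if m is None:
        raise ScopParseError(f"malformed SCOP sid: {text!r}")
    return ScopSid(raw=text, pdb_code=m.group(1), chain_and_region=m.group(2) + m.group(3))


def parse_sccs(text: str) -> ScopClassification:
    """Parse a concise classification string like ``c.2.1.6``."""
    if not text:
        raise ScopParseError("empty sccs")
    m = _SCCS_RE.match(text)
    if m is None:
        raise ScopParseError(f"malformed sccs string: {text!r}")
    return ScopClassification(
        cls=m.group(1),
        fold=int(m.group(2)),
        superfamily=int(m.group(3)),
        family=int(m.group(4)),
    )


def shared_level(
    a: ScopClassification, b: ScopClassification
) -> Optional[HierarchyLevel]:
    """Deepest hierarchy level at which two classifications agree.

    Returns ``HierarchyLevel.FAMILY`` for identical classifications, down to
    ``HierarchyLevel.CLASS`` when only the class letter matches, and ``None``
    when even the classes differ.
    """
    if a.cls != b.cls:
        return None
    if a.fold != b.fold:
        return HierarchyLevel.CLASS
    if a.superfamily != b.superfamily:
        return HierarchyLevel.FOLD
    if a.family != b.family:
        return HierarchyLevel.SUPERFAMILY
    return HierarchyLevel.FAMILY
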