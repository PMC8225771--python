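"""Ranked lineages for reference amplicons.

Lineages are semicolon-delimited strings over the seven canonical ranks
(domain..species).  Trailing ranks may be absent; absent ranks are stored
as ``None`` and written back as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class_",
    "order",
    "family",
    "genus",
    "species",
)

#: rank names as they appear in files (no trailing underscore).
RANK_LABELS: tuple[str, ...] = tuple(r.rstrip("_") for r in RANKS)

_MISSING = {"", "NA", "N/A", "NAN", "NONE"}


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomy from domain to species; missing ranks are ``None``."""

    domain: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def get(self, rank: str) -> Optional[str]:
        rank = rank if rank in RANKS else rank + "_"
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def as_tuple(self) -> tuple[Optional[str], ...]:
        return tuple(getattr(self, f.name) for f in fields(self))

    def to_string(self) -> str:
        return ";".join("NA" if v is None else v for v in self.as_tuple())

    @property
    def is_empty(self) -> bool:
        return all(v is None for v in self.as_tuple())


#: all-NA lineage used in permissive mode.
NA_LINEAGE = Lineage()


def parse_lineage(lineage_string: str) -> Lineage:
    """Parse ``"domain;phylum;...;species"`` into a :class:`Lineage`.

    Missing trailing ranks and empty/``NA`` fields become ``None``; an
    empty string yields an all-NA lineage.  More than seven fields is an
    error (there is no rank below species here).
    """
    s = lineage_string.strip()
    if not s:
        return NA_LINEAGE
    parts = [p.strip() for p in s.split(";")]
    if len(parts) > len(RANKS):
        raise ValueError(
            f"lineage has {len(parts)} fields, at most {len(RANKS)} allowed: "
            f"{lineage_string!r}"
        )
    values: list[Optional[str]] = []
    for p in parts:
        values.append(None if p.upper() in _MISSING else p)
    values.extend([None] * (len(RANKS) - len(values)))
    return Lineage(*values)
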