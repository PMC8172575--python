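"""Non-semantic unique identifiers for records, short forms and long forms.

Identifiers are a single letter prefix followed by a zero-padded number of at
least six digits: ``R`` for records, ``S`` for unique short forms, ``L`` for
unique long forms and ``G`` for synonym groups (e.g. ``R000001``).  Record
identifiers follow the original order of the sources, which preserves source
transparency; S/L identifiers are numbered by first occurrence of the raw
string in record order.  Indices beyond 999,999 widen the digit field rather
than wrap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io import SenseInventory

ID_PATTERN = re.compile(r"^[RSLG][0-9]{6,}$")

_PREFIXES = frozenset("RSLG")


def format_id(prefix: str, n: int) -> str:
    """Format identifier ``n`` with the given prefix, e.g. ``("R", 1) -> "R000001"``."""
    if prefix not in _PREFIXES:
        raise ValueError(f"unknown identifier prefix {prefix!r}; expected one of R, S, L, G")
    if n < 1:
        raise ValueError(f"identifier index must be >= 1, got {n}")
    return f"{prefix}{n:06d}"


@dataclass
class IdRegistry:
    """Injective key -> identifier mapping for one prefix.

    ``assign`` returns the existing identifier for a known key and mints the
    next sequential one otherwise.
    """

    prefix: str
    next_index: int = 1
    assigned: dict[str, str] = field(default_factory=dict)

    def assign(self, key: str) -> str:
        ident = self.assigned.get(key)
        if ident is None:
            ident = format_id(self.prefix, self.next_index)
            self.assigned[key] = ident
            self.next_index += 1
        return ident


def assign_record_ids(inv: SenseInventory, force: bool = False) -> SenseInventory:
    """Assign R identifiers in inventory order (1-based), in place.

    Refuses to overwrite existing record identifiers unless ``force`` is
    set, since renumbering breaks source transparency.
    """
    if not force:
        for rec in inv.records:
            if rec.record_id:
                raise ValueError(
                    f"record already has id {rec.record_id}; pass force=True to reassign"
                )
    for k, rec in enumerate(inv.records, start=1):
        rec.record_id = format_id("R", k)
    return inv


def assign_string_ids(inv: SenseInventory, which: str) -> SenseInventory:
    """Assign S (short-form) or L (long-form) identifiers, in place.

    Uniqueness is keyed on the RAW string: ``"O.C."`` receives its own SFUI
    even though its normalized form ``"oc"`` may be shared.  Numbering is by
    first occurrence in record order, so the assignment is deterministic.
    """
    if which not in ("short_form", "long_form"):
        raise ValueError(f"which must be 'short_form' or 'long_form', got {which!r}")
    for rec in inv.records:
        if not rec.record_id:
            raise ValueError("assign record ids before string ids")
    registry = IdRegistry("S" if which == "short_form" else "L")
    for rec in inv.records:
        if which == "short_form":
            rec.sfui = registry.assign(rec.sf)
        else:
            rec.lfui = registry.assign(rec.lf)
    return inv
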