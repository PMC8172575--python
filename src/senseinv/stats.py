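"""Summary statistics of a harmonized inventory.

After cross-mapping, the interesting quantities are counts of records,
unique short forms (normalized), unique long forms, unique (SF, LF) pairs
and synonym groups, plus the ambiguity profile: how many senses — i.e.
synonym groups — each abbreviation has.  Rounding follows "half away from
zero" at the printed precision.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io import SenseInventory


@dataclass(frozen=True)
class InventoryStats:
    n_records: int
    n_unique_sf: int
    n_unique_lf: int
    n_unique_pairs: int
    n_groups: int
    n_records_without_synonyms: int
    mean_senses_per_sf: float
    max_senses: int
    argmax_sf: str
    n_sf_multi_sense: int
    n_sf_four_plus: int


def share_percent(numerator: int, denominator: int) -> int:
    """``round(100 * numerator / denominator)``, half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("share_percent denominator must be non-zero")
    x = 100 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mean_senses(n_groups: int, n_unique_sf: int, decimals: int = 2) -> float:
    """Groups per unique short form, rounded half away from zero."""
    if n_unique_sf == 0:
        raise ZeroDivisionError("mean_senses denominator must be non-zero")
    q = Decimal(n_groups) / Decimal(n_unique_sf)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def lookup_reduction_percent(n_records: int, n_groups: int) -> int:
    """Percent reduction in linear lookups from using group identifiers.

    With G groups for R records, scanning groups instead of records saves
    ``100 * (1 - G/R)`` percent.
    """
    if not n_records >= n_groups > 0:
        raise ValueError(f"need n_records >= n_groups > 0, got ({n_records}, {n_groups})")
    return share_percent(n_records - n_groups, n_records)


def summarize(inv: SenseInventory) -> InventoryStats:
    """Compute all inventory statistics; requires group ids assigned."""
    if not inv.records:
        raise ValueError("cannot summarize an empty inventory")
    for rec in inv.records:
        if not rec.group_id:
            raise ValueError(f"record {rec.record_id or rec.sf!r} lacks a group id")

    group_sizes = Counter(rec.group_id for rec in inv.records)
    groups_per_sf: dict[str, set[str]] = {}
    for rec in inv.records:
        groups_per_sf.setdefault(rec.norm_sf, set()).add(rec.group_id)
    sense_counts = {sf: len(gids) for sf, gids in groups_per_sf.items()}
    argmax_sf = max(sense_counts, key=lambda sf: (sense_counts[sf], sf))

    n_groups = len(group_sizes)
    n_unique_sf = len(groups_per_sf)
    return InventoryStats(
        n_records=len(inv.records),
        n_unique_sf=n_unique_sf,
        n_unique_lf=len({rec.lf for rec in inv.records}),
        n_unique_pairs=len({(rec.sf, rec.lf) for rec in inv.records}),
        n_groups=n_groups,
        n_records_without_synonyms=sum(
            1 for rec in inv.records if group_sizes[rec.group_id] == 1
        ),
        mean_senses_per_sf=mean_senses(n_groups, n_unique_sf),
        max_senses=sense_counts[argmax_sf],
        argmax_sf=argmax_sf,
        n_sf_multi_sense=sum(1 for c in sense_counts.values() if c > 1),
        n_sf_four_plus=sum(1 for c in sense_counts.values() if c >= 4),
    )
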