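"""Coverage of an inventory against an annotated corpus of abbreviation uses.

An annotated corpus is a list of abbreviation *instances* observed in text:
the surface token, its normalized short form, and optionally the sense in
use (as normalized long-form text).  Two families of metrics:

- *abbreviation coverage*: is the abbreviation present in the inventory at
  all (normalized short form membership)?
- *sense coverage*: is the specific sense of this instance present for that
  abbreviation (normalized long-form match within the short-form block, or
  group membership when synonym groups are assigned)?

Each comes in a *macro* flavour (compute per abbreviation, then average
with equal weight — rare abbreviations count as much as frequent ones) and
a *micro* flavour (every instance counts independently — frequency
weighted).  Macro abbreviation coverage over a Zipf-distributed corpus is
the hard metric: the long tail of rare abbreviations dominates it.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io import NULL_MARKER, SenseInventory
from .normalization import normalize_short_form


@dataclass(frozen=True)
class AnnotatedInstance:
    """One observed abbreviation use: surface token, normalized SF, optional sense."""

    surface: str
    norm_sf: str
    sense: str = ""

    def __post_init__(self) -> None:
        expected = normalize_short_form(self.surface)
        if self.norm_sf != expected:
            raise ValueError(
                f"norm_sf {self.norm_sf!r} does not match normalize_short_form"
                f"({self.surface!r}) = {expected!r}"
            )


@dataclass(frozen=True)
class CoverageReport:
    """The four coverage metrics; sense metrics are None when no labels exist."""

    abbrev_macro: float
    abbrev_micro: float
    sense_macro: float | None
    sense_micro: float | None


def abbreviation_coverage(
    corpus: Sequence[AnnotatedInstance], inv: SenseInventory
) -> tuple[float, float]:
    """(macro, micro) fraction of corpus abbreviations found in the inventory."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    known = {rec.norm_sf for rec in inv.records}
    covered = [inst.norm_sf in known for inst in corpus]
    micro = sum(covered) / len(corpus)
    per_sf = {inst.norm_sf: inst.norm_sf in known for inst in corpus}
    macro = sum(per_sf.values()) / len(per_sf)
    return macro, micro


def _sense_covered(inst: AnnotatedInstance, inv: SenseInventory, use_groups: bool) -> bool:
    if use_groups:
        # sense covered if some group both contains the abbreviation and a
        # record whose normalized long form equals the annotated sense
        sfs_by_group: dict[str, set[str]] = defaultdict(set)
        lfs_by_group: dict[str, set[str]] = defaultdict(set)
        for rec in inv.records:
            sfs_by_group[rec.group_id].add(rec.norm_sf)
            lfs_by_group[rec.group_id].add(rec.norm_lf)
        return any(
            inst.norm_sf in sfs_by_group[gid] and inst.sense in lfs_by_group[gid]
            for gid in sfs_by_group
        )
    return any(
        rec.norm_sf == inst.norm_sf and rec.norm_lf == inst.sense
        for rec in inv.records
    )


def sense_coverage(
    corpus: Sequence[AnnotatedInstance],
    inv: SenseInventory,
    use_groups: bool = False,
) -> tuple[float, float]:
    """(macro, micro) fraction of sense-labeled instances whose sense is known.

    Micro is over all labeled instances; macro averages, over distinct
    abbreviations with labeled instances, each abbreviation's per-instance
    covered fraction.
    """
    labeled = [inst for inst in corpus if inst.sense]
    if not labeled:
        raise ValueError("corpus has no sense-labeled instances")
    # precompute (norm_sf, sense) coverage once per distinct key
    cache: dict[tuple[str, str], bool] = {}
    per_sf_counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])  # covered, total
    n_covered = 0
    for inst in labeled:
        key = (inst.norm_sf, inst.sense)
        if key not in cache:
            cache[key] = _sense_covered(inst, inv, use_groups)
        hit = cache[key]
        n_covered += hit
        per_sf_counts[inst.norm_sf][0] += hit
        per_sf_counts[inst.norm_sf][1] += 1
    micro = n_covered / len(labeled)
    macro = sum(c / t for c, t in per_sf_counts.values()) / len(per_sf_counts)
    return macro, micro


def coverage_report(
    corpus: Sequence[AnnotatedInstance],
    inv: SenseInventory,
    use_groups: bool = False,
) -> CoverageReport:
    """All four metrics at once; sense metrics None without sense labels."""
    abbrev_macro, abbrev_micro = abbreviation_coverage(corpus, inv)
    if any(inst.sense for inst in corpus):
        sense_macro, sense_micro = sense_coverage(corpus, inv, use_groups)
    else:
        sense_macro = sense_micro = None
    return CoverageReport(abbrev_macro, abbrev_micro, sense_macro, sense_micro)


def read_corpus(path: str | Path, delimiter: str = "\t") -> list[AnnotatedInstance]:
    """Read an annotated corpus TSV with columns surface, norm_sf, sense."""
    instances = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for row in reader:
            instances.append(
                AnnotatedInstance(
                    surface=row["surface"],
                    norm_sf=row["norm_sf"],
                    sense=row.get("sense") or "",
                )
            )
    return instances


def write_corpus(
    corpus: Sequence[AnnotatedInstance], path: str | Path, delimiter: str = "\t"
) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["surface", "norm_sf", "sense"])
        for inst in corpus:
            writer.writerow([inst.surface, inst.norm_sf, inst.sense])
    return path
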