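"""Heuristic quality control: flagging and the modify/retire workflow.

Source inventories carry errors.  Four rule-based heuristics flag records
for human review:

1. ``duplicate`` — exact (SF, LF) duplicates within the same source; the
   first occurrence is kept, later ones flagged.
2. ``punctuation`` — excessive or misplaced punctuation in the short form
   (e.g. ``"..MS"``): a leading punctuation run, a trailing run other than
   a single period, or two or more consecutive punctuation characters.
   Each sub-rule can be toggled off.
3. ``char_mismatch`` — an alphanumeric character of the short form never
   occurs in the long form (case-insensitive membership), e.g. the "q" of
   ``("qd", "every day")``.
4. ``spelling`` — an alphabetic long-form token of length >= 4 is absent
   from a reference word corpus.  Advisory only: nothing is auto-corrected.

Flags feed a review step whose outcome is a list of actions: ``keep``,
``modify`` (corrected fields, normalized forms recomputed, the record marked
"modified") or ``retire`` (record moved intact to a side inventory).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io import MODIFIED_FLAG, SenseInventory
from .normalization import (
    DEFAULT_CONFIG,
    NormalizationConfig,
    normalize_long_form,
    normalize_short_form,
)


class Heuristic(str, Enum):
    DUPLICATE = "duplicate"
    PUNCTUATION = "punctuation"
    CHAR_MISMATCH = "char_mismatch"
    SPELLING = "spelling"


class Action(str, Enum):
    KEEP = "keep"
    MODIFY = "modify"
    RETIRE = "retire"


@dataclass(frozen=True)
class QCFlag:
    record_id: str
    heuristic: Heuristic
    detail: str


@dataclass(frozen=True)
class QCAction:
    record_id: str
    action: Action
    corrected_sf: str = ""
    corrected_lf: str = ""

    def __post_init__(self) -> None:
        if self.action == Action.MODIFY and not (self.corrected_sf or self.corrected_lf):
            raise ValueError("modify action requires a corrected SF or LF")


@dataclass(frozen=True)
class PunctuationRules:
    """Toggles for the three punctuation sub-rules."""

    leading_run: bool = True
    trailing_run: bool = True
    consecutive: bool = True


_PUNCT_CHAR = re.compile(r"[^\w\s]")
_ALNUM = re.compile(r"[0-9a-z]")
_ALPHA_TOKEN = re.compile(r"^[a-z]+$")


def flag_intra_source_duplicates(inv: SenseInventory) -> list[QCFlag]:
    """Flag later occurrences of identical raw (source, SF, LF) triples."""
    seen: set[tuple[str, str, str]] = set()
    flags = []
    for rec in inv.records:
        key = (rec.source, rec.sf, rec.lf)
        if key in seen:
            flags.append(
                QCFlag(rec.record_id, Heuristic.DUPLICATE,
                       f"duplicate of earlier {rec.sf!r}/{rec.lf!r} in {rec.source}")
            )
        else:
            seen.add(key)
    return flags


def flag_punctuation(sf: str, rules: PunctuationRules = PunctuationRules()) -> str | None:
    """Detail string when the short form has excessive/misplaced punctuation."""
    s = sf.strip()
    if not s:
        return None
    is_punct = [bool(_PUNCT_CHAR.match(c)) for c in s]
    if rules.leading_run and is_punct[0]:
        return f"leading punctuation in {sf!r}"
    if rules.trailing_run and is_punct[-1] and s[-1] != ".":
        return f"trailing punctuation in {sf!r}"
    if rules.consecutive:
        for a, b in zip(is_punct, is_punct[1:]):
            if a and b:
                return f"consecutive punctuation in {sf!r}"
    return None


def flag_char_mismatch(sf: str, lf: str) -> str | None:
    """Detail string when SF has alphanumerics never occurring in LF."""
    lf_chars = set(lf.casefold())
    missing = sorted(
        {c for c in sf.casefold() if _ALNUM.match(c) and c not in lf_chars}
    )
    if missing:
        return f"short-form characters {missing} absent from long form"
    return None


def flag_spelling(
    lf: str, corpus: Iterable[str], min_len: int = 4
) -> str | None:
    """Detail string listing alphabetic LF tokens (len >= min_len) not in corpus."""
    corpus = corpus if isinstance(corpus, (set, frozenset)) else set(corpus)
    if not corpus:
        raise ValueError("spell-check corpus must be non-empty")
    unknown = [
        tok
        for tok in lf.casefold().split()
        if len(tok) >= min_len and _ALPHA_TOKEN.match(tok) and tok not in corpus
    ]
    if unknown:
        return f"tokens not in word corpus: {unknown}"
    return None


def run_qc(
    inv: SenseInventory,
    corpus: Iterable[str],
    punctuation_rules: PunctuationRules = PunctuationRules(),
    min_token_len: int = 4,
) -> list[QCFlag]:
    """Run all four heuristics; flags in record order, heuristic order."""
    corpus = set(corpus)
    duplicate_ids = {f.record_id for f in flag_intra_source_duplicates(inv)}
    flags: list[QCFlag] = []
    for rec in inv.records:
        if rec.record_id in duplicate_ids:
            flags.append(
                QCFlag(rec.record_id, Heuristic.DUPLICATE,
                       f"duplicate of earlier {rec.sf!r}/{rec.lf!r} in {rec.source}")
            )
        detail = flag_punctuation(rec.sf, punctuation_rules)
        if detail:
            flags.append(QCFlag(rec.record_id, Heuristic.PUNCTUATION, detail))
        detail = flag_char_mismatch(rec.sf, rec.lf)
        if detail:
            flags.append(QCFlag(rec.record_id, Heuristic.CHAR_MISMATCH, detail))
        detail = flag_spelling(rec.lf, corpus, min_token_len)
        if detail:
            flags.append(QCFlag(rec.record_id, Heuristic.SPELLING, detail))
    return flags


def apply_actions(
    inv: SenseInventory,
    actions: Sequence[QCAction],
    cfg: NormalizationConfig = DEFAULT_CONFIG,
) -> tuple[SenseInventory, SenseInventory]:
    """Apply review actions, returning (active, retired) inventories.

    Retired records move intact to the retired inventory; modified records
    get their corrected fields, recomputed normalized forms and the
    "modified" mark.  Records without an action are kept.  Actions whose
    record id is not present (e.g. already retired) are no-ops, which makes
    the operation idempotent for a fixed action list.
    """
    by_id: dict[str, QCAction] = {}
    for action in actions:
        by_id[action.record_id] = action
    active = SenseInventory(
        records=[],
        source_order=list(inv.source_order),
        aux_schema={s: list(c) for s, c in inv.aux_schema.items()},
    )
    retired = SenseInventory(
        records=[],
        source_order=list(inv.source_order),
        aux_schema={s: list(c) for s, c in inv.aux_schema.items()},
    )
    for rec in inv.records:
        action = by_id.get(rec.record_id)
        if action is None or action.action == Action.KEEP:
            active.records.append(rec.copy())
            continue
        if action.action == Action.RETIRE:
            retired.records.append(rec.copy())
            continue
        updated = rec.copy()
        if action.corrected_sf:
            updated.sf = action.corrected_sf
        if action.corrected_lf:
            updated.lf = action.corrected_lf
        updated.norm_sf = normalize_short_form(updated.sf)
        updated.norm_lf = normalize_long_form(updated.lf, cfg)
        updated.modified = MODIFIED_FLAG
        active.records.append(updated)
    return active, retired
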