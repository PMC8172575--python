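"""Candidate-pair generation for synonym cross-mapping.

Cross-mapping is framed as pairwise comparison.  Two stages produce pairs:

- *Training candidates*: all record pairs whose long forms have plain
  Levenshtein ratio strictly above a threshold (default 0.8).  Pairs sharing
  a normalized short form are *potential positives* (likely synonyms); pairs
  with different short forms are *pertinent negatives* — highly similar yet
  non-synonymous, the hard negatives a classifier must learn to reject.
  A small fraction is sampled for manual annotation.

- *Prediction candidates*: pairs are blocked on the normalized short form
  (synonymy is only defined within one abbreviation) and kept when the
  partial Levenshtein ratio of their pairing-normalized long forms meets a
  threshold (default 0.5).

Pairs are canonical: ``record_id_a < record_id_b``, no self pairs, no
duplicates, so candidate sets are invariant under record reordering.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .features import levenshtein_ratio, partial_ratio
from .io import NULL_MARKER, SenseInventory
from .normalization import DEFAULT_CONFIG, NormalizationConfig, normalize_for_pairing


@dataclass(frozen=True)
class CandidatePair:
    """A canonical pair of record identifiers with its prefilter score."""

    record_id_a: str
    record_id_b: str
    same_short_form: bool
    prefilter_score: float

    def __post_init__(self) -> None:
        if not self.record_id_a < self.record_id_b:
            raise ValueError("pair must be canonically ordered: record_id_a < record_id_b")
        if not 0.0 <= self.prefilter_score <= 1.0:
            raise ValueError("prefilter_score must be in [0, 1]")


def _make_pair(id_a: str, id_b: str, same_sf: bool, score: float) -> CandidatePair:
    if id_b < id_a:
        id_a, id_b = id_b, id_a
    return CandidatePair(id_a, id_b, same_sf, score)


def _comparison_text(rec) -> str:
    """Long-form text used for similarity: NormLF, falling back to raw LF."""
    return rec.norm_lf if rec.norm_lf and rec.norm_lf != NULL_MARKER else rec.lf.lower()


def generate_training_candidates(
    inv: SenseInventory, ratio_threshold: float = 0.8
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    """All-pairs Levenshtein filter splitting potential positives from
    pertinent negatives.

    Pairs of long forms with ratio strictly greater than ``ratio_threshold``
    are kept; those sharing a normalized short form go to the positives
    list, the rest to the pertinent-negatives list.  Exact all-pairs
    comparison: intended for desk-scale inventories.
    """
    for rec in inv.records:
        if not rec.record_id:
            raise ValueError("records need identifiers before candidate generation")
        if not rec.norm_sf:
            raise ValueError("records need normalized short forms before candidate generation")
    positives: list[CandidatePair] = []
    negatives: list[CandidatePair] = []
    records = inv.records
    texts = [_comparison_text(r) for r in records]
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            score = levenshtein_ratio(texts[i], texts[j])
            if score > ratio_threshold:
                same_sf = records[i].norm_sf == records[j].norm_sf
                pair = _make_pair(records[i].record_id, records[j].record_id, same_sf, score)
                (positives if same_sf else negatives).append(pair)
    return positives, negatives


def sample_for_annotation(
    pairs: Sequence[CandidatePair], fraction: float = 0.01, seed: int = 0
) -> list[CandidatePair]:
    """Uniform sample without replacement of ``ceil(fraction * n)`` pairs."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not pairs:
        return []
    size = math.ceil(fraction * len(pairs))
    rng = random.Random(seed)
    return rng.sample(list(pairs), size)


def generate_candidate_pairs(
    inv: SenseInventory,
    partial_threshold: float = 0.5,
    cfg: NormalizationConfig = DEFAULT_CONFIG,
) -> list[CandidatePair]:
    """Blocked candidate pairs for prediction.

    Records are blocked on the normalized short form; within each block
    every pair whose pairing-normalized long forms reach the partial-ratio
    threshold is emitted once, in canonical order.
    """
    blocks: dict[str, list] = {}
    for rec in inv.records:
        if not rec.norm_sf:
            raise ValueError("records need normalized short forms before candidate generation")
        blocks.setdefault(rec.norm_sf, []).append(rec)
    out: list[CandidatePair] = []
    for norm_sf in sorted(blocks):
        block = blocks[norm_sf]
        texts = [normalize_for_pairing(_comparison_text(r), cfg) for r in block]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                score = partial_ratio(texts[i], texts[j])
                if score >= partial_threshold:
                    out.append(
                        _make_pair(block[i].record_id, block[j].record_id, True, score)
                    )
    out.sort(key=lambda p: (p.record_id_a, p.record_id_b))
    return out
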