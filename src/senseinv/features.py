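"""String-similarity features for synonym classification.

Five metrics are computed per candidate pair of long forms, each a ratio in
``[0, 1]`` and symmetric in its arguments:

1. *Levenshtein ratio* — indel-normalized similarity
   ``1 - indel(a, b) / (|a| + |b|)`` where ``indel`` is the edit distance
   with unit insertions/deletions and substitution cost 2 (equivalently
   ``|a| + |b| - 2·LCS``).  This is the convention shared by the whole
   partial/token-sort/token-set metric family.
2. *partial ratio* — best Levenshtein ratio of the shorter string against
   any contiguous window of the longer string of the same length.
3. *token-sort ratio* — Levenshtein ratio after tokenizing on whitespace,
   sorting the tokens and rejoining with single spaces.
4. *token-set ratio* — with t0 the sorted token intersection, t1 = t0 plus
   tokens unique to ``a`` and t2 = t0 plus tokens unique to ``b`` (sorted,
   space-joined): the maximum pairwise Levenshtein ratio among t0/t1/t2.
5. *numeric similarity* — multiset Jaccard over the maximal digit runs of
   each string; two strings with no digits at all score 1 (numeric-free
   pairs are neutral, "type 1" vs "type 2" score 0).

:func:`featurize_pair` applies the pre-pairing replacement table (roman
numerals, ions) to both strings before computing all five.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .normalization import DEFAULT_CONFIG, NormalizationConfig, normalize_for_pairing

FEATURE_NAMES = (
    "ratio",
    "partial_ratio",
    "token_sort_ratio",
    "token_set_ratio",
    "numeric_similarity",
)

_DIGIT_RUN_RE = re.compile(r"[0-9]+")


@dataclass(frozen=True)
class PairFeatures:
    """The five-element similarity feature vector of one candidate pair."""

    ratio: float
    partial_ratio: float
    token_sort_ratio: float
    token_set_ratio: float
    numeric_similarity: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.ratio,
            self.partial_ratio,
            self.token_sort_ratio,
            self.token_set_ratio,
            self.numeric_similarity,
        )


def _lcs_length(a: str, b: str) -> int:
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        append = cur.append
        for j, cb in enumerate(b, 1):
            if ca == cb:
                append(prev[j - 1] + 1)
            else:
                pj, cl = prev[j], cur[-1]
                append(pj if pj >= cl else cl)
        prev = cur
    return prev[-1]


def levenshtein_ratio(a: str, b: str) -> float:
    """Indel-normalized similarity of two strings; both empty -> 1.0."""
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    distance = total - 2 * _lcs_length(a, b)
    return 1.0 - distance / total


def partial_ratio(a: str, b: str) -> float:
    """Best window match of the shorter string inside the longer one."""
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    if len(shorter) == len(longer):
        return levenshtein_ratio(a, b)
    if not shorter:
        return 1.0
    n = len(shorter)
    return max(
        levenshtein_ratio(shorter, longer[i : i + n])
        for i in range(len(longer) - n + 1)
    )


def _tokens(s: str) -> list[str]:
    return s.lower().split()


def token_sort_ratio(a: str, b: str) -> float:
    """Levenshtein ratio on sorted-token rejoins (word order insensitive)."""
    return levenshtein_ratio(" ".join(sorted(_tokens(a))), " ".join(sorted(_tokens(b))))


def token_set_ratio(a: str, b: str) -> float:
    """Levenshtein ratio family maximum over intersection/remainder joins."""
    ta, tb = set(_tokens(a)), set(_tokens(b))
    inter = sorted(ta & tb)
    t0 = " ".join(inter)
    t1 = " ".join(inter + sorted(ta - tb))
    t2 = " ".join(inter + sorted(tb - ta))
    return max(
        levenshtein_ratio(t0, t1),
        levenshtein_ratio(t0, t2),
        levenshtein_ratio(t1, t2),
    )


def numeric_similarity(a: str, b: str) -> float:
    """Multiset Jaccard of maximal digit runs; both digit-free -> 1.0."""
    runs_a = Counter(_DIGIT_RUN_RE.findall(a))
    runs_b = Counter(_DIGIT_RUN_RE.findall(b))
    if not runs_a and not runs_b:
        return 1.0
    intersection = sum((runs_a & runs_b).values())
    union = sum((runs_a | runs_b).values())
    return intersection / union


def featurize_pair(
    lf_a: str, lf_b: str, cfg: NormalizationConfig = DEFAULT_CONFIG
) -> PairFeatures:
    """Pairing-normalize both long forms, then compute all five metrics."""
    na = normalize_for_pairing(lf_a, cfg)
    nb = normalize_for_pairing(lf_b, cfg)
    return PairFeatures(
        ratio=levenshtein_ratio(na, nb),
        partial_ratio=partial_ratio(na, nb),
        token_sort_ratio=token_sort_ratio(na, nb),
        token_set_ratio=token_set_ratio(na, nb),
        numeric_similarity=numeric_similarity(na, nb),
    )
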