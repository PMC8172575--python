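"""Lexical normalization of short forms and long forms.

Short forms are canonicalized with the CARD-style rules: lowercase, strip
surrounding whitespace, delete periods, map every remaining non-alphanumeric
character to an underscore (``"O.C." -> "oc"``, ``"D/C" -> "d_c"``).

Long forms go through a rule-driven re-implementation of the LVG
normalization flow, with the steps applied in this fixed order and the token
order preserved (no alphabetical sorting)::

    g   remove genitives            ("patient's" -> "patient")
    rs  strip plural forms          ("contraceptives" -> "contraceptive")
    o   replace punctuation         ("x-ray" -> "x ray")
    t   remove stop words           ("coarctation of the aorta" -> "coarctation aorta")
    l   lowercase
    B   uninflect                   ("filled" -> "fill")
    Ct  map synonyms                (configurable, empty by default)

The rule tables (stop words, suffix rewrites, synonym map) are deliberately
small, pinned defaults living in :class:`NormalizationConfig`; they
approximate the behaviour of the full LVG toolset, whose exact tables are
external.  When normalization consumes the whole string (all periods, all
stop words, non-Latin text) the literal null marker ``"null"`` is returned.

A third, lighter normalization (:func:`normalize_for_pairing`) replaces
unusual textual features — roman numerals, common ion symbols — with plain
text before string-similarity comparison, so that e.g. "type II" and
"type 2" pair up.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .io import NULL_MARKER

DEFAULT_STOP_WORDS = frozenset(
    {"a", "an", "the", "of", "and", "with", "for", "in", "on", "to", "by"}
)

#: Genitive suffixes, tried in order; the bare apostrophe handles "patients'".
DEFAULT_GENITIVE_MARKERS = ("'s", "’s", "'", "’")

#: Ordered plural suffix rewrites; first match wins.
DEFAULT_PLURAL_RULES = (
    ("ies", "y"),
    ("sses", "ss"),
    ("ches", "ch"),
    ("shes", "sh"),
    ("xes", "x"),
    ("zes", "z"),
    ("s", ""),
)

#: Words whose trailing "s"/"es" is not a plural marker.
DEFAULT_PLURAL_EXCEPTIONS = frozenset(
    {"diabetes", "herpes", "series", "species", "mellitus", "pertussis"}
)

#: Ordered inflection suffix rewrites (the LVG "B" step); first match wins.
DEFAULT_UNINFLECT_RULES = (
    ("ied", "y"),
    ("ing", ""),
    ("ed", ""),
)

#: Token replacements applied before pairing: roman numerals i-x to digits,
#: five common ion symbols to element names.  Fully overridable.
DEFAULT_REPLACEMENTS = {
    "i": "1",
    "ii": "2",
    "iii": "3",
    "iv": "4",
    "v": "5",
    "vi": "6",
    "vii": "7",
    "viii": "8",
    "ix": "9",
    "x": "10",
    "na+": "sodium",
    "k+": "potassium",
    "ca2+": "calcium",
    "cl-": "chloride",
    "mg2+": "magnesium",
}

_PUNCT_RE = re.compile(r"[^0-9A-Za-z\s]")
_SF_NON_WORD_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizationConfig:
    """Rule tables driving long-form normalization and pairing replacement."""

    stop_words: frozenset[str] = DEFAULT_STOP_WORDS
    genitive_markers: tuple[str, ...] = DEFAULT_GENITIVE_MARKERS
    plural_rules: tuple[tuple[str, str], ...] = DEFAULT_PLURAL_RULES
    plural_exceptions: frozenset[str] = DEFAULT_PLURAL_EXCEPTIONS
    uninflect_rules: tuple[tuple[str, str], ...] = DEFAULT_UNINFLECT_RULES
    synonym_map: dict[str, str] = field(default_factory=dict)
    replacement_table: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REPLACEMENTS)
    )

    def __post_init__(self) -> None:
        for word, canon in self.synonym_map.items():
            if canon in self.synonym_map and self.synonym_map[canon] != canon:
                raise ValueError(f"synonym map not idempotent at {word!r} -> {canon!r}")


DEFAULT_CONFIG = NormalizationConfig()


def normalize_short_form(sf: str) -> str:
    """CARD-style short-form normalization; returns "null" if nothing remains."""
    s = sf.strip().lower()
    s = s.replace(".", "")
    s = _SF_NON_WORD_RE.sub("_", s)
    s = _WS_RE.sub("_", s.strip())
    return s if s else NULL_MARKER


def _strip_genitive(token: str, cfg: NormalizationConfig) -> str:
    low = token.lower()
    for marker in cfg.genitive_markers:
        if low.endswith(marker) and len(token) > len(marker):
            return token[: len(token) - len(marker)]
    return token


def _strip_plural(token: str, cfg: NormalizationConfig) -> str:
    low = token.lower()
    if low in cfg.plural_exceptions or low.endswith(("ss", "us", "is")):
        return token
    for suffix, replacement in cfg.plural_rules:
        if low.endswith(suffix) and len(low) > len(suffix) + 1:
            return token[: len(token) - len(suffix)] + replacement
    return token


def _uninflect(token: str, cfg: NormalizationConfig) -> str:
    for suffix, replacement in cfg.uninflect_rules:
        if token.endswith(suffix):
            stem = token[: len(token) - len(suffix)] + replacement
            if len(stem) < 3:
                continue
            # doubled-consonant repair: "stopped" -> "stop"; keep ll/ss
            if (
                not replacement
                and len(stem) >= 4
                and stem[-1] == stem[-2]
                and stem[-1] not in "aeiouls"
            ):
                stem = stem[:-1]
            return stem
    return token


def normalize_long_form(lf: str, cfg: NormalizationConfig = DEFAULT_CONFIG) -> str:
    """LVG-style long-form normalization, token order preserved.

    Returns the null marker when the flow consumes the entire string.
    """
    tokens = lf.strip().split()
    tokens = [_strip_genitive(t, cfg) for t in tokens]                      # g
    tokens = [_strip_plural(t, cfg) for t in tokens]                        # rs
    text = _PUNCT_RE.sub(" ", " ".join(tokens))                             # o
    tokens = [t for t in text.split() if t.lower() not in cfg.stop_words]   # t
    tokens = [t.lower() for t in tokens]                                    # l
    tokens = [_uninflect(t, cfg) for t in tokens]                           # B
    tokens = [cfg.synonym_map.get(t, t) for t in tokens]                    # Ct
    result = " ".join(tokens)
    return result if result else NULL_MARKER


def normalize_for_pairing(text: str, cfg: NormalizationConfig = DEFAULT_CONFIG) -> str:
    """Lowercase and replace whole tokens found in the replacement table."""
    tokens = text.lower().split()
    return " ".join(cfg.replacement_table.get(t, t) for t in tokens)


def load_config(path: str | Path) -> NormalizationConfig:
    """Load a :class:`NormalizationConfig` from a plain-text rule file.

    One rule per line, ``kind: payload``; ``#`` starts a comment.  Kinds:

    - ``stopword: the``
    - ``genitive: 's``
    - ``plural: ies -> y``
    - ``plural_exception: diabetes``
    - ``uninflect: ed ->``
    - ``synonym: tumour -> tumor``
    - ``replace: ii -> 2``

    Any rule kind present in the file replaces that default table entirely.
    """
    tables: dict[str, list] = {
        "stopword": [],
        "genitive": [],
        "plural": [],
        "plural_exception": [],
        "uninflect": [],
        "synonym": [],
        "replace": [],
    }
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            kind, payload = line.split(":", 1)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 'kind: payload'") from None
        kind = kind.strip()
        if kind not in tables:
            raise ValueError(f"{path}:{lineno}: unknown rule kind {kind!r}")
        payload = payload.strip()
        if kind in ("plural", "uninflect", "synonym", "replace"):
            if "->" not in payload:
                raise ValueError(f"{path}:{lineno}: expected 'lhs -> rhs'")
            lhs, rhs = (part.strip() for part in payload.split("->", 1))
            tables[kind].append((lhs, rhs))
        else:
            tables[kind].append(payload)
    kwargs: dict = {}
    if tables["stopword"]:
        kwargs["stop_words"] = frozenset(tables["stopword"])
    if tables["genitive"]:
        kwargs["genitive_markers"] = tuple(tables["genitive"])
    if tables["plural"]:
        kwargs["plural_rules"] = tuple(tables["plural"])
    if tables["plural_exception"]:
        kwargs["plural_exceptions"] = frozenset(tables["plural_exception"])
    if tables["uninflect"]:
        kwargs["uninflect_rules"] = tuple(tables["uninflect"])
    if tables["synonym"]:
        kwargs["synonym_map"] = dict(tables["synonym"])
    if tables["replace"]:
        kwargs["replacement_table"] = dict(tables["replace"])
    return NormalizationConfig(**kwargs)


def normalize_inventory(inv, cfg: NormalizationConfig = DEFAULT_CONFIG):
    """Fill NormSF and NormLF for every record, in place; returns the inventory."""
    for rec in inv.records:
        rec.norm_sf = normalize_short_form(rec.sf)
        rec.norm_lf = normalize_long_form(rec.lf, cfg)
    return inv
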