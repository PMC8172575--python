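"""Synthetic multi-source sense inventories with known ground truth.

The generator emulates the situation the harmonization pipeline is built
for: several source inventories describe overlapping sets of underlying
*concepts* (abbreviation + canonical long form), each source writing the
same concept with its own lexical habits — case and period variants of the
short form; plural, genitive, inserted stop-word, word-order and
misspelling variants of the long form.  A configurable fraction of
concepts share an abbreviation with another concept (ambiguity, the "PA"
problem).  Known error types can be injected at chosen rates for testing
quality control, and a Zipf-distributed annotated corpus is drawn from the
same concepts for coverage evaluation.

Every concept is anchored in one "home" source that records it in
canonical form; other sources apply variants.  Ground truth (record ->
concept) and truth-consistent labeled pairs are recorded, so recovery of
the true synonym groups by the full pipeline is measurable.

All generation is deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .coverage import AnnotatedInstance
from .features import featurize_pair
from .identifiers import assign_record_ids, assign_string_ids
from .io import NULL_MARKER, Record, SenseInventory, merge_sources
from .model import LabeledPair
from .normalization import (
    DEFAULT_CONFIG,
    NormalizationConfig,
    normalize_long_form,
    normalize_short_form,
    normalize_inventory,
)
from .qc import Heuristic

#: Bundled vocabulary for building synthetic long forms.  Medical-flavoured
#: so that generated inventories look like the real inputs; no external
#: lexicon is needed.
VOCABULARY = (
    "abdominal", "acute", "adenocarcinoma", "admission", "airway", "albumin",
    "analysis", "anemia", "anterior", "aorta", "aortic", "arterial", "artery",
    "assessment", "asthma", "atrial", "bilateral", "biopsy", "blockade",
    "blood", "bowel", "brain", "cardiac", "carcinoma", "catheter", "cavity",
    "cell", "cerebral", "cervical", "chest", "chronic", "circulation",
    "clinical", "colon", "congestive", "coronary", "count", "cranial",
    "culture", "daily", "defect", "deficiency", "diagnosis", "dialysis",
    "disease", "disorder", "distal", "dose", "drainage", "duct", "edema",
    "ejection", "embolism", "emergency", "enzyme", "evaluation", "exam",
    "failure", "femoral", "fibrillation", "fluid", "fraction", "function",
    "gastric", "gland", "glucose", "graft", "heart", "hemoglobin", "hepatic",
    "hernia", "history", "hypertension", "imaging", "infarction", "infection",
    "infusion", "injection", "injury", "intensive", "internal", "kidney",
    "lateral", "left", "lesion", "liver", "lobe", "lower", "lumbar", "lung",
    "lymph", "magnetic", "marrow", "mass", "medial", "membrane", "mitral",
    "motor", "murmur", "muscle", "nasal", "necrosis", "nerve", "neural",
    "node", "normal", "obstruction", "oral", "output", "ovarian", "oxygen",
    "pancreatic", "partial", "patient", "pelvic", "peptide", "perfusion",
    "pressure", "procedure", "protein", "proximal", "pulmonary", "radial",
    "rate", "renal", "report", "resection", "respiratory", "review", "right",
    "rupture", "saline", "sample", "scan", "sclerosis", "screen", "segment",
    "seizure", "sepsis", "serum", "sodium", "spinal", "status", "stenosis",
    "sternal", "stress", "study", "surgery", "syndrome", "systolic", "test",
    "therapy", "thoracic", "tissue", "total", "tract", "transfusion",
    "trauma", "tumor", "ulcer", "unit", "upper", "urinary", "uterine",
    "valve", "vascular", "venous", "ventricular", "vessel", "volume",
)

_STOP_INSERTS = ("of", "the", "with", "for")
_SOURCE_PREFIX = "SYN"


@dataclass(frozen=True)
class Concept:
    """One underlying meaning: canonical abbreviation + canonical long form."""

    concept_id: str
    abbrev: str
    long_form: str


@dataclass(frozen=True)
class ConceptBank:
    concepts: tuple[Concept, ...]
    zipf_exponent: float = 1.1


@dataclass(frozen=True)
class VariantRates:
    """Per-record probabilities of each lexical variant."""

    sf_case: float = 0.3
    sf_periods: float = 0.2
    lf_plural: float = 0.25
    lf_genitive: float = 0.05
    lf_stopword: float = 0.15
    lf_token_swap: float = 0.1
    lf_misspell: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"variant rate {name}={value} outside [0, 1]")


@dataclass(frozen=True)
class ErrorRates:
    """Per-record probabilities of each injected quality-control error."""

    duplicate: float = 0.0
    punctuation: float = 0.0
    char_mismatch: float = 0.0
    spelling: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"error rate {name}={value} outside [0, 1]")


@dataclass
class FixtureBundle:
    """Everything a pipeline test needs, with ground truth attached."""

    inventories: list[SenseInventory]
    merged: SenseInventory
    truth_groups: dict[str, str]            # record id -> concept id
    labeled_pairs: list[LabeledPair]
    injected_errors: list[tuple[str, Heuristic]]
    word_corpus: set[str]
    corpus: list[AnnotatedInstance] = field(default_factory=list)


def generate_concept_bank(
    n_concepts: int,
    ambiguity_rate: float = 0.2,
    seed: int = 0,
    zipf_exponent: float = 1.1,
) -> ConceptBank:
    """Draw concepts with unique long forms and controlled SF ambiguity.

    Roughly ``ambiguity_rate`` of concepts reuse the abbreviation of an
    earlier concept (with a different long form); the rest get distinct
    abbreviations built from the initials of their words.
    """
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    if not 0.0 <= ambiguity_rate < 1.0:
        raise ValueError(f"ambiguity_rate must be in [0, 1), got {ambiguity_rate}")
    rng = random.Random(seed)
    by_initial: dict[str, list[str]] = {}
    for word in VOCABULARY:
        by_initial.setdefault(word[0], []).append(word)
    concepts: list[Concept] = []
    used_abbrevs: list[str] = []
    used_lfs: set[tuple[str, ...]] = set()
    for i in range(n_concepts):
        ambiguous = bool(used_abbrevs) and rng.random() < ambiguity_rate
        for _ in range(1000):
            if ambiguous:
                # a different sense of an existing abbreviation: words are
                # re-drawn so their initials still spell the abbreviation
                abbrev = rng.choice(used_abbrevs)
                words = tuple(rng.choice(by_initial[c.lower()]) for c in abbrev)
                if len(set(words)) != len(words):
                    continue
            else:
                words = tuple(rng.sample(VOCABULARY, rng.randint(2, 4)))
                abbrev = "".join(w[0] for w in words).upper()
                if abbrev in used_abbrevs:
                    continue
            if words in used_lfs:
                continue
            break
        else:  # pragma: no cover - vocabulary is large enough in practice
            raise RuntimeError("could not draw a fresh concept")
        used_lfs.add(words)
        if abbrev not in used_abbrevs:
            used_abbrevs.append(abbrev)
        concepts.append(
            Concept(concept_id=f"C{i + 1:06d}", abbrev=abbrev, long_form=" ".join(words))
        )
    return ConceptBank(concepts=tuple(concepts), zipf_exponent=zipf_exponent)


def _sf_variant(abbrev: str, rates: VariantRates, rng: random.Random) -> str:
    sf = abbrev
    if rng.random() < rates.sf_case:
        sf = sf.lower()
    if rng.random() < rates.sf_periods and sf.isalpha():
        sf = "".join(c + "." for c in sf)
    return sf


def _misspell(token: str, rng: random.Random, corpus: set[str] | None) -> str:
    """Perturb an interior character; never the first, so SF initials survive."""
    for _ in range(50):
        i = rng.randrange(1, len(token))
        kind = rng.random()
        if kind < 0.5:
            mutated = token[:i] + rng.choice("abcdefghijklmnopqrstuvwxyz") + token[i + 1 :]
        elif kind < 0.75 and len(token) > 4:
            mutated = token[:i] + token[i + 1 :]
        else:
            mutated = token[:i] + token[i] + token[i:]
        if mutated != token and (corpus is None or mutated.lower() not in corpus):
            return mutated
    return token + "zq"  # pragma: no cover - fallback for pathological corpora


def _lf_variant(long_form: str, rates: VariantRates, rng: random.Random) -> str:
    tokens = long_form.split()
    if rng.random() < rates.lf_plural and not tokens[-1].endswith("s"):
        tokens[-1] += "s"
    if rng.random() < rates.lf_genitive:
        i = rng.randrange(len(tokens))
        if not tokens[i].endswith("s"):
            tokens[i] += "'s"
    if rng.random() < rates.lf_stopword and len(tokens) >= 2:
        tokens.insert(rng.randrange(1, len(tokens)), rng.choice(_STOP_INSERTS))
    if rng.random() < rates.lf_token_swap and len(tokens) >= 2:
        i = rng.randrange(len(tokens) - 1)
        tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
    if rng.random() < rates.lf_misspell:
        candidates = [i for i, t in enumerate(tokens) if len(t) >= 5 and t.isalpha()]
        if candidates:
            i = rng.choice(candidates)
            tokens[i] = _misspell(tokens[i], rng, None)
    return " ".join(tokens)


def generate_inventories(
    bank: ConceptBank,
    n_sources: int = 3,
    variant_rates: VariantRates | None = None,
    error_rates: ErrorRates | None = None,
    seed: int = 0,
    source_coverage: float = 0.7,
    cfg: NormalizationConfig = DEFAULT_CONFIG,
    n_corpus_instances: int = 200,
) -> FixtureBundle:
    """Generate per-source inventories, merge, normalize, assign identifiers.

    Each concept is recorded canonically in one home source and, with
    probability ``source_coverage``, as a lexical variant in each other
    source.  QC errors are injected at ``error_rates`` with ground truth
    recorded; labeled pairs are derived transitively from the truth.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rates = variant_rates or VariantRates()
    errors = error_rates or ErrorRates()
    rng = random.Random(seed)

    source_names = [f"{_SOURCE_PREFIX}{s + 1}" for s in range(n_sources)]
    home = {c.concept_id: rng.randrange(n_sources) for c in bank.concepts}

    # rows[s] holds (sf, lf, concept_id, error or None) before record ids exist
    rows: list[list[list]] = [[] for _ in range(n_sources)]
    for concept in bank.concepts:
        for s in range(n_sources):
            if s == home[concept.concept_id]:
                rows[s].append([concept.abbrev, concept.long_form, concept.concept_id, None])
            elif rng.random() < source_coverage:
                rows[s].append(
                    [
                        _sf_variant(concept.abbrev, rates, rng),
                        _lf_variant(concept.long_form, rates, rng),
                        concept.concept_id,
                        None,
                    ]
                )

    # the spell corpus reflects the clean fixture text
    word_corpus = {
        tok.lower()
        for source_rows in rows
        for _, lf, _, _ in source_rows
        for tok in lf.replace("'s", "").split()
        if tok.isalpha()
    }
    word_corpus.update(VOCABULARY)
    word_corpus.update(w + "s" for w in VOCABULARY)

    # error injection, ground truth recorded via the per-row error slot;
    # duplicates are appended after mutation so they stay exact copies
    for s in range(n_sources):
        injected: list[list] = []
        for row in rows[s]:
            if rng.random() < errors.punctuation:
                row[0] = ".." + row[0]
                row[3] = Heuristic.PUNCTUATION
            elif rng.random() < errors.char_mismatch:
                extra = next(c for c in "qzxj" if c not in row[1].lower())
                row[0] = row[0] + extra
                row[3] = Heuristic.CHAR_MISMATCH
            elif rng.random() < errors.spelling:
                tokens = row[1].split()
                candidates = [i for i, t in enumerate(tokens) if len(t) >= 4 and t.isalpha()]
                if candidates:
                    i = rng.choice(candidates)
                    tokens[i] = _misspell(tokens[i], rng, word_corpus)
                    row[1] = " ".join(tokens)
                    row[3] = Heuristic.SPELLING
            if rng.random() < errors.duplicate:
                injected.append([row[0], row[1], row[2], Heuristic.DUPLICATE])
        rows[s].extend(injected)

    inventories = [
        SenseInventory(
            records=[Record(sf=sf, lf=lf, source=name) for sf, lf, _, _ in source_rows],
            source_order=[name],
        )
        for name, source_rows in zip(source_names, rows)
    ]
    merged = merge_sources(inventories)
    normalize_inventory(merged, cfg)
    assign_record_ids(merged)
    assign_string_ids(merged, "short_form")
    assign_string_ids(merged, "long_form")

    flat = [row for source_rows in rows for row in source_rows]
    truth_groups = {rec.record_id: row[2] for rec, row in zip(merged.records, flat)}
    injected_errors = [
        (rec.record_id, row[3]) for rec, row in zip(merged.records, flat) if row[3] is not None
    ]

    labeled_pairs = _labeled_pairs_from_truth(merged, truth_groups, rng, cfg)
    corpus = generate_annotated_corpus(
        bank, n_instances=n_corpus_instances, labeled_fraction=1.0, seed=seed + 1, cfg=cfg
    )
    return FixtureBundle(
        inventories=inventories,
        merged=merged,
        truth_groups=truth_groups,
        labeled_pairs=labeled_pairs,
        injected_errors=injected_errors,
        word_corpus=word_corpus,
        corpus=corpus,
    )


def _comparison_text(rec) -> str:
    return rec.norm_lf if rec.norm_lf and rec.norm_lf != NULL_MARKER else rec.lf.lower()


def _labeled_pairs_from_truth(
    merged: SenseInventory,
    truth_groups: dict[str, str],
    rng: random.Random,
    cfg: NormalizationConfig,
) -> list[LabeledPair]:
    """All within-block pairs labeled from truth, plus cross-block negatives."""
    blocks: dict[str, list] = {}
    for rec in merged.records:
        blocks.setdefault(rec.norm_sf, []).append(rec)
    pairs: list[LabeledPair] = []
    for block in blocks.values():
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                a, b = block[i], block[j]
                label = int(truth_groups[a.record_id] == truth_groups[b.record_id])
                pairs.append(
                    LabeledPair(
                        pair_id=tuple(sorted((a.record_id, b.record_id))),
                        features=featurize_pair(_comparison_text(a), _comparison_text(b), cfg),
                        label=label,
                    )
                )
    n_extra = max(len(pairs) // 2, 10)
    records = merged.records
    for _ in range(n_extra):
        a, b = rng.sample(records, 2)
        if a.norm_sf == b.norm_sf:
            continue
        pairs.append(
            LabeledPair(
                pair_id=tuple(sorted((a.record_id, b.record_id))),
                features=featurize_pair(_comparison_text(a), _comparison_text(b), cfg),
                label=int(truth_groups[a.record_id] == truth_groups[b.record_id]),
            )
        )
    return pairs


def generate_annotated_corpus(
    bank: ConceptBank,
    n_instances: int,
    labeled_fraction: float = 1.0,
    seed: int = 0,
    cfg: NormalizationConfig = DEFAULT_CONFIG,
) -> list[AnnotatedInstance]:
    """Draw abbreviation instances with Zipf weights over the concept bank."""
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError(f"labeled_fraction must be in [0, 1], got {labeled_fraction}")
    rng = random.Random(seed)
    weights = [(rank + 1) ** -bank.zipf_exponent for rank in range(len(bank.concepts))]
    instances = []
    for _ in range(n_instances):
        concept = rng.choices(bank.concepts, weights=weights, k=1)[0]
        labeled = labeled_fraction >= 1.0 or rng.random() < labeled_fraction
        instances.append(
            AnnotatedInstance(
                surface=concept.abbrev,
                norm_sf=normalize_short_form(concept.abbrev),
                sense=normalize_long_form(concept.long_form, cfg) if labeled else "",
            )
        )
    return instances
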