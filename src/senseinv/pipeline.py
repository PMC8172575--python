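"""End-to-end harmonization: sources in, concept-oriented inventory out.

Stage order: merge -> lexical normalization -> R/S/L identifier assignment
-> quality-control flagging (actions applied only when supplied) ->
candidate generation -> feature computation -> synonym prediction at a
high-specificity threshold -> connected-component grouping -> G identifier
assignment -> summary statistics.  Two runs with identical inputs, config
and seeds produce identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import qc as qc_mod
from .candidates import CandidatePair, generate_candidate_pairs
from .features import featurize_pair
from .grouping import SenseGroup, assign_group_ids, build_groups
from .identifiers import assign_record_ids, assign_string_ids
from .io import NULL_MARKER, SenseInventory, merge_sources
from .model import (
    LabeledPair,
    SynonymClassifier,
    predict_pairs,
    select_threshold,
    train_classifier,
)
from .normalization import DEFAULT_CONFIG, NormalizationConfig, normalize_inventory
from .stats import InventoryStats, summarize


@dataclass
class PipelineConfig:
    """Thresholds, seeds and tables steering a harmonization run."""

    training_ratio_threshold: float = 0.8
    candidate_partial_threshold: float = 0.5
    probability_threshold: float | None = None  # None -> select from training data
    k_folds: int = 5
    target_precision: float = 0.99
    seed: int = 0
    backend: str = "lightgbm"
    model_params: dict | None = None
    normalization: NormalizationConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        for name in ("training_ratio_threshold", "candidate_partial_threshold", "target_precision"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.probability_threshold is not None and not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold outside [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class HarmonizeResult:
    inventory: SenseInventory
    groups: list[SenseGroup]
    stats: InventoryStats
    flags: list[qc_mod.QCFlag]
    threshold: float
    n_candidates: int
    n_positive_pairs: int
    report: dict


def _comparison_text(rec) -> str:
    return rec.norm_lf if rec.norm_lf and rec.norm_lf != NULL_MARKER else rec.lf.lower()


def run_harmonize(
    sources: Sequence[SenseInventory],
    cfg: PipelineConfig | None = None,
    model: SynonymClassifier | None = None,
    training_pairs: Sequence[LabeledPair] | None = None,
    qc_corpus: Sequence[str] | None = None,
    qc_actions: Sequence[qc_mod.QCAction] | None = None,
) -> HarmonizeResult:
    """Run the full harmonization pipeline over source inventories.

    Either a trained ``model`` or ``training_pairs`` to fit one must be
    supplied.  QC flags are always computed when a word corpus is given;
    actions are applied only when ``qc_actions`` is supplied.
    """
    cfg = cfg or PipelineConfig()
    if model is None and training_pairs is None:
        raise ValueError("supply a trained model or training pairs")

    inv = merge_sources(sources)
    normalize_inventory(inv, cfg.normalization)
    assign_record_ids(inv)
    assign_string_ids(inv, "short_form")
    assign_string_ids(inv, "long_form")

    flags: list[qc_mod.QCFlag] = []
    if qc_corpus is not None:
        flags = qc_mod.run_qc(inv, qc_corpus)
    if qc_actions:
        inv, _retired = qc_mod.apply_actions(inv, qc_actions, cfg.normalization)

    if model is None:
        model = train_classifier(
            training_pairs, params=cfg.model_params, seed=cfg.seed, backend=cfg.backend
        )
    threshold = cfg.probability_threshold
    if threshold is None:
        if training_pairs is None:
            raise ValueError("probability_threshold required when no training pairs are given")
        threshold = select_threshold(model, training_pairs, cfg.target_precision)

    candidate_pairs = generate_candidate_pairs(
        inv, cfg.candidate_partial_threshold, cfg.normalization
    )
    by_id = {rec.record_id: rec for rec in inv.records}
    featurized = [
        (
            pair,
            featurize_pair(
                _comparison_text(by_id[pair.record_id_a]),
                _comparison_text(by_id[pair.record_id_b]),
                cfg.normalization,
            ),
        )
        for pair in candidate_pairs
    ]
    predictions = predict_pairs(model, featurized, threshold)
    positive = [p.pair for p in predictions if p.is_synonym]

    groups = build_groups(inv, positive)
    groups = assign_group_ids(groups, inv)
    stats = summarize(inv)

    flag_counts: dict[str, int] = {}
    for flag in flags:
        flag_counts[flag.heuristic.value] = flag_counts.get(flag.heuristic.value, 0) + 1
    report = {
        "n_records": stats.n_records,
        "n_candidates": len(candidate_pairs),
        "n_positive_pairs": len(positive),
        "threshold": threshold,
        "flag_counts": flag_counts,
        "stats": stats,
    }
    return HarmonizeResult(
        inventory=inv,
        groups=groups,
        stats=stats,
        flags=flags,
        threshold=threshold,
        n_candidates=len(candidate_pairs),
        n_positive_pairs=len(positive),
        report=report,
    )
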