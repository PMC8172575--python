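import math
from collections import Counter

import pytest

import senseinv as si


class TestConceptBank:
    def test_zero_ambiguity_all_abbrevs_distinct(self):
        bank = si.generate_concept_bank(10, ambiguity_rate=0.0, seed=4)
        abbrevs = [c.abbrev for c in bank.concepts]
        assert len(set(abbrevs)) == 10

    def test_deterministic_under_seed(self):
        assert si.generate_concept_bank(100, 0.5, seed=9) == si.generate_concept_bank(
            100, 0.5, seed=9
        )

    def test_ambiguity_produces_shared_abbrevs(self):
        bank = si.generate_concept_bank(100, ambiguity_rate=0.5, seed=9)
        counts = Counter(c.abbrev for c in bank.concepts)
        assert max(counts.values()) >= 2

    def test_long_forms_unique(self):
        bank = si.generate_concept_bank(200, ambiguity_rate=0.3, seed=1)
        lfs = [c.long_form for c in bank.concepts]
        assert len(set(lfs)) == len(lfs)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            si.generate_concept_bank(10, ambiguity_rate=1.0, seed=0)
        with pytest.raises(ValueError):
            si.generate_concept_bank(0, 0.1, seed=0)


class TestGenerateInventories:
    def test_zero_error_rates_inject_nothing(self, clean_bundle):
        assert clean_bundle.injected_errors == []

    def test_zero_variants_give_cross_source_exact_duplicates(self, clean_bundle):
        # every concept present in both sources appears with identical text,
        # so its pair scores ratio 1
        by_concept = {}
        for rec in clean_bundle.merged:
            cid = clean_bundle.truth_groups[rec.record_id]
            by_concept.setdefault(cid, []).append(rec)
        multi = [recs for recs in by_concept.values() if len(recs) > 1]
        assert multi
        for recs in multi:
            assert len({(r.sf, r.lf) for r in recs}) == 1

    def test_truth_covers_every_record(self, default_bundle):
        assert set(default_bundle.truth_groups) == {
            r.record_id for r in default_bundle.merged
        }

    def test_labeled_pairs_consistent_with_truth(self, default_bundle):
        truth = default_bundle.truth_groups
        for pair in default_bundle.labeled_pairs:
            a, b = pair.pair_id
            assert pair.label == int(truth[a] == truth[b])

    def test_every_concept_reaches_some_source(self):
        bank = si.generate_concept_bank(30, 0.1, seed=6)
        bundle = si.generate_inventories(bank, n_sources=3, seed=6, source_coverage=0.0)
        assert len({cid for cid in bundle.truth_groups.values()}) == 30

    def test_misspelling_count_within_binomial_bound(self):
        bank = si.generate_concept_bank(400, ambiguity_rate=0.0, seed=7)
        rates = si.VariantRates(
            sf_case=0.0, sf_periods=0.0, lf_plural=0.0, lf_genitive=0.0,
            lf_stopword=0.0, lf_token_swap=0.0, lf_misspell=0.1,
        )
        bundle = si.generate_inventories(
            bank, n_sources=4, variant_rates=rates, seed=7, source_coverage=0.9
        )
        canonical = {c.concept_id: c.long_form for c in bank.concepts}
        # only non-home records carry variants; home records are canonical
        candidates = [
            rec for rec in bundle.merged
            if rec.lf != canonical[bundle.truth_groups[rec.record_id]]
        ]
        n_variant_records = sum(
            1 for rec in bundle.merged
        ) - len(canonical)  # every concept has exactly one canonical home record
        count = len(candidates)
        p = 0.1
        sigma = math.sqrt(n_variant_records * p * (1 - p))
        assert abs(count - n_variant_records * p) <= 3 * sigma

    def test_bit_reproducible_under_seed(self):
        bank = si.generate_concept_bank(25, 0.2, seed=8)
        a = si.generate_inventories(bank, n_sources=2, seed=8)
        b = si.generate_inventories(bank, n_sources=2, seed=8)
        assert [(r.sf, r.lf, r.source) for r in a.merged] == [
            (r.sf, r.lf, r.source) for r in b.merged
        ]
        assert a.truth_groups == b.truth_groups
        assert a.labeled_pairs == b.labeled_pairs

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            si.VariantRates(lf_misspell=1.5)
        with pytest.raises(ValueError):
            si.ErrorRates(duplicate=-0.1)


class TestAnnotatedCorpus:
    def test_full_labeling(self, default_bundle):
        assert all(inst.sense for inst in default_bundle.corpus)

    def test_deterministic(self):
        bank = si.generate_concept_bank(20, 0.1, seed=5)
        a = si.generate_annotated_corpus(bank, 100, seed=5)
        b = si.generate_annotated_corpus(bank, 100, seed=5)
        assert a == b

    def test_zipf_dominance(self):
        bank = si.generate_concept_bank(50, 0.0, seed=5, zipf_exponent=2.5)
        corpus = si.generate_annotated_corpus(bank, 500, seed=5)
        counts = Counter(inst.surface for inst in corpus)
        top_surface, top_count = counts.most_common(1)[0]
        assert top_surface == bank.concepts[0].abbrev
        assert top_count > 500 / 3

    def test_invalid_parameters(self):
        bank = si.generate_concept_bank(5, 0.0, seed=0)
        with pytest.raises(ValueError):
            si.generate_annotated_corpus(bank, 0)
        with pytest.raises(ValueError):
            si.generate_annotated_corpus(bank, 10, labeled_fraction=1.5)


class TestEndToEndRecovery:
    def test_coverage_identity_on_clean_fixture(self, clean_bundle):
        report = si.coverage_report(clean_bundle.corpus, clean_bundle.merged)
        assert report == si.CoverageReport(1.0, 1.0, 1.0, 1.0)

    def test_perfect_recovery_without_noise(self, clean_bundle):
        result = si.run_harmonize(
            clean_bundle.inventories,
            si.PipelineConfig(seed=2),
            training_pairs=clean_bundle.labeled_pairs,
        )
        predicted = {r.record_id: r.group_id for r in result.inventory.records}
        _, _, f1 = si.pairwise_f1(predicted, clean_bundle.truth_groups)
        assert f1 == 1.0
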