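import random

import pytest

import senseinv as si
from conftest import make_inventory
from senseinv.qc import Heuristic

CORPUS = {"multiple", "sclerosis", "oral", "contraceptive", "contraceptives", "every", "day"}


class TestDuplicates:
    def test_second_identical_row_flagged(self):
        inv = make_inventory(
            [("MS", "multiple sclerosis", "A"), ("MS", "multiple sclerosis", "A")]
        )
        flags = si.flag_intra_source_duplicates(inv)
        assert [f.record_id for f in flags] == ["R000002"]

    def test_identical_rows_in_different_sources_not_flagged(self):
        inv = make_inventory(
            [("MS", "multiple sclerosis", "A"), ("MS", "multiple sclerosis", "B")]
        )
        assert si.flag_intra_source_duplicates(inv) == []

    def test_triple_occurrence_two_flags(self):
        inv = make_inventory([("MS", "multiple sclerosis", "A")] * 3)
        assert len(si.flag_intra_source_duplicates(inv)) == 2


class TestPunctuation:
    @pytest.mark.parametrize(
        "sf, flagged",
        [
            ("..MS", True),       # leading run
            ("O.C.", False),      # single trailing period allowed
            ("D//C", True),       # consecutive punctuation
            ("MS-", True),        # trailing non-period
            ("MS", False),
            ("D/C", False),
        ],
    )
    def test_rules(self, sf, flagged):
        assert (si.flag_punctuation(sf) is not None) == flagged

    def test_subrules_toggleable(self):
        rules = si.PunctuationRules(leading_run=False)
        # a single leading period trips only the leading-run rule
        assert si.flag_punctuation(".MS") is not None
        assert si.flag_punctuation(".MS", rules) is None


class TestCharMismatch:
    @pytest.mark.parametrize(
        "sf, lf, flagged",
        [
            ("MS", "multiple sclerosis", False),
            ("qd", "every day", True),
            ("T2", "type 2 diabetes", False),
            ("Ms", "MULTIPLE SCLEROSIS", False),  # case-insensitive
        ],
    )
    def test_rules(self, sf, lf, flagged):
        assert (si.flag_char_mismatch(sf, lf) is not None) == flagged


class TestSpelling:
    def test_known_words_pass(self):
        assert si.flag_spelling("multiple sclerosis", CORPUS) is None

    def test_unknown_token_flagged_with_detail(self):
        detail = si.flag_spelling("multiple sclerosi", CORPUS)
        assert detail is not None and "sclerosi" in detail

    def test_short_tokens_exempt(self):
        assert si.flag_spelling("MS of hip", CORPUS) is None

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            si.flag_spelling("anything here", set())


class TestRunQC:
    def test_clean_generated_fixture_yields_no_flags(self, clean_bundle):
        flags = si.run_qc(clean_bundle.merged, clean_bundle.word_corpus)
        assert flags == []

    def test_one_error_per_heuristic_gives_four_flags(self):
        inv = make_inventory(
            [
                ("MS", "multiple sclerosis", "A"),
                ("MS", "multiple sclerosis", "A"),     # duplicate
                ("..OC", "oral contraceptive", "A"),   # punctuation
                ("qd", "every day", "A"),              # char mismatch
                ("MS", "multiple sclerosi", "A"),      # spelling
            ]
        )
        flags = si.run_qc(inv, CORPUS)
        assert sorted(f.heuristic for f in flags) == sorted(
            [Heuristic.DUPLICATE, Heuristic.PUNCTUATION,
             Heuristic.CHAR_MISMATCH, Heuristic.SPELLING]
        )

    def test_injected_errors_all_recalled(self):
        bank = si.generate_concept_bank(50, ambiguity_rate=0.1, seed=3)
        bundle = si.generate_inventories(
            bank,
            n_sources=3,
            error_rates=si.ErrorRates(
                duplicate=0.05, punctuation=0.05, char_mismatch=0.05, spelling=0.05
            ),
            seed=3,
        )
        assert bundle.injected_errors  # rates high enough to inject something
        flagged = {(f.record_id, f.heuristic) for f in si.run_qc(bundle.merged, bundle.word_corpus)}
        for record_id, heuristic in bundle.injected_errors:
            assert (record_id, heuristic) in flagged

    def test_flag_multiset_invariant_under_permutation(self):
        inv = make_inventory(
            [("..MS", "multiple sclerosis", "A"), ("qd", "every day", "A"),
             ("OC", "oral contraceptive", "A")]
        )
        baseline = {(f.record_id, f.heuristic) for f in si.run_qc(inv, CORPUS)}
        shuffled = inv.copy()
        random.Random(1).shuffle(shuffled.records)
        assert {(f.record_id, f.heuristic) for f in si.run_qc(shuffled, CORPUS)} == baseline


class TestApplyActions:
    def _inventory(self):
        return make_inventory(
            [("MS", "multiple sclerosis", "A"), ("OC", "oral contraceptives", "A"),
             ("PA", "physician assistant", "A")]
        )

    def test_retire_conserves_records(self):
        inv = self._inventory()
        active, retired = si.apply_actions(
            inv, [si.QCAction("R000002", si.Action.RETIRE)]
        )
        assert len(active) == 2 and len(retired) == 1
        assert retired.records[0].sf == "OC"
        assert len(active) + len(retired) == len(inv)

    def test_modify_recomputes_normalized_forms(self):
        inv = self._inventory()
        active, _ = si.apply_actions(
            inv, [si.QCAction("R000001", si.Action.MODIFY, corrected_lf="multiple scleroses")]
        )
        rec = active.record_by_id("R000001")
        assert rec.lf == "multiple scleroses"
        assert rec.norm_lf == si.normalize_long_form("multiple scleroses")
        assert rec.modified == "modified"
        assert rec.record_id == "R000001"  # identifier unchanged

    def test_empty_action_list_is_identity(self):
        inv = self._inventory()
        active, retired = si.apply_actions(inv, [])
        assert len(retired) == 0
        assert [(r.sf, r.lf) for r in active] == [(r.sf, r.lf) for r in inv]

    def test_modify_without_correction_rejected(self):
        with pytest.raises(ValueError):
            si.QCAction("R000001", si.Action.MODIFY)

    def test_idempotent_for_fixed_action_list(self):
        inv = self._inventory()
        actions = [
            si.QCAction("R000002", si.Action.RETIRE),
            si.QCAction("R000001", si.Action.MODIFY, corrected_sf="M.S."),
        ]
        once_active, once_retired = si.apply_actions(inv, actions)
        twice_active, twice_retired = si.apply_actions(once_active, actions)
        assert [(r.sf, r.lf, r.modified) for r in twice_active] == [
            (r.sf, r.lf, r.modified) for r in once_active
        ]
        assert len(twice_retired) == 0  # already retired: no-op
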