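"""Speller state machines, bigram suggestions, and copy-spelling simulation."""

import numpy as np
import pytest

from cvep.metrics_eval import accuracy
from cvep.speller import (SpellerState, apply_selection, four_target_layout,
                          intended_target, normalize_task, simulate_copy_spelling,
                          suggest, thirty_two_target_layout, train_bigram,
                          update_suggestions)

L4 = four_target_layout()
L32 = thirty_two_target_layout()


class TestFourTargetTree:
    def test_spelling_b_takes_three_steps(self):
        """B lives in group A-I, sub-group A-C, leaf 2."""
        s = SpellerState()
        s = apply_selection(s, L4, 0)      # group A-I
        s = apply_selection(s, L4, 0)      # sub-group A-C
        s = apply_selection(s, L4, 1)      # letter B
        assert s.typed_text == "B"
        assert s.tree_position == ()

    def test_undo_at_root_deletes_character(self):
        s = SpellerState(typed_text="AB", history=("A", "B"))
        s = apply_selection(s, L4, 3)
        assert s.typed_text == "A"

    def test_undo_below_root_ascends(self):
        s = SpellerState(typed_text="A", tree_position=(1, 2), history=("A",))
        s = apply_selection(s, L4, 3)
        assert s.tree_position == (1,)
        assert s.typed_text == "A"
        s = apply_selection(s, L4, 3)
        assert s.tree_position == ()

    def test_underscore_reachable(self):
        s = SpellerState()
        for t in (2, 2, 2):                # group S-_, sub-group Y,Z,_, leaf 3
            s = apply_selection(s, L4, t)
        assert s.typed_text == "_"


class TestThirtyTwoTarget:
    def test_character_append_and_undo(self):
        s = SpellerState()
        s = apply_selection(s, L32, 0)
        s = apply_selection(s, L32, 1)
        assert s.typed_text == "AB"
        s = apply_selection(s, L32, 31)
        assert s.typed_text == "A"

    def test_suggestion_completes_word_with_boundary(self):
        s = SpellerState(typed_text="QU", history=("Q", "U"),
                         suggestions=("QUICK", "QUIET", "QUEEN"))
        s = apply_selection(s, L32, 28)
        assert s.typed_text == "QUICK_"

    def test_undo_removes_entire_word_completion(self):
        s = SpellerState(typed_text="QU", history=("Q", "U"),
                         suggestions=("QUICK",))
        s = apply_selection(s, L32, 28)
        s = apply_selection(s, L32, 31)
        assert s.typed_text == "QU"

    def test_empty_suggestion_slot_is_a_no_op(self):
        s = SpellerState(typed_text="A", history=("A",), suggestions=())
        assert apply_selection(s, L32, 29).typed_text == "A"

    def test_invalid_target_rejected(self):
        with pytest.raises(IndexError):
            apply_selection(SpellerState(), L32, 32)


class TestBigram:
    def test_equal_context_counts_give_equal_probability(self):
        m = train_bigram(["A B", "A C"])
        assert m.probability("B", "A") == pytest.approx(0.5)
        assert m.probability("C", "A") == pytest.approx(0.5)

    def test_unigram_fallback_for_unseen_context(self):
        m = train_bigram(["DOG RUNS", "DOG SLEEPS", "DOG RUNS FAST"])
        ranked = suggest(m, "UNSEEN", "")
        assert ranked[0] == "DOG"  # most frequent word overall

    def test_bigram_counts_conserved(self):
        sentences = ["THE DOG RUNS", "THE CAT SLEEPS ALL DAY", "SUN"]
        m = train_bigram(sentences)
        expected = sum(len(s.split()) - 1 for s in sentences)
        assert sum(m.bigram.values()) == expected

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_bigram(["123", "..."])

    def test_ranking_matches_brute_force(self):
        corpus = ["A B", "A B", "A C", "A D", "B C", "C D D"]
        m = train_bigram(corpus)
        got = suggest(m, "A", "", n=3)
        # brute force: sort successors of A by count, unigram, alphabet
        brute = sorted(m.unigram, key=lambda w: (-m.bigram.get(("A", w), 0),
                                                 -m.unigram[w], w))[:3]
        assert got == brute

    def test_no_match_gives_empty_list(self):
        m = train_bigram(["A B"])
        assert suggest(m, None, "ZZZ") == []


class TestIntentPolicy:
    def test_first_step_towards_b_is_group_one(self):
        goal = normalize_task("BCI", L4)
        assert intended_target(SpellerState(), L4, goal) == 0  # group A-I

    def test_wrong_character_triggers_undo(self):
        s = SpellerState(typed_text="X", history=("X",))
        assert intended_target(s, L32, "BRAIN") == 31
        assert intended_target(s, L4, normalize_task("BRAIN", L4)) == 3

    def test_letter_by_letter_never_selects_suggestions(self):
        m = train_bigram(["THE QUICK BROWN FOX"])
        s = update_suggestions(SpellerState(typed_text="THE_QU", history=tuple("THE_QU")), m)
        assert s.suggestions  # a completion is on display
        t = intended_target(s, L32, normalize_task("THE QUICK", L32),
                            use_dictionary=False)
        assert t < 28  # heads for the next character, not a suggestion


class TestCopySpelling:
    def test_pangram_selection_counts_error_free(self, pangram):
        s32 = simulate_copy_spelling(L32, pangram, accuracy=1.0)
        s4 = simulate_copy_spelling(L4, pangram, accuracy=1.0)
        assert s32.n_selections == 43
        assert s4.n_selections == 129
        assert s32.final_text == s4.final_text == normalize_task(pangram, L32)

    def test_dictionary_reduces_selections(self, pangram):
        bigram = train_bigram([pangram])
        sd = simulate_copy_spelling(L32, pangram, accuracy=1.0, bigram=bigram,
                                    use_dictionary=True)
        assert sd.n_selections < 43
        assert sd.final_text == normalize_task(pangram, L32)

    @pytest.mark.parametrize("layout", [L32, L4], ids=["32-target", "4-target"])
    def test_errors_are_corrected_and_goal_reached(self, layout, pangram):
        sess = simulate_copy_spelling(layout, pangram, accuracy=0.85, seed=4)
        assert sess.final_text == sess.goal
        assert sess.n_selections > len(sess.goal)
        assert accuracy(sess.log) == pytest.approx(sess.n_correct / sess.n_selections)
        assert 0.7 < accuracy(sess.log) < 1.0

    def test_decoder_oracle_can_be_plugged_in(self):
        rng = np.random.default_rng(0)

        def stuck_key(intended):
            return 0 if rng.random() < 0.1 else intended

        sess = simulate_copy_spelling(L32, "CAB", accuracy=1.0,
                                      selection_oracle=stuck_key, seed=1)
        assert sess.final_text == "CAB"

    def test_unrepresentable_character_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_copy_spelling(L32, "HELLO 3 WORLD")

    def test_full_stop_only_on_32_target(self):
        assert simulate_copy_spelling(L32, "OK.").final_text == "OK."
        with pytest.raises(ValueError):
            simulate_copy_spelling(L4, "OK.")
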