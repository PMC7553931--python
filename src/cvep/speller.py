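"""Speller state machines, bigram word prediction, and copy-spelling simulation.

Two layouts are modelled.  The 4-target speller selects one of 27
characters (26 letters + underscore/space) in three steps through a
selection tree — three groups of nine, then groups of three, then single
characters — with the fourth target acting as undo (delete the last
character at the root, go back one step below it).  The 32-target
speller selects in a single step among 28 characters (letters,
underscore, full stop), three dictionary suggestion slots, and one undo
target that removes the previous selection's entire output.

Word suggestions come from a bigram model over words: candidates
completing the current prefix are ranked by their bigram probability
given the previously spelled word, falling back to unigram frequency
for unseen contexts.  A small bundled corpus of uppercase sentences
serves as the default training text.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SpellerLayout", "SpellerState", "BigramModel", "SelectionRecord", "SpellingSession",
    "four_target_layout", "thirty_two_target_layout",
    "apply_selection", "update_suggestions", "train_bigram", "suggest",
    "intended_target", "simulate_copy_spelling", "load_bundled_corpus", "normalize_task",
]

CHARSET_4 = "ABCDEFGHIJKLMNOPQRSTUVWXYZ_"      # 27 symbols, 3 groups of 9
CHARSET_32 = "ABCDEFGHIJKLMNOPQRSTUVWXYZ_."    # 28 symbols on the 32-target grid
N_SUGGESTIONS = 3


@dataclass(frozen=True)
class SpellerLayout:
    kind: str                 # "four_target" | "thirty_two_target"
    K: int
    charset: str

    @property
    def undo_target(self) -> int:
        return self.K - 1 if self.kind == "four_target" else 31

    @property
    def suggestion_targets(self) -> range:
        if self.kind != "thirty_two_target":
            return range(0)
        return range(len(self.charset), len(self.charset) + N_SUGGESTIONS)


def four_target_layout() -> SpellerLayout:
    return SpellerLayout(kind="four_target", K=4, charset=CHARSET_4)


def thirty_two_target_layout() -> SpellerLayout:
    return SpellerLayout(kind="thirty_two_target", K=32, charset=CHARSET_32)


@dataclass(frozen=True)
class SpellerState:
    """Immutable speller state; selections return updated copies."""

    typed_text: str = ""
    tree_position: tuple = ()            # 4-target only: (), (group,), (group, sub)
    suggestions: tuple = ()              # up to 3 displayed words
    history: tuple = ()                  # output appended by each productive selection


# -- bigram word prediction ------------------------------------------------


@dataclass
class BigramModel:
    unigram: Counter = field(default_factory=Counter)
    bigram: Counter = field(default_factory=Counter)
    context_totals: Counter = field(default_factory=Counter)

    @property
    def vocabulary(self) -> "list[str]":
        return sorted(self.unigram)

    def probability(self, word: str, previous: str | None = None) -> float:
        """P(word | previous) with unigram fallback for unseen contexts."""
        if previous is not None and self.context_totals[previous] > 0:
            return self.bigram[(previous, word)] / self.context_totals[previous]
        total = sum(self.unigram.values())
        return self.unigram[word] / total if total else 0.0


def _words(sentence: str) -> "list[str]":
    return re.sub(r"[^A-Z]+", " ", sentence.upper()).split()


def train_bigram(corpus: "list[str]") -> BigramModel:
    """Count word unigrams and ordered word pairs from sentences."""
    model = BigramModel()
    for sentence in corpus:
        ws = _words(sentence)
        model.unigram.update(ws)
        for a, b in zip(ws, ws[1:]):
            model.bigram[(a, b)] += 1
            model.context_totals[a] += 1
    if not model.unigram:
        raise ValueError("empty corpus: no words to build a bigram model from")
    return model


def suggest(model: BigramModel, previous: str | None, prefix: str, n: int = N_SUGGESTIONS) -> "list[str]":
    """Top-n vocabulary words matching *prefix*, ranked by P(word | previous).

    Ranking: bigram count given the previous word first, unigram
    frequency second, alphabetical order as the deterministic tie-break.
    """
    prefix = prefix.upper()
    cands = [w for w in model.unigram if w.startswith(prefix)]
    cands.sort(key=lambda w: (-model.bigram.get((previous, w), 0) if previous else 0,
                              -model.unigram[w], w))
    return cands[:n]


def load_bundled_corpus() -> "list[str]":
    """Sentences of the bundled toy corpus, one per line."""
    text = resources.files("cvep").joinpath("data/corpus.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def load_corpus(path: "str | Path") -> "list[str]":
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


# -- state machine ---------------------------------------------------------


def _word_context(typed: str) -> "tuple[str | None, str]":
    """(previously completed word, current partial-word prefix)."""
    parts = re.split(r"[_.]", typed)
    prefix = parts[-1]
    completed = [p for p in parts[:-1] if p]
    return (completed[-1] if completed else None), prefix


def update_suggestions(state: SpellerState, model: BigramModel | None) -> SpellerState:
    if model is None:
        return replace(state, suggestions=())
    previous, prefix = _word_context(state.typed_text)
    return replace(state, suggestions=tuple(suggest(model, previous, prefix)))


def _undo(state: SpellerState) -> SpellerState:
    if not state.history:
        return state
    last = state.history[-1]
    return replace(state, typed_text=state.typed_text[: len(state.typed_text) - len(last)],
                   history=state.history[:-1])


def apply_selection(state: SpellerState, layout: SpellerLayout, target: int) -> SpellerState:
    """Apply one (possibly erroneous) selection and return the new state."""
    if not 0 <= target < layout.K:
        raise IndexError(f"target {target} outside 0..{layout.K - 1}")

    if layout.kind == "four_target":
        pos = state.tree_position
        if target == 3:
            if not pos:                      # root: delete last character
                return _undo(state)
            return replace(state, tree_position=pos[:-1])   # go back one step
        if len(pos) < 2:                     # descend group / sub-group
            return replace(state, tree_position=pos + (target,))
        g, sg = pos                          # leaf: emit a character, reset
        ch = layout.charset[g * 9 + sg * 3 + target]
        return replace(state, typed_text=state.typed_text + ch,
                       tree_position=(), history=state.history + (ch,))

    # thirty_two_target
    if target == layout.undo_target:
        return _undo(state)
    if target in layout.suggestion_targets:
        slot = target - len(layout.charset)
        if slot >= len(state.suggestions):
            return state                     # empty slot: selection with no output
        word = state.suggestions[slot]
        _, prefix = _word_context(state.typed_text)
        if not word.startswith(prefix):
            return state
        appended = word[len(prefix):] + "_"  # complete the word + word boundary
        return replace(state, typed_text=state.typed_text + appended,
                       history=state.history + (appended,))
    ch = layout.charset[target]
    return replace(state, typed_text=state.typed_text + ch,
                   history=state.history + (ch,))


# -- intent policy and simulation -----------------------------------------


def normalize_task(task: str, layout: SpellerLayout) -> str:
    goal = task.upper().replace(" ", "_")
    bad = set(goal) - set(layout.charset)
    if bad:
        raise ValueError(f"task contains characters outside the layout: {sorted(bad)}")
    return goal


def intended_target(
    state: SpellerState,
    layout: SpellerLayout,
    goal: str,
    use_dictionary: bool = False,
) -> int:
    """Greedy intent policy used by the simulated user.

    Undo whenever the typed text stopped being a prefix of the goal (or
    the 4-target position is mid-tree with nothing left to type);
    otherwise pick a displayed suggestion that completes the next goal
    word (dictionary mode only), else head for the next character.
    """
    typed = state.typed_text
    if not goal.startswith(typed):
        return layout.undo_target
    if layout.kind == "four_target":
        if typed == goal:
            if state.tree_position:
                return 3                     # climb back; caller stops at the root
            raise ValueError("goal already reached")
        c = goal[len(typed)]
        idx = layout.charset.index(c)
        g, sg, leaf = idx // 9, (idx % 9) // 3, idx % 3
        pos = state.tree_position
        if not pos:
            return g
        if len(pos) == 1:
            return sg if pos[0] == g else 3
        return leaf if pos[:2] == (g, sg) else 3

    if typed == goal:
        raise ValueError("goal already reached")
    if use_dictionary and state.suggestions:
        _, prefix = _word_context(typed)
        for slot, word in enumerate(state.suggestions):
            if not word.startswith(prefix) or len(word) <= len(prefix):
                continue
            if goal.startswith(typed + word[len(prefix):] + "_"):
                return len(layout.charset) + slot
    return layout.charset.index(goal[len(typed)])


@dataclass
class SelectionRecord:
    intended: int
    selected: int
    correct: bool


@dataclass
class SpellingSession:
    layout: SpellerLayout
    goal: str
    log: "list[SelectionRecord]"
    final_text: str

    @property
    def n_selections(self) -> int:
        return len(self.log)

    @property
    def n_correct(self) -> int:
        return sum(r.correct for r in self.log)

    @property
    def n_chars(self) -> int:
        """Characters of the final correct output (errors corrected)."""
        return len(self.goal)


def simulate_copy_spelling(
    layout: SpellerLayout,
    task: str,
    accuracy: float = 1.0,
    bigram: BigramModel | None = None,
    use_dictionary: bool = False,
    seed: int = 0,
    selection_oracle=None,
    max_selections: int = 100_000,
) -> SpellingSession:
    """Simulate copy-spelling of *task* until the goal text is produced.

    Each intended selection is realised correctly with probability
    *accuracy*; an error picks uniformly among the other K-1 targets
    (pass *selection_oracle*, a callable intended -> realised, to plug
    in e.g. a decoder-in-the-loop).  Errors are later corrected through
    the undo mechanics, so the loop ends exactly when the typed text
    equals the goal.
    """
    if not 0.0 < accuracy <= 1.0:
        raise ValueError("accuracy must lie in (0, 1]")
    goal = normalize_task(task, layout)
    rng = np.random.default_rng(seed)
    if selection_oracle is None:
        def selection_oracle(intended: int) -> int:
            if accuracy >= 1.0 or rng.random() < accuracy:
                return intended
            others = [t for t in range(layout.K) if t != intended]
            return int(rng.choice(others))

    state = update_suggestions(SpellerState(), bigram if use_dictionary else None)
    log: list[SelectionRecord] = []
    while not (state.typed_text == goal and not state.tree_position):
        if len(log) >= max_selections:
            raise RuntimeError("copy-spelling did not terminate within the selection cap")
        intended = intended_target(state, layout, goal, use_dictionary=use_dictionary)
        selected = selection_oracle(intended)
        state = apply_selection(state, layout, selected)
        state = update_suggestions(state, bigram if use_dictionary else None)
        log.append(SelectionRecord(intended=intended, selected=selected,
                                   correct=selected == intended))
    return SpellingSession(layout=layout, goal=goal, log=log, final_text=state.typed_text)
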