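"""Serial grapheme-phoneme rule route.

A word is read left to right: at each position the rule with the longest
grapheme matching there fires, emits its phoneme and consumes its letters.
Position classes (onset / vowel / coda / any) constrain which rules are
eligible: before a vowel-class rule has fired, onset and vowel rules are
eligible; afterwards only coda rules; class 'any' is always eligible but
loses length ties to class-specific rules.

The stimulus representation of a word is the sparse indicator vector of the
rules it fired.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import LexiconFormatError, UnpronounceableInputError
from .lexicon import GROUPS, Lexicon

POSITION_CLASSES = ("onset", "vowel", "coda", "any")


@dataclass(frozen=True)
class GPCRule:
    grapheme: str
    phoneme: str
    position_class: str
    rule_index: int

    def __post_init__(self):
        if not self.grapheme:
            raise LexiconFormatError("rule grapheme must be non-empty")
        if self.position_class not in POSITION_CLASSES:
            raise LexiconFormatError(
                f"bad position class {self.position_class!r}"
            )
        object.__setattr__(self, "grapheme", self.grapheme.lower())


class GPCRuleSet:
    """Ordered rule collection; (grapheme, position_class) pairs are unique."""

    def __init__(self, rules: Iterable[GPCRule]):
        self.rules: tuple[GPCRule, ...] = tuple(rules)
        keys = [(r.grapheme, r.position_class) for r in self.rules]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise LexiconFormatError(
                f"duplicate (grapheme, position_class) rules: {dupes}"
            )
        indices = sorted(r.rule_index for r in self.rules)
        if indices != list(range(len(self.rules))):
            raise LexiconFormatError("rule indices must be 0..n-1 and unique")
        # lookup: grapheme -> {position_class -> rule}
        self._by_grapheme: dict[str, dict[str, GPCRule]] = {}
        for r in self.rules:
            self._by_grapheme.setdefault(r.grapheme, {})[r.position_class] = r
        self._max_len = max((len(r.grapheme) for r in self.rules), default=0)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def match(self, grapheme: str, allowed: Sequence[str]) -> GPCRule | None:
        """Rule for this exact grapheme under the allowed classes.

        Class-specific rules beat 'any'; `allowed` is in priority order.
        """
        classes = self._by_grapheme.get(grapheme)
        if not classes:
            return None
        for cls in allowed:
            if cls in classes:
                return classes[cls]
        if "any" in classes:
            return classes["any"]
        return None

    @property
    def max_grapheme_length(self) -> int:
        return self._max_len


@dataclass(frozen=True)
class GPCTrace:
    """Record of one serial reading pass: which rule fired on which span."""

    spelling: str
    steps: tuple[tuple[int, int, int], ...]  # (start, length, rule_index)
    phonemes: tuple[str, ...]

    def __post_init__(self):
        pos = 0
        for start, length, _ in self.steps:
            if start != pos or length < 1:
                raise ValueError("trace spans must tile the spelling left to right")
            pos += length
        if pos != len(self.spelling):
            raise ValueError("trace does not cover the spelling")

    @property
    def rule_indices(self) -> tuple[int, ...]:
        return tuple(idx for _, _, idx in self.steps)


def apply_gpc(spelling: str, ruleset: GPCRuleSet) -> GPCTrace:
    """Serial left-to-right longest-match rule application.

    Raises :class:`UnpronounceableInputError` if no eligible rule matches at
    some position.
    """
    spelling = spelling.lower()
    if not spelling:
        raise ValueError("spelling must be non-empty")
    pos = 0
    vowel_fired = False
    steps: list[tuple[int, int, int]] = []
    phonemes: list[str] = []
    while pos < len(spelling):
        allowed = ("coda",) if vowel_fired else ("onset", "vowel")
        chosen: GPCRule | None = None
        max_len = min(ruleset.max_grapheme_length, len(spelling) - pos)
        for length in range(max_len, 0, -1):  # largest to smallest grapheme
            rule = ruleset.match(spelling[pos:pos + length], allowed)
            if rule is not None:
                chosen = rule
                break
        if chosen is None:
            raise UnpronounceableInputError(spelling, pos)
        steps.append((pos, len(chosen.grapheme), chosen.rule_index))
        phonemes.append(chosen.phoneme)
        if chosen.position_class == "vowel":
            vowel_fired = True
        pos += len(chosen.grapheme)
    return GPCTrace(spelling, tuple(steps), tuple(phonemes))


def gpc_representation(lexicon: Lexicon, ruleset: GPCRuleSet) -> np.ndarray:
    """n_stimuli x n_rules binary matrix: 1 where a rule fired for a word.

    A rule firing more than once in one word still yields a single 1 (set
    semantics).
    """
    mat = np.zeros((len(lexicon), len(ruleset)), dtype=np.uint8)
    for i, entry in enumerate(lexicon):
        trace = apply_gpc(entry.spelling, ruleset)
        mat[i, list(set(trace.rule_indices))] = 1
    return mat


def lexical_extension(n_words: int) -> np.ndarray:
    """One-hot orthographic plus one-hot phonological lexicon units.

    Row i carries a 1 at position i in each of the two n_words blocks, so the
    result has 2*n_words columns and every row sums to 2.
    """
    eye = np.eye(n_words, dtype=np.uint8)
    return np.concatenate([eye, eye], axis=1)


def generate_rules(lexicon: Lexicon, multi_letter: bool = True) -> GPCRuleSet:
    """Derive a rule set from a lexicon's majority grapheme-to-phoneme mapping.

    For every (slot group, grapheme) pair attested in the lexicon, the most
    frequent phoneme it maps to (type counts; ties broken lexicographically)
    becomes a rule with that slot as its position class.  Multi-letter
    graphemes yield multi-letter rules unless ``multi_letter`` is false.
    """
    counts: dict[tuple[str, str], Counter] = {}
    for entry in lexicon:
        for grp in GROUPS:
            gs, ps = entry.graphemes(grp), entry.phonemes(grp)
            if len(gs) != len(ps):
                raise LexiconFormatError(
                    f"word {entry.word_id!r}: {grp} grapheme/phoneme "
                    f"sequences differ in length; cannot derive rules"
                )
            for g, p in zip(gs, ps):
                counts.setdefault((grp, g), Counter())[p] += 1
    rules = []
    idx = 0
    for (grp, g), ctr in sorted(counts.items()):
        if len(g) > 1 and not multi_letter:
            continue
        top = max(ctr.items(), key=lambda kv: (kv[1], kv[0]))
        # deterministic tie-break: highest count, then lexicographically last
        rules.append(GPCRule(g, top[0], grp, idx))
        idx += 1
    return GPCRuleSet(rules)


def write_rules_tsv(ruleset: GPCRuleSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rule_index", "grapheme", "phoneme", "position_class"])
        for r in ruleset:
            writer.writerow([r.rule_index, r.grapheme, r.phoneme, r.position_class])


def read_rules_tsv(path) -> GPCRuleSet:
    rules = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["rule_index", "grapheme", "phoneme", "position_class"]:
            raise LexiconFormatError(f"{path}: bad rules header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise LexiconFormatError(f"{path}:{lineno}: expected 4 fields")
            try:
                rules.append(GPCRule(row[1], row[2], row[3], int(row[0])))
            except (ValueError, LexiconFormatError) as exc:
                raise LexiconFormatError(f"{path}:{lineno}: {exc}") from exc
    return GPCRuleSet(rules)
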