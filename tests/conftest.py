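import numpy as np
import pytest

from readrsa.lexicon import (GraphemeSlotScheme, Lexicon, LexiconEntry,
                             PhonemeSlotScheme)


@pytest.fixture
def toy_gscheme() -> GraphemeSlotScheme:
    return GraphemeSlotScheme(onset=["b", "c", "ch", "p", "h", "ph"],
                              vowel=["a", "e"],
                              coda=["t", "s", "ts"])


@pytest.fixture
def toy_pscheme() -> PhonemeSlotScheme:
    return PhonemeSlotScheme(onset=["B", "K", "C", "P", "F"],
                             vowel=["A", "E"],
                             coda=["T", "S", "TS"],
                             compound_map={"TS": ("T", "S")})


def make_entry(word_id, onset, vowel, coda, p_onset, p_vowel, p_coda, freq=1.0):
    return LexiconEntry(word_id, "".join(onset + vowel + coda),
                        onset, vowel, coda, p_onset, p_vowel, p_coda, freq)


@pytest.fixture
def toy_lexicon(toy_gscheme, toy_pscheme) -> Lexicon:
    entries = [
        make_entry("w1", ("ch",), ("a",), ("t",), ("C",), ("A",), ("T",), 10.0),
        make_entry("w2", ("b",), ("e",), ("ts",), ("B",), ("E",), ("TS",), 5.0),
        make_entry("w3", ("p",), ("a",), ("s",), ("P",), ("A",), ("S",), 2.0),
        make_entry("w4", (), ("a",), (), (), ("A",), (), 1.0),
    ]
    return Lexicon(entries, toy_gscheme, toy_pscheme)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
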