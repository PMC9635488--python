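"""Slot schemes, lexicon entries and binary feature encodings.

Words are represented in onset / vowel / coda slot structure on both the
spelling side (graphemes) and the pronunciation side (phonemes).  Each slot
group defines a contiguous block of units; a word's binary vector has a 1
for every grapheme (or phoneme) it uses.  Multi-letter graphemes also
activate their single-letter constituents when those constituents belong to
the same slot group, and compound phonemes likewise activate their
constituent phonemes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import EncodingError, LexiconFormatError

GROUPS = ("onset", "vowel", "coda")

Channel = Literal["orthography", "phonology"]


def _check_group(symbols: Sequence[str], group: str) -> tuple[str, ...]:
    symbols = tuple(symbols)
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise LexiconFormatError(f"duplicate symbols in {group} group: {dupes}")
    if any(not s for s in symbols):
        raise LexiconFormatError(f"empty symbol in {group} group")
    return symbols


@dataclass(frozen=True)
class GraphemeSlotScheme:
    """Ordered grapheme inventories for the onset, vowel and coda blocks.

    Letters are case-insensitive: all symbols are lower-cased on
    construction.  Unit order is onset block, then vowel, then coda, each
    in group order.
    """

    onset: tuple[str, ...]
    vowel: tuple[str, ...]
    coda: tuple[str, ...]

    def __init__(self, onset: Iterable[str], vowel: Iterable[str], coda: Iterable[str]):
        object.__setattr__(self, "onset", _check_group([g.lower() for g in onset], "onset"))
        object.__setattr__(self, "vowel", _check_group([g.lower() for g in vowel], "vowel"))
        object.__setattr__(self, "coda", _check_group([g.lower() for g in coda], "coda"))

    @property
    def n_units(self) -> int:
        return len(self.onset) + len(self.vowel) + len(self.coda)

    def group(self, name: str) -> tuple[str, ...]:
        return {"onset": self.onset, "vowel": self.vowel, "coda": self.coda}[name]

    @property
    def unit_labels(self) -> list[str]:
        return [f"{grp}:{sym}" for grp in GROUPS for sym in self.group(grp)]

    def unit_index(self, group: str, symbol: str) -> int:
        offset = 0
        for grp in GROUPS:
            members = self.group(grp)
            if grp == group:
                try:
                    return offset + members.index(symbol)
                except ValueError:
                    raise EncodingError(
                        f"grapheme {symbol!r} not in {group} group"
                    ) from None
            offset += len(members)
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class PhonemeSlotScheme:
    """Ordered phoneme inventories plus a compound-phoneme decomposition map.

    ``compound_map`` sends a compound phoneme (e.g. a cluster coded as a
    single unit) to its constituent phonemes; constituents must live in the
    same slot group as the compound.
    """

    onset: tuple[str, ...]
    vowel: tuple[str, ...]
    coda: tuple[str, ...]
    compound_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __init__(
        self,
        onset: Iterable[str],
        vowel: Iterable[str],
        coda: Iterable[str],
        compound_map: dict[str, Sequence[str]] | None = None,
    ):
        object.__setattr__(self, "onset", _check_group(tuple(onset), "onset"))
        object.__setattr__(self, "vowel", _check_group(tuple(vowel), "vowel"))
        object.__setattr__(self, "coda", _check_group(tuple(coda), "coda"))
        cmap = {k: tuple(v) for k, v in (compound_map or {}).items()}
        object.__setattr__(self, "compound_map", cmap)
        for compound, parts in cmap.items():
            grp = self._group_of(compound)
            if grp is None:
                raise LexiconFormatError(f"compound {compound!r} not in any group")
            members = self.group(grp)
            for p in parts:
                if p not in members:
                    raise LexiconFormatError(
                        f"constituent {p!r} of compound {compound!r} "
                        f"not in the {grp} group"
                    )

    def _group_of(self, symbol: str) -> str | None:
        for grp in GROUPS:
            if symbol in self.group(grp):
                return grp
        return None

    @property
    def n_units(self) -> int:
        return len(self.onset) + len(self.vowel) + len(self.coda)

    def group(self, name: str) -> tuple[str, ...]:
        return {"onset": self.onset, "vowel": self.vowel, "coda": self.coda}[name]

    @property
    def unit_labels(self) -> list[str]:
        return [f"{grp}:{sym}" for grp in GROUPS for sym in self.group(grp)]

    def unit_index(self, group: str, symbol: str) -> int:
        offset = 0
        for grp in GROUPS:
            members = self.group(grp)
            if grp == group:
                try:
                    return offset + members.index(symbol)
                except ValueError:
                    raise EncodingError(
                        f"phoneme {symbol!r} not in {group} group"
                    ) from None
            offset += len(members)
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class LexiconEntry:
    word_id: str
    spelling: str
    onset: tuple[str, ...]
    vowel: tuple[str, ...]
    coda: tuple[str, ...]
    p_onset: tuple[str, ...]
    p_vowel: tuple[str, ...]
    p_coda: tuple[str, ...]
    frequency: float

    def __init__(self, word_id, spelling, onset, vowel, coda,
                 p_onset, p_vowel, p_coda, frequency):
        object.__setattr__(self, "word_id", str(word_id))
        object.__setattr__(self, "spelling", str(spelling).lower())
        object.__setattr__(self, "onset", tuple(g.lower() for g in onset))
        object.__setattr__(self, "vowel", tuple(g.lower() for g in vowel))
        object.__setattr__(self, "coda", tuple(g.lower() for g in coda))
        object.__setattr__(self, "p_onset", tuple(p_onset))
        object.__setattr__(self, "p_vowel", tuple(p_vowel))
        object.__setattr__(self, "p_coda", tuple(p_coda))
        object.__setattr__(self, "frequency", float(frequency))
        if self.frequency <= 0:
            raise LexiconFormatError(
                f"word {self.word_id!r}: frequency must be > 0, got {frequency}"
            )
        joined = "".join(self.onset + self.vowel + self.coda)
        if joined != self.spelling:
            raise LexiconFormatError(
                f"word {self.word_id!r}: graphemes {joined!r} do not spell "
                f"{self.spelling!r}"
            )

    def graphemes(self, group: str) -> tuple[str, ...]:
        return {"onset": self.onset, "vowel": self.vowel, "coda": self.coda}[group]

    def phonemes(self, group: str) -> tuple[str, ...]:
        return {"onset": self.p_onset, "vowel": self.p_vowel, "coda": self.p_coda}[group]

    @property
    def pronunciation(self) -> tuple[str, ...]:
        return self.p_onset + self.p_vowel + self.p_coda


@dataclass(frozen=True)
class Lexicon:
    """An ordered collection of entries sharing a grapheme and phoneme scheme."""

    entries: tuple[LexiconEntry, ...]
    grapheme_scheme: GraphemeSlotScheme
    phoneme_scheme: PhonemeSlotScheme

    def __init__(self, entries, grapheme_scheme, phoneme_scheme):
        entries = tuple(entries)
        ids = [e.word_id for e in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LexiconFormatError(f"duplicate word_ids: {dupes}")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "grapheme_scheme", grapheme_scheme)
        object.__setattr__(self, "phoneme_scheme", phoneme_scheme)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i) -> LexiconEntry:
        return self.entries[i]

    @property
    def word_ids(self) -> list[str]:
        return [e.word_id for e in self.entries]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency for e in self.entries], dtype=float)


@dataclass(frozen=True)
class BinaryFeatureMatrix:
    """Stimuli-by-units {0,1} matrix with row (word) and column (unit) labels."""

    row_labels: tuple[str, ...]
    unit_labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, row_labels, unit_labels, values):
        values = np.asarray(values, dtype=np.uint8)
        row_labels = tuple(row_labels)
        unit_labels = tuple(unit_labels)
        if values.shape != (len(row_labels), len(unit_labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("entries must be binary")
        object.__setattr__(self, "row_labels", row_labels)
        object.__setattr__(self, "unit_labels", unit_labels)
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def encode_orthography(entry: LexiconEntry, scheme: GraphemeSlotScheme) -> np.ndarray:
    """Binary orthographic vector for one entry.

    Each used grapheme activates its own unit; a multi-letter grapheme also
    activates the units of its single-letter constituents when those letters
    are members of the same slot group (constituents belonging to other
    groups are not activated).
    """
    vec = np.zeros(scheme.n_units, dtype=np.uint8)
    for grp in GROUPS:
        members = scheme.group(grp)
        for g in entry.graphemes(grp):
            vec[scheme.unit_index(grp, g)] = 1
            if len(g) > 1:
                for letter in g:
                    if letter in members:
                        vec[scheme.unit_index(grp, letter)] = 1
    return vec


def encode_phonology(entry: LexiconEntry, scheme: PhonemeSlotScheme) -> np.ndarray:
    """Binary phonological vector; compound phonemes activate constituents."""
    vec = np.zeros(scheme.n_units, dtype=np.uint8)
    for grp in GROUPS:
        for p in entry.phonemes(grp):
            vec[scheme.unit_index(grp, p)] = 1
            for part in scheme.compound_map.get(p, ()):
                vec[scheme.unit_index(grp, part)] = 1
    return vec


def encode_lexicon(lexicon: Lexicon, channel: Channel) -> BinaryFeatureMatrix:
    """Encode every entry; rows follow lexicon order."""
    if channel == "orthography":
        scheme = lexicon.grapheme_scheme
        enc = lambda e: encode_orthography(e, scheme)  # noqa: E731
    elif channel == "phonology":
        scheme = lexicon.phoneme_scheme
        enc = lambda e: encode_phonology(e, scheme)  # noqa: E731
    else:
        raise ValueError(f"unknown channel {channel!r}")
    rows = []
    for entry in lexicon:
        try:
            rows.append(enc(entry))
        except EncodingError as exc:
            raise EncodingError(f"word {entry.word_id!r}: {exc}") from exc
    values = np.vstack(rows) if rows else np.zeros((0, scheme.n_units), np.uint8)
    return BinaryFeatureMatrix(lexicon.word_ids, scheme.unit_labels, values)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_LEXICON_COLUMNS = [
    "word_id", "onset", "vowel", "coda",
    "p_onset", "p_vowel", "p_coda", "freq_per_million",
]


def _split(field_value: str) -> tuple[str, ...]:
    return tuple(field_value.split("+")) if field_value else ()


def _join(seq: Sequence[str]) -> str:
    return "+".join(seq)


def write_lexicon_tsv(lexicon: Lexicon, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LEXICON_COLUMNS)
        for e in lexicon:
            writer.writerow([
                e.word_id, _join(e.onset), _join(e.vowel), _join(e.coda),
                _join(e.p_onset), _join(e.p_vowel), _join(e.p_coda),
                repr(e.frequency),
            ])


def read_lexicon_tsv(path, grapheme_scheme: GraphemeSlotScheme,
                     phoneme_scheme: PhonemeSlotScheme) -> Lexicon:
    """Read a tab-separated lexicon; malformed rows raise with their line number."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconFormatError(f"{path}: empty file") from None
        if header != _LEXICON_COLUMNS:
            raise LexiconFormatError(
                f"{path}: expected columns {_LEXICON_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_LEXICON_COLUMNS):
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected {len(_LEXICON_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            try:
                onset, vowel, coda = map(_split, row[1:4])
                entry = LexiconEntry(
                    word_id=row[0],
                    spelling="".join(onset + vowel + coda),
                    onset=onset, vowel=vowel, coda=coda,
                    p_onset=_split(row[4]), p_vowel=_split(row[5]),
                    p_coda=_split(row[6]),
                    frequency=float(row[7]),
                )
            except (ValueError, LexiconFormatError) as exc:
                raise LexiconFormatError(f"{path}:{lineno}: {exc}") from exc
            entries.append(entry)
    lex = Lexicon(entries, grapheme_scheme, phoneme_scheme)
    _validate_encodable(lex)
    return lex


def _validate_encodable(lexicon: Lexicon) -> None:
    for entry in lexicon:
        for grp in GROUPS:
            for g in entry.graphemes(grp):
                if g not in lexicon.grapheme_scheme.group(grp):
                    raise LexiconFormatError(
                        f"word {entry.word_id!r}: grapheme {g!r} not in "
                        f"{grp} group of scheme"
                    )
            for p in entry.phonemes(grp):
                if p not in lexicon.phoneme_scheme.group(grp):
                    raise LexiconFormatError(
                        f"word {entry.word_id!r}: phoneme {p!r} not in "
                        f"{grp} group of scheme"
                    )


def write_scheme_tsv(scheme, path) -> None:
    """Scheme file: columns group, symbol, constituents ('+'-joined)."""
    compound_map = getattr(scheme, "compound_map", {})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group", "symbol", "constituents"])
        for grp in GROUPS:
            for sym in scheme.group(grp):
                writer.writerow([grp, sym, _join(compound_map.get(sym, ()))])


def read_scheme_tsv(path, kind: Channel):
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    compound_map: dict[str, tuple[str, ...]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["group", "symbol", "constituents"]:
            raise LexiconFormatError(f"{path}: bad scheme header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3 or row[0] not in GROUPS:
                raise LexiconFormatError(f"{path}:{lineno}: malformed scheme row")
            groups[row[0]].append(row[1])
            if row[2]:
                compound_map[row[1]] = _split(row[2])
    if kind == "orthography":
        return GraphemeSlotScheme(groups["onset"], groups["vowel"], groups["coda"])
    return PhonemeSlotScheme(groups["onset"], groups["vowel"], groups["coda"],
                             compound_map)


def segment_greedy(spelling: str, scheme: GraphemeSlotScheme
                   ) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Greedy longest-match segmentation of a spelling into slot graphemes.

    Utility for synthetic lexicon generation only; the analysis path takes
    words pre-segmented.
    """
    spelling = spelling.lower()
    pos = 0
    state = 0  # 0: onset, 1: vowel seen -> coda
    out: dict[str, list[str]] = {"onset": [], "vowel": [], "coda": []}
    while pos < len(spelling):
        allowed = ("onset", "vowel") if state == 0 else ("coda",)
        best: tuple[str, str] | None = None
        for grp in allowed:
            for sym in scheme.group(grp):
                if spelling.startswith(sym, pos):
                    if best is None or len(sym) > len(best[1]):
                        best = (grp, sym)
        if best is None:
            raise EncodingError(
                f"cannot segment {spelling!r} at position {pos}"
            )
        grp, sym = best
        out[grp].append(sym)
        if grp == "vowel":
            state = 1
        pos += len(sym)
    return tuple(out["onset"]), tuple(out["vowel"]), tuple(out["coda"])
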