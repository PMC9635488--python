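"""Synthetic inputs: artificial lexicons, nonwords, rules and beta volumes.

Everything the pipeline consumes can be generated here: a monosyllabic
artificial lexicon with controllable spelling-sound consistency and Zipfian
frequencies, nonword test items with multiple acceptable pronunciations, a
grapheme-phoneme rule table consistent with the lexicon's regular words, and
multi-subject beta-series volumes in which chosen regions carry a noisy
linear embedding of a chosen model's stimulus features.

All randomness flows from a top-level seed through named
``numpy.random.SeedSequence`` streams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import LexiconFormatError
from .lexicon import (
    GraphemeSlotScheme, Lexicon, LexiconEntry, PhonemeSlotScheme,
    encode_orthography, encode_phonology,
)
from .searchlight import BetaSeries, VolumeGrid, check_mask, sphere_offsets

log = logging.getLogger(__name__)

_CONSONANTS = "bcdfghjklmnpqrstvwxyz"   # 21 letters
_VOWELS = "aeiou"

_ONSET_PHONEMES = ["b", "d", "f", "g", "h", "j", "k", "l", "m", "n", "p",
                   "r", "s", "t", "v", "w", "z", "S", "T", "C", "D", "Z", "G"]
_VOWEL_PHONEMES = ["A", "E", "I", "O", "U", "@", "^", "e", "i", "o",
                   "u", "a", "W", "Y"]
_CODA_PHONEMES = ["p", "s", "t", "k", "b", "d", "f", "g", "l", "m", "n",
                  "r", "v", "z", "S", "T", "N", "C", "D", "Z", "J",
                  "ps", "ks", "ts"]
_CODA_COMPOUNDS = {"ps": ("p", "s"), "ks": ("k", "s"), "ts": ("t", "s")}


def _letter_group(pool: str, size: int, group: str) -> list[str]:
    """Singles from the pool, then deterministic digraphs, up to `size`."""
    out = list(pool)
    if size <= len(out):
        return out[:size]
    for a in pool:
        for b in pool:
            d = a + b
            if d not in out:
                out.append(d)
            if len(out) == size:
                return out
    raise ValueError(f"cannot build {size} graphemes for {group} from {pool!r}")


def _symbol_group(base: Sequence[str], size: int, prefix: str) -> list[str]:
    out = list(base)[:size]
    i = 0
    while len(out) < size:
        sym = f"{prefix}{i}"
        if sym not in out:
            out.append(sym)
        i += 1
    return out


def default_grapheme_scheme(n_onset: int = 30, n_vowel: int = 27,
                            n_coda: int = 48) -> GraphemeSlotScheme:
    """Deterministic synthetic grapheme inventories of the requested sizes.

    The paper-scale default is 30 onset, 27 vowel and 48 coda graphemes
    (105 units).  Onset and coda draw on consonant letters, the vowel group
    on vowel letters, so slot boundaries inside a spelling are unambiguous.
    """
    return GraphemeSlotScheme(
        onset=_letter_group(_CONSONANTS, n_onset, "onset"),
        vowel=_letter_group(_VOWELS, n_vowel, "vowel"),
        coda=_letter_group(_CONSONANTS, n_coda, "coda"),
    )


def default_phoneme_scheme(n_onset: int = 23, n_vowel: int = 14,
                           n_coda: int = 24) -> PhonemeSlotScheme:
    """Synthetic phoneme inventories; the 23/14/24 default gives 61 slots.

    The coda group carries three compound phonemes whose constituents are
    also coda members, mirroring cluster units that activate both the
    combination and its parts.
    """
    coda = _symbol_group(_CODA_PHONEMES, n_coda, "c")
    cmap = {k: v for k, v in _CODA_COMPOUNDS.items()
            if k in coda and all(p in coda for p in v)}
    return PhonemeSlotScheme(
        onset=_symbol_group(_ONSET_PHONEMES, n_onset, "o"),
        vowel=_symbol_group(_VOWEL_PHONEMES, n_vowel, "v"),
        coda=coda,
        compound_map=cmap,
    )


@dataclass(frozen=True)
class SyntheticLexiconSpec:
    n_onset_graphemes: int = 30
    n_vowel_graphemes: int = 27
    n_coda_graphemes: int = 48
    n_onset_phonemes: int = 23
    n_vowel_phonemes: int = 14
    n_coda_phonemes: int = 24
    n_words: int = 200
    exception_proportion: float = 0.1
    zipf_exponent: float = 1.1
    p_empty_onset: float = 0.15
    p_empty_coda: float = 0.25
    seed: int = 0
    max_length_frequency_r: float = 0.15
    max_retries: int = 20

    def __post_init__(self):
        if min(self.n_onset_graphemes, self.n_vowel_graphemes,
               self.n_coda_graphemes) < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 <= self.exception_proportion <= 1.0:
            raise ValueError("exception proportion must be in [0, 1]")
        if self.n_words < 2:
            raise ValueError("need at least 2 words")


class CanonicalMap:
    """Deterministic regular grapheme-to-phoneme mapping per slot group.

    Grapheme i of a group maps to phoneme i modulo the group's phoneme
    count; the exception alternative for a vowel grapheme is the next vowel
    phoneme in the inventory.
    """

    def __init__(self, gscheme: GraphemeSlotScheme, pscheme: PhonemeSlotScheme):
        self.gscheme = gscheme
        self.pscheme = pscheme

    def regular(self, group: str, grapheme: str) -> str:
        gs = self.gscheme.group(group)
        ps = self.pscheme.group(group)
        return ps[gs.index(grapheme) % len(ps)]

    def exception_vowel(self, grapheme: str) -> str:
        gs = self.gscheme.vowel
        ps = self.pscheme.vowel
        return ps[(gs.index(grapheme) + 1) % len(ps)]


def _zipf_frequencies(n: int, exponent: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """Occurrences per million under a Zipf law, ranks randomly assigned."""
    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** (-exponent)
    return 1e6 * weights / weights.sum()


def generate_lexicon(spec: SyntheticLexiconSpec) -> Lexicon:
    """Generate a monosyllabic artificial lexicon.

    Words are onset+vowel+coda grapheme draws (onset/coda optionally empty)
    with unique spellings; pronunciations follow the canonical mapping
    except for an exact number of exception words, which receive a deviant
    vowel phoneme.  Exceptions are capped per vowel grapheme so the regular
    mapping stays the majority mapping for every grapheme.  Frequencies are
    Zipfian and independent of spelling; the draw is retried (bounded, with
    fresh substreams) until |r(length, log frequency)| is below the spec
    threshold.
    """
    gscheme = default_grapheme_scheme(
        spec.n_onset_graphemes, spec.n_vowel_graphemes, spec.n_coda_graphemes)
    pscheme = default_phoneme_scheme(
        spec.n_onset_phonemes, spec.n_vowel_phonemes, spec.n_coda_phonemes)
    cmap = CanonicalMap(gscheme, pscheme)
    root = np.random.SeedSequence(spec.seed)
    for attempt, child in enumerate(root.spawn(spec.max_retries)):
        rng = np.random.default_rng(child)
        lexicon = _generate_once(spec, gscheme, pscheme, cmap, rng)
        lengths = np.array([len(e.spelling) for e in lexicon], dtype=float)
        logf = np.log(lexicon.frequencies)
        r = float(np.corrcoef(lengths, logf)[0, 1])
        if abs(r) < spec.max_length_frequency_r:
            if attempt:
                log.info("lexicon decorrelation met after %d retries", attempt)
            return lexicon
        log.info("attempt %d: |r(length, log f)| = %.3f >= %.3f; retrying",
                 attempt, abs(r), spec.max_length_frequency_r)
    raise RuntimeError("could not decorrelate length and frequency "
                       f"in {spec.max_retries} attempts")


def _generate_once(spec, gscheme, pscheme, cmap: CanonicalMap,
                   rng: np.random.Generator) -> Lexicon:
    seen: set[str] = set()
    triples: list[tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]] = []
    guard = 0
    while len(triples) < spec.n_words:
        guard += 1
        if guard > spec.n_words * 200:
            raise RuntimeError("cannot draw enough unique spellings; "
                               "increase inventories or reduce n_words")
        onset = (() if rng.random() < spec.p_empty_onset
                 else (gscheme.onset[rng.integers(len(gscheme.onset))],))
        vowel = (gscheme.vowel[rng.integers(len(gscheme.vowel))],)
        coda = (() if rng.random() < spec.p_empty_coda
                else (gscheme.coda[rng.integers(len(gscheme.coda))],))
        spelling = "".join(onset + vowel + coda)
        if spelling in seen:
            continue
        seen.add(spelling)
        triples.append((onset, vowel, coda))

    n_exceptions = int(round(spec.exception_proportion * spec.n_words))
    exception_ids = _pick_exceptions(triples, n_exceptions, rng)

    freqs = _zipf_frequencies(spec.n_words, spec.zipf_exponent, rng)
    entries = []
    for i, (onset, vowel, coda) in enumerate(triples):
        p_on = tuple(cmap.regular("onset", g) for g in onset)
        p_cd = tuple(cmap.regular("coda", g) for g in coda)
        if i in exception_ids:
            p_vw = (cmap.exception_vowel(vowel[0]),)
        else:
            p_vw = (cmap.regular("vowel", vowel[0]),)
        entries.append(LexiconEntry(
            word_id=f"w{i:04d}", spelling="".join(onset + vowel + coda),
            onset=onset, vowel=vowel, coda=coda,
            p_onset=p_on, p_vowel=p_vw, p_coda=p_cd,
            frequency=float(freqs[i]),
        ))
    return Lexicon(entries, gscheme, pscheme)


def _pick_exceptions(triples, n_exceptions: int, rng: np.random.Generator
                     ) -> set[int]:
    """Choose exception word indices, keeping regulars the strict majority
    for every vowel grapheme."""
    if n_exceptions == 0:
        return set()
    by_vowel: dict[str, list[int]] = {}
    for i, (_, vowel, _) in enumerate(triples):
        by_vowel.setdefault(vowel[0], []).append(i)
    caps = {v: max(0, (len(idx) - 1) // 2) for v, idx in by_vowel.items()}
    if sum(caps.values()) < n_exceptions:
        raise RuntimeError(
            f"cannot plant {n_exceptions} exceptions while keeping the "
            f"regular mapping a per-grapheme majority"
        )
    chosen: set[int] = set()
    used = {v: 0 for v in by_vowel}
    for i in rng.permutation(len(triples)):
        v = triples[i][1][0]
        if used[v] < caps[v]:
            chosen.add(int(i))
            used[v] += 1
            if len(chosen) == n_exceptions:
                break
    return chosen


def exception_word_ids(lexicon: Lexicon) -> list[str]:
    """Words whose vowel phoneme deviates from the canonical mapping."""
    cmap = CanonicalMap(lexicon.grapheme_scheme, lexicon.phoneme_scheme)
    out = []
    for e in lexicon:
        if e.p_vowel and e.p_vowel[0] != cmap.regular("vowel", e.vowel[0]):
            out.append(e.word_id)
    return out


# ---------------------------------------------------------------------------
# Nonwords
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nonword:
    word_id: str
    spelling: str
    onset: tuple[str, ...]
    vowel: tuple[str, ...]
    coda: tuple[str, ...]
    # each pronunciation: (onset phonemes, vowel phonemes, coda phonemes)
    pronunciations: tuple[tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self):
        if not self.pronunciations:
            raise ValueError(f"nonword {self.word_id!r} has no pronunciations")


def generate_nonwords(lexicon: Lexicon, n: int, seed: int,
                      min_attestation: int = 3) -> list[Nonword]:
    """Unused grapheme combinations with all plausible pronunciations.

    Spellings recombine onset/vowel/coda grapheme patterns attested in the
    lexicon and are rejected if present there.  Patterns containing a
    grapheme attested fewer than ``min_attestation`` times are excluded
    (pronounceable nonwords use familiar spelling patterns; a mapping seen
    once or twice is not a pattern); the threshold backs off automatically
    if it would leave a slot group empty.  Acceptable pronunciations are
    the canonical (regular) one plus, for the item's vowel grapheme, every
    deviant vowel mapping attested among the lexicon's exception words.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cmap = CanonicalMap(lexicon.grapheme_scheme, lexicon.phoneme_scheme)
    from collections import Counter
    counts: Counter = Counter()
    for e in lexicon:
        for grp in ("onset", "vowel", "coda"):
            for g in e.graphemes(grp):
                counts[(grp, g)] += 1

    def attested(group: str, seqs) -> list:
        for thresh in range(min_attestation, 0, -1):
            kept = sorted({s for s in seqs
                           if all(counts[(group, g)] >= thresh for g in s)})
            if kept:
                if thresh < min_attestation:
                    log.info("nonwords: %s attestation threshold lowered "
                             "to %d", group, thresh)
                return kept
        raise RuntimeError(f"no usable {group} patterns in lexicon")

    onsets = attested("onset", (e.onset for e in lexicon))
    vowels = attested("vowel", (e.vowel for e in lexicon))
    codas = attested("coda", (e.coda for e in lexicon))
    known = {e.spelling for e in lexicon}
    # deviant vowel phonemes attested per vowel grapheme
    deviants: dict[str, set[str]] = {}
    for e in lexicon:
        reg = cmap.regular("vowel", e.vowel[0])
        if e.p_vowel[0] != reg:
            deviants.setdefault(e.vowel[0], set()).add(e.p_vowel[0])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[Nonword] = []
    seen: set[str] = set()
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > n * 1000:
            raise RuntimeError("cannot draw enough unused spellings")
        onset = onsets[rng.integers(len(onsets))]
        vowel = vowels[rng.integers(len(vowels))]
        coda = codas[rng.integers(len(codas))]
        spelling = "".join(onset + vowel + coda)
        if not spelling or spelling in known or spelling in seen:
            continue
        seen.add(spelling)
        p_on = tuple(cmap.regular("onset", g) for g in onset)
        p_cd = tuple(cmap.regular("coda", g) for g in coda)
        prons = [(p_on, (cmap.regular("vowel", vowel[0]),), p_cd)]
        for dev in sorted(deviants.get(vowel[0], ())):
            prons.append((p_on, (dev,), p_cd))
        out.append(Nonword(
            word_id=f"nw{len(out):04d}", spelling=spelling,
            onset=onset, vowel=vowel, coda=coda,
            pronunciations=tuple(prons),
        ))
    return out


def _nonword_entry(nw: Nonword, pron) -> LexiconEntry:
    return LexiconEntry(
        word_id=nw.word_id, spelling=nw.spelling,
        onset=nw.onset, vowel=nw.vowel, coda=nw.coda,
        p_onset=pron[0], p_vowel=pron[1], p_coda=pron[2], frequency=1.0)


def nonword_orthography(nonwords: Sequence[Nonword],
                        scheme: GraphemeSlotScheme) -> np.ndarray:
    rows = [encode_orthography(_nonword_entry(nw, nw.pronunciations[0]), scheme)
            for nw in nonwords]
    return np.vstack(rows)


def nonword_targets(nonwords: Sequence[Nonword], scheme: PhonemeSlotScheme
                    ) -> list[list[np.ndarray]]:
    """Per nonword, the binary target vector of each acceptable pronunciation."""
    out = []
    for nw in nonwords:
        out.append([encode_phonology(_nonword_entry(nw, p), scheme)
                    for p in nw.pronunciations])
    return out


def _fmt_pron(pron) -> str:
    return "/".join("+".join(slot) for slot in pron)


def _parse_pron(text: str):
    slots = text.split("/")
    if len(slots) != 3:
        raise LexiconFormatError(f"bad pronunciation field {text!r}")
    return tuple(tuple(s.split("+")) if s else () for s in slots)


def write_nonwords_tsv(nonwords: Sequence[Nonword], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["word_id", "onset", "vowel", "coda", "pronunciations"])
        for nw in nonwords:
            writer.writerow([
                nw.word_id, "+".join(nw.onset), "+".join(nw.vowel),
                "+".join(nw.coda),
                "|".join(_fmt_pron(p) for p in nw.pronunciations),
            ])


def read_nonwords_tsv(path) -> list[Nonword]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["word_id", "onset", "vowel", "coda", "pronunciations"]:
            raise LexiconFormatError(f"{path}: bad nonword header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise LexiconFormatError(f"{path}:{lineno}: expected 5 fields")
            onset = tuple(row[1].split("+")) if row[1] else ()
            vowel = tuple(row[2].split("+")) if row[2] else ()
            coda = tuple(row[3].split("+")) if row[3] else ()
            prons = tuple(_parse_pron(p) for p in row[4].split("|"))
            out.append(Nonword(row[0], "".join(onset + vowel + coda),
                               onset, vowel, coda, prons))
    return out


# ---------------------------------------------------------------------------
# Brain volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRoiSpec:
    """A spherical region carrying a linear embedding of model features."""

    center: tuple[int, int, int]
    radius: int
    source: str
    gain: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def ellipsoid_mask(grid: VolumeGrid,
                   semi_axes: tuple[float, float, float] | float,
                   center: tuple[float, float, float] | None = None
                   ) -> np.ndarray:
    """Ellipsoidal stand-in for a gray-matter mask (voxel units)."""
    if np.isscalar(semi_axes):
        semi_axes = (semi_axes,) * 3
    if center is None:
        center = tuple((s - 1) / 2.0 for s in grid.shape)
    idx = np.indices(grid.shape, dtype=float)
    dist2 = sum(((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    return dist2 <= 1.0


def roi_mask(grid: VolumeGrid, roi: PlantedRoiSpec,
             mask: np.ndarray) -> np.ndarray:
    """Voxels of the planted sphere that fall inside the gray-matter mask."""
    out = np.zeros(grid.shape, dtype=bool)
    coords = np.asarray(roi.center) + sphere_offsets(roi.radius)
    inside = ((coords >= 0) & (coords < np.asarray(grid.shape))).all(axis=1)
    coords = coords[inside]
    out[tuple(coords.T)] = True
    out &= mask
    if not out.any():
        raise ValueError(f"planted region at {roi.center} misses the mask")
    return out


def generate_beta_series(features: Mapping[str, np.ndarray],
                         labels: Sequence[str],
                         grid: VolumeGrid,
                         mask: np.ndarray,
                         roi_specs: Sequence[PlantedRoiSpec],
                         n_subjects: int,
                         seed: int,
                         baseline_noise_sd: float = 1.0,
                         ) -> tuple[list[BetaSeries], dict[str, np.ndarray]]:
    """Multi-subject beta volumes with planted representational geometry.

    Outside every planted region each beta is pure Gaussian noise.  Inside a
    region, the z-scored source feature matrix is mapped to the region's
    voxels by a random linear projection (redrawn per subject) scaled by the
    region's gain, plus Gaussian noise at the region's noise_sd.  Returns
    the subject series and a ground-truth map name -> region mask.

    Feature rows are centered and scaled to unit norm after column
    z-scoring, so the expected voxel-pattern correlation between two
    stimuli is a uniform attenuation of their feature-row Pearson
    correlation: the planted neural geometry is a rank-preserving image of
    the source RDM rather than one warped by per-stimulus norms.
    """
    from .rdm import zscore_features

    def _row_normalize(Z: np.ndarray) -> np.ndarray:
        Zc = Z - Z.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(Zc, axis=1, keepdims=True)
        if (nrm == 0).any():
            raise ValueError("a stimulus has constant features after z-scoring")
        return Zc / nrm

    mask = check_mask(mask, grid)
    labels = tuple(str(s) for s in labels)
    n_stim = len(labels)
    zfeat = {}
    regions: dict[str, np.ndarray] = {}
    colmap = np.flatnonzero(mask.ravel())
    col_of = {flat: i for i, flat in enumerate(colmap)}
    roi_cols = []
    for k, roi in enumerate(roi_specs):
        if roi.source not in features:
            raise KeyError(f"no feature matrix for source {roi.source!r}")
        if features[roi.source].shape[0] != n_stim:
            raise ValueError(f"features for {roi.source!r} do not match labels")
        if roi.source not in zfeat:
            zfeat[roi.source] = _row_normalize(zscore_features(features[roi.source]))
        rmask = roi_mask(grid, roi, mask)
        regions[f"roi{k}_{roi.source}"] = rmask
        cols = np.array([col_of[f] for f in np.flatnonzero(rmask.ravel())])
        roi_cols.append(cols)

    root = np.random.SeedSequence(seed)
    subjects = []
    for s, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        data = rng.normal(0.0, baseline_noise_sd, (n_stim, int(mask.sum())))
        for roi, cols in zip(roi_specs, roi_cols):
            Z = zfeat[roi.source]
            proj = rng.normal(0.0, 1.0, (Z.shape[1], len(cols)))
            signal = roi.gain * (Z @ proj)  # unit-norm rows: per-voxel sd = gain
            noise = rng.normal(0.0, roi.noise_sd, (n_stim, len(cols)))
            data[:, cols] = signal + noise
        subjects.append(BetaSeries(f"sub{s:02d}", grid, labels, mask, data))
    return subjects, regions


def write_ground_truth(regions: Mapping[str, np.ndarray], path) -> None:
    payload = {name: np.argwhere(m).tolist() for name, m in regions.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path, shape) -> dict[str, np.ndarray]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for name, coords in payload.items():
        m = np.zeros(shape, dtype=bool)
        if coords:
            m[tuple(np.asarray(coords).T)] = True
        out[name] = m
    return out


# ---------------------------------------------------------------------------
# Whole-dataset orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDatasetSpec:
    lexicon: SyntheticLexiconSpec = field(default_factory=SyntheticLexiconSpec)
    n_nonwords: int = 60
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    mask_semi_axes: tuple[float, float, float] = (9.0, 9.0, 9.0)
    rois: tuple[PlantedRoiSpec, ...] = (
        PlantedRoiSpec(center=(12, 12, 12), radius=4,
                       source="orthography", gain=1.0),
    )
    n_subjects: int = 18
    seed: int = 0


@dataclass
class SyntheticDataset:
    lexicon: Lexicon
    nonwords: list[Nonword]
    ruleset: "object"
    grid: VolumeGrid
    mask: np.ndarray
    betas: list[BetaSeries]
    regions: dict[str, np.ndarray]
    features: dict[str, np.ndarray]


def make_dataset(spec: SyntheticDatasetSpec,
                 extra_features: Mapping[str, np.ndarray] | None = None,
                 ann_config=None,
                 ) -> SyntheticDataset:
    """Generate lexicon, nonwords, rules and planted beta volumes.

    Feature sources 'orthography', 'phonology' and 'gpc' are computed from
    the generated lexicon.  If an ROI names the source 'ann_hidden', a
    single network instantiation is trained on the lexicon (``ann_config``
    or defaults, seeded from the dataset seed) and its hidden-layer matrix
    is used.  Any other source must be supplied via ``extra_features``.
    """
    from . import gpc as gpc_mod
    from .lexicon import encode_lexicon

    ss = np.random.SeedSequence(spec.seed)
    lex_seed, nw_seed, beta_seed, ann_seed = (int(c.generate_state(1)[0])
                                              for c in ss.spawn(4))
    lexicon = generate_lexicon(replace(spec.lexicon, seed=lex_seed))
    nonwords = generate_nonwords(lexicon, spec.n_nonwords, nw_seed)
    ruleset = gpc_mod.generate_rules(lexicon)
    orth = encode_lexicon(lexicon, "orthography").values.astype(float)
    phon = encode_lexicon(lexicon, "phonology").values.astype(float)
    features: dict[str, np.ndarray] = {
        "orthography": orth,
        "phonology": phon,
        "gpc": gpc_mod.gpc_representation(lexicon, ruleset).astype(float),
    }
    if extra_features:
        features.update(extra_features)
    needs_ann = any(r.source == "ann_hidden" for r in spec.rois)
    if needs_ann and "ann_hidden" not in features:
        from dataclasses import replace as _replace

        from .ann import AnnConfig, hidden_representations, initialize_model, train
        cfg = ann_config or AnnConfig(epochs=150)
        cfg = _replace(cfg, n_input=orth.shape[1], n_output=phon.shape[1],
                       seed=ann_seed % (2**31))
        model, _ = train(initialize_model(cfg), orth, phon,
                         lexicon.frequencies, cfg)
        features["ann_hidden"] = hidden_representations(model, orth)
    grid = VolumeGrid(spec.grid_shape,
                      (spec.voxel_size_mm,) * 3)
    mask = ellipsoid_mask(grid, spec.mask_semi_axes)
    betas, regions = generate_beta_series(
        features, lexicon.word_ids, grid, mask, spec.rois,
        spec.n_subjects, beta_seed)
    return SyntheticDataset(lexicon, nonwords, ruleset, grid, mask,
                            betas, regions, features)
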