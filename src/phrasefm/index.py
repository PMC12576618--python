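"""The two-level FM-index and its count query.

The index couples an FM-index over the character-level text S with an
FM-index over the phrase-level parse P.  A bitvector B marks the rows of
the BWT matrix of S whose rotations start at a phrase boundary (a trigger
occurrence); because phrase IDs inherit the lexicographic order of their
phrases and the dictionary is prefix-free, the i-th marked row of S
corresponds to the i-th row of the BWT matrix of P, so ``rank``/``select``
on B convert intervals between the two levels.

A count query backward-searches the pattern's suffix beta character by
character, hops to the parse level, consumes the complete phrases one ID
per step, hops back, and finishes with the remainder of the prefix alpha
character by character.  For patterns spanning several phrases this does
far fewer rank queries than plain character-level search; the result is
always the exact number of (possibly overlapping) occurrences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .alphabet import SENTINEL, Alphabet
from .fm import EMPTY_INTERVAL, FMIndex, Interval, IntText, build_suffix_array, bwt_from_sa
from .pfp import (
    NOT_IN_TEXT,
    Dictionary,
    Parse,
    ParseParams,
    PartialEncoding,
    build_pfp,
    parse_pattern,
)

__all__ = [
    "MarkBitvector",
    "PhraseMap",
    "PFPFMIndex",
    "CountTrace",
    "IndexLoadError",
    "build_index",
    "map_to_parse",
    "map_to_text",
    "trigger_aligned",
    "count",
    "count_trace",
    "count_single_level",
    "save_index",
    "load_index",
]

_FORMAT_MAGIC = "phrasefm-index"
_FORMAT_VERSION = 1


class MarkBitvector:
    """Bitvector with rank/select, stored as the sorted positions of its 1s."""

    def __init__(self, n: int, one_positions: np.ndarray):
        ones = np.asarray(one_positions, dtype=np.int64)
        if ones.size and (ones.min() < 0 or ones.max() >= n):
            raise ValueError("mark position outside the bitvector")
        if np.any(np.diff(ones) <= 0):
            raise ValueError("mark positions must be strictly increasing")
        self.n = int(n)
        self.ones = ones

    @property
    def num_ones(self) -> int:
        return len(self.ones)

    @property
    def num_runs(self) -> int:
        """Number of maximal runs of 1s."""
        if not len(self.ones):
            return 0
        return int(np.count_nonzero(np.diff(self.ones) > 1)) + 1

    def __getitem__(self, i: int) -> int:
        return int(np.any(self.ones == i))

    def rank1(self, i: int) -> int:
        """Number of 1s in bits[0..i-1]."""
        if not 0 <= i <= self.n:
            raise IndexError(f"rank position {i} outside [0, {self.n}]")
        return int(np.searchsorted(self.ones, i, side="left"))

    def select1(self, k: int) -> int:
        """Position of the k-th 1 (1-indexed)."""
        if not 1 <= k <= len(self.ones):
            raise IndexError(f"select index {k} outside [1, {len(self.ones)}]")
        return int(self.ones[k - 1])

    def to_bits(self) -> np.ndarray:
        bits = np.zeros(self.n, dtype=np.uint8)
        bits[self.ones] = 1
        return bits


class PhraseMap:
    """Exact fingerprint-to-ID map over the dictionary phrases.

    Lookups hash the candidate phrase and then verify it character by
    character against the stored phrase, so a string outside the
    dictionary always maps to None — no false positives, regardless of
    hash collisions.
    """

    def __init__(self, dictionary: Dictionary, params: ParseParams):
        self.dictionary = dictionary
        self.params = params
        self._table: dict[int, list[int]] = {}
        for pid, phrase in enumerate(dictionary.phrases):
            self._table.setdefault(self._hash(phrase), []).append(pid)

    def _hash(self, phrase: str) -> int:
        h = 0
        base, mod = self.params.hash_base, self.params.hash_modulus
        for c in phrase:
            h = (h * base + ord(c)) % mod
        return h

    def lookup(self, phrase: str) -> int | None:
        for pid in self._table.get(self._hash(phrase), ()):
            if self.dictionary.phrases[pid] == phrase:
                return pid
        return None


@dataclass
class PFPFMIndex:
    """Everything needed to answer count queries on the indexed text."""

    fm_text: FMIndex
    fm_parse: FMIndex
    marks: MarkBitvector
    phrase_map: PhraseMap
    dictionary: Dictionary
    parse: Parse
    rotated_parse: tuple[int, ...]
    params: ParseParams
    alphabet: Alphabet
    text_length: int

    @property
    def n(self) -> int:
        return self.text_length


class IndexLoadError(Exception):
    """Raised when an index file is unreadable, corrupt or incompatible."""


def build_index(text: str, params: ParseParams) -> PFPFMIndex:
    """Parse, index and mark a text; appends the sentinel when missing."""
    text = text.upper()
    if not text.endswith(SENTINEL):
        text = text + SENTINEL
    dictionary, parse = build_pfp(text, params)

    alphabet = Alphabet(set(text))
    n = len(text)
    int_text = IntText(alphabet.encode(text), alphabet.size)
    sa = build_suffix_array(int_text)
    fm_text = bwt_from_sa(int_text, sa)

    # phrase boundaries in text coordinates: S' position j <-> S position (j-1) mod n
    boundary = np.sort((np.asarray(parse.occ_starts, dtype=np.int64) - 1) % n)
    marked_rows = np.flatnonzero(np.isin(np.asarray(sa), boundary))
    marks = MarkBitvector(n, marked_rows)

    # rotate the parse so the sentinel-anchored phrase (ID 0, unique) is terminal
    ids = np.asarray(parse.ids, dtype=np.int64)
    pos0 = int(np.flatnonzero(ids == 0)[0])
    rotated = tuple(int(x) for x in np.roll(ids, -(pos0 + 1)))
    int_parse = IntText(np.asarray(rotated, dtype=np.int64), len(dictionary))
    fm_parse = bwt_from_sa(int_parse, build_suffix_array(int_parse))

    return PFPFMIndex(
        fm_text=fm_text,
        fm_parse=fm_parse,
        marks=marks,
        phrase_map=PhraseMap(dictionary, params),
        dictionary=dictionary,
        parse=parse,
        rotated_parse=rotated,
        params=params,
        alphabet=alphabet,
        text_length=n,
    )


def trigger_aligned(idx: PFPFMIndex, iv: Interval) -> bool:
    """True iff every row of the text-level interval is marked."""
    if iv.is_empty:
        raise ValueError("trigger alignment is undefined for an empty interval")
    return idx.marks.rank1(iv.hi + 1) - idx.marks.rank1(iv.lo) == iv.size


def map_to_parse(idx: PFPFMIndex, iv: Interval) -> Interval:
    """Text-level interval (all rows marked) -> parse-level interval."""
    if iv.is_empty:
        raise ValueError("cannot map an empty interval")
    if not trigger_aligned(idx, iv):
        raise ValueError("interval contains unmarked rows; not trigger-aligned")
    return Interval(idx.marks.rank1(iv.lo), idx.marks.rank1(iv.hi))


def map_to_text(idx: PFPFMIndex, iv: Interval) -> Interval:
    """Parse-level interval -> interval over the marked rows of the text BWT."""
    if iv.is_empty:
        raise ValueError("cannot map an empty interval")
    if iv.lo < 0 or iv.hi >= idx.marks.num_ones:
        raise IndexError("parse-level interval out of range")
    return Interval(idx.marks.select1(iv.lo + 1), idx.marks.select1(iv.hi + 1))


@dataclass
class CountTrace:
    """Interval chain of one count query, for inspection and self-tests."""

    pattern: str
    encoding: PartialEncoding | None  # None when the pattern was rejected early
    beta_interval: Interval | None = None  # text level, after searching beta
    parse_start: Interval | None = None  # parse level, after mapping down
    parse_final: Interval | None = None  # parse level, after the phrase IDs
    mapped_back: Interval | None = None  # text level, after mapping up
    final: Interval | None = None  # text level, after the alpha remainder
    count: int = 0


def _char_search(idx: PFPFMIndex, s: str, start: Interval | None = None) -> Interval:
    coded = idx.alphabet.try_encode(s)
    if coded is None:
        return EMPTY_INTERVAL
    return idx.fm_text.backward_search(coded, start=start)


def count_trace(idx: PFPFMIndex, pattern: str) -> CountTrace:
    """Two-level backward search; returns the full interval chain."""
    pattern = pattern.upper()
    if SENTINEL in pattern:
        raise ValueError("patterns must not contain the sentinel character")
    if pattern == "":
        # the empty pattern prefixes every rotation
        full = idx.fm_text.full_interval
        return CountTrace(pattern, None, final=full, count=full.size)

    enc = parse_pattern(pattern, idx.params, idx.phrase_map)
    if enc is NOT_IN_TEXT:
        return CountTrace(pattern, None, count=0)

    if not enc.ids:
        # fewer than two triggers: plain character-level backward search
        iv = _char_search(idx, pattern)
        return CountTrace(pattern, enc, final=iv, count=iv.size)

    trace = CountTrace(pattern, enc)
    if enc.beta:
        beta_iv = _char_search(idx, enc.beta)
        trace.beta_interval = beta_iv
        if beta_iv.is_empty:
            return trace
        # beta starts with a trigger, so every matching row is marked
        piv = map_to_parse(idx, beta_iv)
    else:
        piv = idx.fm_parse.full_interval
    trace.parse_start = piv

    piv = idx.fm_parse.backward_search(enc.ids, start=piv)
    trace.parse_final = piv
    if piv.is_empty:
        return trace

    iv = map_to_text(idx, piv)
    trace.mapped_back = iv

    if enc.alpha:
        # the trailing w characters of alpha are the trigger already matched
        remainder = enc.alpha[: -idx.params.w]
        if remainder:
            iv = _char_search(idx, remainder, start=iv)
            if iv.is_empty:
                trace.final = iv
                return trace
    trace.final = iv
    trace.count = iv.size
    return trace


def count(idx: PFPFMIndex, pattern: str) -> int:
    """Number of (possibly overlapping) occurrences of ``pattern`` in the text."""
    return count_trace(idx, pattern).count


def count_single_level(idx: PFPFMIndex, pattern: str) -> int:
    """Plain character-level FM-index count, bypassing the phrase level."""
    pattern = pattern.upper()
    if SENTINEL in pattern:
        raise ValueError("patterns must not contain the sentinel character")
    iv = _char_search(idx, pattern)
    return iv.size


def save_index(idx: PFPFMIndex, path) -> None:
    """Write a single self-describing index file.

    Format: magic line, 8-byte little-endian header length, a JSON header
    (parameters, hash constants, dictionary, array manifest), then the raw
    little-endian bytes of each array.  The layout is fully deterministic:
    rebuilding the same text with the same parameters produces a
    byte-identical file.
    """
    arrays = {
        "bwt_text": idx.fm_text.bwt.astype("<i8"),
        "bwt_parse": idx.fm_parse.bwt.astype("<i8"),
        "mark_ones": idx.marks.ones.astype("<i8"),
        "parse_ids": np.asarray(idx.parse.ids, dtype="<i8"),
        "occ_starts": np.asarray(idx.parse.occ_starts, dtype="<i8"),
        "rotated_parse": np.asarray(idx.rotated_parse, dtype="<i8"),
    }
    header = {
        "magic": _FORMAT_MAGIC,
        "version": _FORMAT_VERSION,
        "n": idx.text_length,
        "w": idx.params.w,
        "p": idx.params.p,
        "mode": idx.params.mode,
        "explicit_triggers": sorted(idx.params.explicit_triggers),
        "hash_base": idx.params.hash_base,
        "hash_modulus": idx.params.hash_modulus,
        "alphabet": "".join(idx.alphabet.chars),
        "phrases": list(idx.dictionary.phrases),
        "arrays": [{"name": k, "length": len(v)} for k, v in arrays.items()],
    }
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(b"%s\n" % _FORMAT_MAGIC.encode())
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for arr in arrays.values():
            fh.write(arr.tobytes())


def load_index(path) -> PFPFMIndex:
    """Read an index file written by :func:`save_index`."""
    try:
        with open(path, "rb") as fh:
            magic = fh.readline().strip().decode(errors="replace")
            if magic != _FORMAT_MAGIC:
                raise IndexLoadError("not a phrasefm index file")
            hlen = int.from_bytes(fh.read(8), "little")
            raw = fh.read(hlen)
            if len(raw) != hlen:
                raise IndexLoadError("truncated index header")
            header = json.loads(raw)
            if header.get("version") != _FORMAT_VERSION:
                raise IndexLoadError(
                    f"unsupported index format version {header.get('version')!r}"
                )
            data = {}
            for spec in header["arrays"]:
                nbytes = spec["length"] * 8
                buf = fh.read(nbytes)
                if len(buf) != nbytes:
                    raise IndexLoadError(f"truncated array {spec['name']!r}")
                data[spec["name"]] = np.frombuffer(buf, dtype="<i8")
        bwt_text = data["bwt_text"]
        bwt_parse = data["bwt_parse"]
        mark_ones = data["mark_ones"]
        parse_ids = data["parse_ids"]
        occ_starts = data["occ_starts"]
        rotated = data["rotated_parse"]
    except IndexLoadError:
        raise
    except Exception as exc:
        raise IndexLoadError(f"cannot read index file: {exc}") from exc

    params = ParseParams(
        w=header["w"],
        p=header["p"],
        mode=header["mode"],
        explicit_triggers=frozenset(header["explicit_triggers"]),
        hash_base=header["hash_base"],
        hash_modulus=header["hash_modulus"],
    )
    alphabet = Alphabet(set(header["alphabet"]))
    dictionary = Dictionary(tuple(header["phrases"]))
    parse = Parse(tuple(int(x) for x in parse_ids), tuple(int(x) for x in occ_starts))
    return PFPFMIndex(
        fm_text=FMIndex(bwt_text, alphabet.size),
        fm_parse=FMIndex(bwt_parse, len(dictionary)),
        marks=MarkBitvector(int(header["n"]), mark_ones),
        phrase_map=PhraseMap(dictionary, params),
        dictionary=dictionary,
        parse=parse,
        rotated_parse=tuple(int(x) for x in rotated),
        params=params,
        alphabet=alphabet,
        text_length=int(header["n"]),
    )
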