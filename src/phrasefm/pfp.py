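"""Prefix-free parsing of a sentinel-terminated text.

A length-``w`` window is a *trigger string* when its Karp-Rabin fingerprint
is 0 modulo ``p`` (hash mode) or when it belongs to a user-supplied set
(explicit mode, convenient for reproducing small hand-worked examples).
Scanning the cyclically extended text ``S' = $ S[0..n-2] $ S[0..w-2]`` for
trigger occurrences cuts it into phrases that begin and end with a trigger
and contain no other trigger.  The sorted set of distinct phrases is the
dictionary D; rewriting the text as the sequence of phrase ranks gives the
parse P.  Because a trigger inside a phrase would have been a cut point,
no phrase can be a proper prefix of another: D is prefix-free.

The same scan applied to a query pattern (not cyclic, no sentinel window)
yields its *partial encoding*: a prefix alpha ending at the first trigger,
the IDs of the complete phrases in the middle, and a suffix beta starting
at the last trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .alphabet import SENTINEL, Alphabet

__all__ = [
    "ParseParams",
    "Dictionary",
    "Parse",
    "PartialEncoding",
    "NOT_IN_TEXT",
    "kr_fingerprint",
    "RollingHasher",
    "is_trigger",
    "build_pfp",
    "parse_pattern",
]

# Defaults for the polynomial rolling hash.  Recorded in every index so the
# pattern parser provably uses the same fingerprint as the text parser.
DEFAULT_HASH_BASE = 256
DEFAULT_HASH_MODULUS = (1 << 61) - 1  # Mersenne prime


@dataclass(frozen=True)
class ParseParams:
    """Parameters of the prefix-free parse.

    w
        Window (trigger-string) length in characters, >= 2.
    p
        Trigger modulus: a window triggers when its fingerprint is
        divisible by ``p``.  Larger ``p`` gives longer, rarer phrases.
    mode
        ``"hash"`` (the normal case) or ``"explicit"`` (trigger windows
        enumerated by name).
    explicit_triggers
        The trigger windows in explicit mode; each must have length ``w``.
    """

    w: int
    p: int = 1
    mode: str = "hash"
    explicit_triggers: frozenset[str] = field(default_factory=frozenset)
    hash_base: int = DEFAULT_HASH_BASE
    hash_modulus: int = DEFAULT_HASH_MODULUS

    def __post_init__(self) -> None:
        if self.w < 2:
            raise ValueError("window length w must be >= 2")
        if self.p < 1:
            raise ValueError("hash modulus p must be >= 1")
        if self.mode not in ("hash", "explicit"):
            raise ValueError(f"unknown parse mode {self.mode!r}")
        if self.mode == "explicit":
            for t in self.explicit_triggers:
                if len(t) != self.w:
                    raise ValueError(
                        f"explicit trigger {t!r} does not have length w={self.w}"
                    )
        if self.hash_base < 2 or self.hash_modulus < 2:
            raise ValueError("hash constants must be >= 2")


@dataclass(frozen=True)
class Dictionary:
    """Lexicographically sorted, prefix-free set of phrases; rank = phrase ID."""

    phrases: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.phrases)

    def __getitem__(self, i: int) -> str:
        return self.phrases[i]

    def id_of(self, phrase: str) -> int | None:
        # small |D| at desk scale; tests use this as the exact reference
        try:
            return self.phrases.index(phrase)
        except ValueError:
            return None

    # a Dictionary can stand in wherever a PhraseLookup is expected
    lookup = id_of


@dataclass(frozen=True)
class Parse:
    """The text as a sequence of phrase IDs.

    ``occ_starts[i]`` is the 0-based start of occurrence ``i`` in the
    extended text S'; consecutive occurrences overlap by ``w`` characters.
    """

    ids: tuple[int, ...]
    occ_starts: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class PartialEncoding:
    """(alpha, phrase IDs, beta) decomposition of a query pattern.

    Re-assembling ``alpha``, the expanded phrases and ``beta`` while
    collapsing the ``w``-character overlap at every junction reproduces
    the pattern.  ``ids`` is empty when the pattern contains fewer than
    two trigger occurrences; such patterns are searched purely at the
    character level.
    """

    alpha: str
    ids: tuple[int, ...]
    beta: str


class _NotInText:
    """Returned when a complete phrase of the pattern is absent from D."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_IN_TEXT"


NOT_IN_TEXT = _NotInText()


class PhraseLookup(Protocol):
    def lookup(self, phrase: str) -> int | None: ...


def kr_fingerprint(window: str, params: ParseParams) -> int:
    """Polynomial Karp-Rabin fingerprint of a length-``w`` window.

    f(s) = sum_i ord(s[i]) * base^(w-1-i)  mod  hash_modulus
    """
    if len(window) != params.w:
        raise ValueError(f"window must have length w={params.w}, got {len(window)}")
    h = 0
    for c in window:
        h = (h * params.hash_base + ord(c)) % params.hash_modulus
    return h


class RollingHasher:
    """O(1) sliding update of the Karp-Rabin fingerprint."""

    def __init__(self, params: ParseParams):
        self.params = params
        self._shift = pow(params.hash_base, params.w - 1, params.hash_modulus)

    def full(self, window: str) -> int:
        return kr_fingerprint(window, self.params)

    def roll(self, h: int, out_char: str, in_char: str) -> int:
        m = self.params.hash_modulus
        h = (h - ord(out_char) * self._shift) % m
        return (h * self.params.hash_base + ord(in_char)) % m


def is_trigger(
    window: str, params: ParseParams, sentinel_window: str | None = None
) -> bool:
    """Is this window a phrase boundary?

    ``sentinel_window`` is the designated window starting at the sentinel
    (a trigger regardless of mode); pattern parsing passes None.
    """
    if len(window) != params.w:
        raise ValueError(f"window must have length w={params.w}, got {len(window)}")
    if sentinel_window is not None and window == sentinel_window:
        return True
    if params.mode == "explicit":
        return window in params.explicit_triggers
    return kr_fingerprint(window, params) % params.p == 0


def _trigger_positions(s: str, params: ParseParams, sentinel_window: str | None) -> list[int]:
    """Start positions of every trigger-window occurrence in ``s``."""
    w = params.w
    if len(s) < w:
        return []
    out: list[int] = []
    if params.mode == "explicit":
        for i in range(len(s) - w + 1):
            win = s[i : i + w]
            if win in params.explicit_triggers or win == sentinel_window:
                out.append(i)
        return out
    hasher = RollingHasher(params)
    h = hasher.full(s[:w])
    for i in range(len(s) - w + 1):
        if i > 0:
            h = hasher.roll(h, s[i - 1], s[i + w - 1])
        if h % params.p == 0 or s[i : i + w] == sentinel_window:
            out.append(i)
    return out


def build_pfp(text: str, params: ParseParams) -> tuple[Dictionary, Parse]:
    """Prefix-free parse of a sentinel-terminated text.

    ``text`` must end with the sentinel and contain it nowhere else.  The
    scan runs over the extension ``S' = $ S[0..n-2] $ S[0..w-2]``; the
    window starting at each sentinel is a trigger by definition, so the
    parse always starts and ends there.  Phrase ranks are taken under the
    index symbol order (sentinel < separator < ordinary characters).
    """
    n = len(text)
    if n == 0:
        raise ValueError("cannot parse an empty text")
    if text[-1] != SENTINEL:
        raise ValueError("text must be terminated by the sentinel")
    if SENTINEL in text[:-1]:
        raise ValueError("sentinel occurs before the final position")
    w = params.w
    if n < w + 1:
        raise ValueError(f"text of length {n} is too short for window length w={w}")

    s_prime = SENTINEL + text[:-1] + SENTINEL + text[: w - 1]
    sentinel_window = s_prime[:w]
    starts = _trigger_positions(s_prime, params, sentinel_window)
    # positions 0 and n hold the sentinel window, so len(starts) >= 2
    occ_phrases = [
        s_prime[starts[i] : starts[i + 1] + w] for i in range(len(starts) - 1)
    ]

    alphabet = Alphabet(set(text))
    ordered = sorted(set(occ_phrases), key=alphabet.sort_key)
    rank = {ph: i for i, ph in enumerate(ordered)}
    ids = tuple(rank[ph] for ph in occ_phrases)
    return Dictionary(tuple(ordered)), Parse(ids, tuple(starts[:-1]))


def expand_parse(dictionary: Dictionary, ids: Sequence[int], w: int) -> str:
    """Concatenate phrases collapsing the ``w``-character junction overlaps."""
    if not len(ids):
        return ""
    parts = [dictionary[ids[0]]]
    parts.extend(dictionary[i][w:] for i in ids[1:])
    return "".join(parts)


def parse_pattern(
    pattern: str, params: ParseParams, phrase_lookup: PhraseLookup
) -> PartialEncoding | _NotInText:
    """Partial encoding of a query pattern.

    The pattern is scanned with the same trigger function used for the
    text, but with no sentinel window and no cyclic wrap.  Patterns with
    fewer than two trigger occurrences carry no complete phrase and are
    returned with empty ``ids`` (alpha/beta only); if any complete phrase
    is missing from the dictionary the pattern cannot occur in the text
    and ``NOT_IN_TEXT`` is returned.
    """
    if SENTINEL in pattern:
        raise ValueError("patterns must not contain the sentinel character")
    w = params.w
    if len(pattern) < w:
        return PartialEncoding(pattern, (), "")
    starts = _trigger_positions(pattern, params, sentinel_window=None)
    if not starts:
        return PartialEncoding(pattern, (), "")

    first, last = starts[0], starts[-1]
    alpha = pattern[: first + w] if first > 0 else ""
    # a suffix ending with a trigger is a complete phrase, not a beta
    beta = pattern[last:] if last < len(pattern) - w else ""
    ids: list[int] = []
    for a, b in zip(starts, starts[1:]):
        phrase = pattern[a : b + w]
        pid = phrase_lookup.lookup(phrase)
        if pid is None:
            return NOT_IN_TEXT
        ids.append(pid)
    if not alpha and not ids and not beta:
        # the pattern is exactly one trigger string
        return PartialEncoding("", (), pattern)
    return PartialEncoding(alpha, tuple(ids), beta)
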