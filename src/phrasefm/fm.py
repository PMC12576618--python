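"""Suffix array, Burrows-Wheeler transform and backward search.

Everything here works over a dense integer alphabet ``0..sigma-1`` so the
same machinery indexes both the character-level text (alphabet of a few
DNA symbols) and the phrase-level parse (alphabet of phrase IDs, which can
be large).  The terminal symbol must be the unique smallest symbol and sit
at the final position, which makes suffix order coincide with cyclic
rotation order.

Intervals over the BWT matrix are 0-based and inclusive; an interval is
empty when ``lo > hi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IntText",
    "Interval",
    "FMIndex",
    "build_suffix_array",
    "bwt_from_sa",
]

# alphabets up to this size use a dense (n+1) x sigma occurrence table;
# larger ones (phrase IDs) use per-symbol sorted position lists
_DENSE_ALPHABET_MAX = 64


@dataclass(frozen=True)
class Interval:
    """Inclusive row range [lo..hi] of a BWT matrix; empty iff lo > hi."""

    lo: int
    hi: int

    @property
    def is_empty(self) -> bool:
        return self.lo > self.hi

    @property
    def size(self) -> int:
        return 0 if self.is_empty else self.hi - self.lo + 1


EMPTY_INTERVAL = Interval(0, -1)


@dataclass(frozen=True)
class IntText:
    """Integer-coded text whose unique smallest symbol terminates it."""

    symbols: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("text must be a non-empty 1-d symbol sequence")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return len(self.symbols)

    def validate_terminal(self) -> None:
        s = self.symbols
        smallest = int(s.min())
        if int(s[-1]) != smallest or int(np.count_nonzero(s == smallest)) != 1:
            raise ValueError(
                "the smallest symbol must occur exactly once, at the final position"
            )


def build_suffix_array(text: IntText) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log n) with numpy sorts).

    Because the terminal is unique and smallest, the returned order is
    also the lexicographic order of the cyclic rotations.
    """
    text.validate_terminal()
    s = text.symbols.astype(np.int64)
    n = len(s)
    rank = s
    order = np.argsort(rank, kind="stable")
    k = 1
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        ranks_sorted = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = ranks_sorted
        if ranks_sorted[-1] == n - 1:
            break
        k *= 2
    return order


class FMIndex:
    """BWT + cumulative counts + rank support; answers backward search.

    ``C[c]`` counts the suffixes starting with a symbol smaller than
    ``c``; ``rank(c, i)`` counts occurrences of ``c`` in ``bwt[0..i-1]``.
    """

    def __init__(self, bwt: np.ndarray, alphabet_size: int):
        bwt = np.ascontiguousarray(bwt, dtype=np.int64)
        if bwt.size and (bwt.min() < 0 or bwt.max() >= alphabet_size):
            raise ValueError("BWT symbol outside the declared alphabet")
        self.bwt = bwt
        self.alphabet_size = int(alphabet_size)
        self.n = len(bwt)
        counts = np.bincount(bwt, minlength=self.alphabet_size)
        self.C = np.zeros(self.alphabet_size + 1, dtype=np.int64)
        np.cumsum(counts, out=self.C[1:])
        if self.alphabet_size <= _DENSE_ALPHABET_MAX:
            occ = np.zeros((self.n + 1, self.alphabet_size), dtype=np.int32)
            for c in range(self.alphabet_size):
                occ[1:, c] = np.cumsum(bwt == c)
            self._occ: np.ndarray | None = occ
            self._pos_order = None
        else:
            # sorted positions of each symbol, sliced out of one argsort
            self._occ = None
            self._pos_order = np.argsort(bwt, kind="stable")

    @property
    def full_interval(self) -> Interval:
        return Interval(0, self.n - 1)

    def rank(self, symbol: int, i: int) -> int:
        """Occurrences of ``symbol`` in ``bwt[0..i-1]``; unknown symbols -> 0."""
        if not 0 <= i <= self.n:
            raise IndexError(f"rank position {i} outside [0, {self.n}]")
        if symbol < 0 or symbol >= self.alphabet_size:
            return 0
        if self._occ is not None:
            return int(self._occ[i, symbol])
        lo, hi = int(self.C[symbol]), int(self.C[symbol + 1])
        positions = self._pos_order[lo:hi]
        return int(np.searchsorted(positions, i, side="left"))

    def lf(self, i: int) -> int:
        c = int(self.bwt[i])
        return int(self.C[c]) + self.rank(c, i)

    def backward_step(self, iv: Interval, symbol: int) -> Interval:
        """One LF-refinement: rows prefixed by ``symbol`` + previous prefix."""
        if iv.is_empty:
            return EMPTY_INTERVAL
        if symbol < 0 or symbol >= self.alphabet_size:
            return EMPTY_INTERVAL
        c = int(self.C[symbol])
        lo = c + self.rank(symbol, iv.lo)
        hi = c + self.rank(symbol, iv.hi + 1) - 1
        return Interval(lo, hi) if lo <= hi else EMPTY_INTERVAL

    def backward_search(
        self, pattern: Sequence[int], start: Interval | None = None
    ) -> Interval:
        """Interval of rows prefixed by ``pattern`` (restricted to ``start``)."""
        iv = self.full_interval if start is None else start
        for symbol in reversed(list(pattern)):
            iv = self.backward_step(iv, int(symbol))
            if iv.is_empty:
                return EMPTY_INTERVAL
        return iv

    def reconstruct(self) -> np.ndarray:
        """Invert the BWT; the terminal row is row 0 of the matrix."""
        out = np.empty(self.n, dtype=np.int64)
        out[-1] = int(self.bwt.min())  # the terminal symbol
        s = 0
        for i in range(self.n - 2, -1, -1):
            out[i] = self.bwt[s]
            s = self.lf(s)
        return out


def bwt_from_sa(text: IntText, sa: np.ndarray) -> FMIndex:
    """FM-index from a text and its suffix array: bwt[i] = S[(sa[i]-1) mod n]."""
    s = text.symbols
    n = len(s)
    if len(sa) != n:
        raise ValueError("suffix array length does not match the text")
    bwt = s[(np.asarray(sa) - 1) % n]
    return FMIndex(bwt, text.alphabet_size)
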