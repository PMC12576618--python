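"""Symbol ordering shared by the parser and both FM-indexes.

The index works over an integer alphabet in which the terminal sentinel is
the unique smallest symbol, the record separator (used when several FASTA
records are concatenated) sits between the sentinel and the ordinary
alphabet, and every other character keeps its natural order.  All phrase
sorting and suffix sorting goes through this encoding, so ``$ < # < A < C
< G < T`` regardless of ASCII.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

SENTINEL = "$"
SEPARATOR = "#"


class Alphabet:
    """Dense integer codes for the characters of an indexed text.

    Code 0 is the sentinel, code 1 the separator (only if present in the
    text), ordinary characters follow in sorted order.
    """

    def __init__(self, chars: Iterable[str]):
        seen = set(chars)
        ordinary = sorted(c for c in seen if c not in (SENTINEL, SEPARATOR))
        self.chars: list[str] = [SENTINEL]
        if SEPARATOR in seen:
            self.chars.append(SEPARATOR)
        self.chars.extend(ordinary)
        self.code: dict[str, int] = {c: i for i, c in enumerate(self.chars)}
        # byte-level lookup table; -1 marks characters outside the alphabet
        self._lut = np.full(256, -1, dtype=np.int32)
        for c, i in self.code.items():
            self._lut[ord(c)] = i

    @property
    def size(self) -> int:
        return len(self.chars)

    def encode(self, s: str) -> np.ndarray:
        """Map a string to its integer codes; raises on unknown characters."""
        raw = np.frombuffer(s.encode("latin-1"), dtype=np.uint8)
        out = self._lut[raw]
        if out.size and out.min() < 0:
            bad = s[int(np.argmin(out >= 0))]
            raise ValueError(f"character {bad!r} is not in the indexed alphabet")
        return out

    def try_encode(self, s: str) -> np.ndarray | None:
        """Like :meth:`encode` but returns None for out-of-alphabet input."""
        raw = np.frombuffer(s.encode("latin-1"), dtype=np.uint8)
        out = self._lut[raw]
        if out.size and out.min() < 0:
            return None
        return out

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.chars[int(c)] for c in codes)

    def sort_key(self, s: str) -> bytes:
        """Translation of ``s`` whose byte order equals the symbol order."""
        return self.encode(s).astype(np.uint8).tobytes()
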