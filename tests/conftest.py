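"""Shared fixtures and brute-force reference helpers.

The reference helpers are deliberately naive (quadratic sorts, direct
scans) so they are independent of the code paths they check.
"""

from __future__ import annotations

import pytest

from phrasefm import ParseParams, build_index

# A 41-character hand-checkable example: with w=2 and triggers AA, CG, TA
# (plus the sentinel-anchored window $T) it parses into six phrases, and
# the query below spans four complete phrases with non-trivial alpha/beta.
EXAMPLE_TEXT = "TCCAGAAGAGTATCTCCTCGACATGTTGAAGACATATGAT$"
EXAMPLE_TRIGGERS = frozenset({"AA", "CG", "TA"})
EXAMPLE_QUERY = "CAGAAGAGTATCTCCTCGACATGTTGAAGACATAT"

# A second hand-checkable example containing '#' record separators; with
# w=2 and triggers AC, TC its parse is (0, 2, 3, 4, 5, 2, 1).
SEPARATED_TEXT = "AGACGACT#AGATACT#AGATTCGAGACGAC"
SEPARATED_TRIGGERS = frozenset({"AC", "TC"})


@pytest.fixture(scope="session")
def example_params() -> ParseParams:
    return ParseParams(w=2, mode="explicit", explicit_triggers=EXAMPLE_TRIGGERS)


@pytest.fixture(scope="session")
def example_index(example_params):
    return build_index(EXAMPLE_TEXT, example_params)


def rotation(text: str, i: int) -> str:
    """The i-th cyclic rotation of ``text``."""
    return (text + text)[i : i + len(text)]


def naive_suffix_array(symbols) -> list[int]:
    """Quadratic comparison sort of all suffixes (integer sequences)."""
    seq = list(symbols)
    return sorted(range(len(seq)), key=lambda i: seq[i:])


def naive_occurrences(text: str, pattern: str) -> int:
    """Overlapping occurrence count by checking every start position."""
    if not pattern:
        return len(text)
    return sum(
        1
        for i in range(len(text) - len(pattern) + 1)
        if text[i : i + len(pattern)] == pattern
    )


def cyclic_expansion(dictionary, rotated_parse, start: int, w: int) -> str:
    """Expand a rotation of the parse into the corresponding rotation of S.

    Going around the full cycle, each phrase contributes everything but
    its trailing w characters (those are the head of the next phrase).
    """
    m = len(rotated_parse)
    out = []
    for j in range(m):
        phrase = dictionary[rotated_parse[(start + j) % m]]
        out.append(phrase[:-w])
    return "".join(out)
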