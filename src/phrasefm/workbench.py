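"""Corpus I/O, synthetic data and the naive counting oracle.

The generator produces pangenome-style collections: one random base
sequence plus point-mutated copies, concatenated with ``#`` separators and
terminated by the sentinel.  Sampled query patterns never cross a record
boundary, so they are guaranteed substrings of some record.  The naive
scan counter is the ground truth every index query is tested against.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import SENTINEL, SEPARATOR

DNA = "ACGT"

__all__ = [
    "Corpus",
    "QuerySet",
    "read_fasta",
    "read_text",
    "generate_pangenome",
    "generate_random_text",
    "sample_patterns",
    "mutate_pattern",
    "naive_count",
]


@dataclass
class Corpus:
    """A sentinel-terminated text plus its record structure."""

    name: str
    text: str  # records joined by separators, sentinel at the end
    record_spans: list[tuple[int, int]]  # [start, end) of each record in text
    record_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.text.endswith(SENTINEL):
            raise ValueError("corpus text must end with the sentinel")
        if SENTINEL in self.text[:-1]:
            raise ValueError("sentinel occurs inside the corpus")
        for lo, hi in self.record_spans:
            if SEPARATOR in self.text[lo:hi]:
                raise ValueError("separator occurs inside a record")

    @property
    def alphabet_summary(self) -> dict[str, int]:
        chars, counts = np.unique(list(self.text), return_counts=True)
        return dict(zip(chars.tolist(), counts.tolist()))

    def records(self) -> list[str]:
        return [self.text[lo:hi] for lo, hi in self.record_spans]


@dataclass
class QuerySet:
    """Sampled query patterns with their provenance."""

    patterns: list[str]
    provenance: list[tuple[int, int]]  # (start in corpus text, length)
    seed: int | None = None


def _assemble(name: str, records: list[str], names: list[str]) -> Corpus:
    for r in records:
        if not r:
            raise ValueError("empty record in corpus")
        if SENTINEL in r or SEPARATOR in r:
            raise ValueError("record contains a reserved symbol")
    spans: list[tuple[int, int]] = []
    parts: list[str] = []
    pos = 0
    for i, rec in enumerate(records):
        if i > 0:
            parts.append(SEPARATOR)
            pos += 1
        spans.append((pos, pos + len(rec)))
        parts.append(rec)
        pos += len(rec)
    parts.append(SENTINEL)
    return Corpus(name, "".join(parts), spans, names)


def read_fasta(path) -> Corpus:
    """Load a FASTA file; records are uppercased and joined by separators."""
    path = Path(path)
    records, names = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(str(rec.seq).upper())
        names.append(rec.id)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return _assemble(path.name, records, names)


def read_text(path) -> Corpus:
    """Load a plain-text file as a single record (whitespace stripped)."""
    path = Path(path)
    text = "".join(path.read_text().split()).upper()
    if not text:
        raise ValueError(f"empty text file {path}")
    if text.endswith(SENTINEL):
        text = text[:-1]
    return _assemble(path.name, [text], [path.stem])


def read_corpus(path) -> Corpus:
    """Dispatch on content: FASTA if the file starts with '>', else plain text."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fasta(path) if first == ">" else read_text(path)


def generate_random_text(length: int, seed: int, alphabet: str = DNA) -> Corpus:
    """Uniform random single-record corpus."""
    rng = np.random.default_rng(seed)
    rec = "".join(rng.choice(list(alphabet), size=length))
    return _assemble(f"random-{length}", [rec], ["random"])


def generate_pangenome(
    base_length: int, n_copies: int, mutation_rate: float, seed: int
) -> Corpus:
    """Repetitive collection: a random base plus point-mutated copies.

    Each site of a copy is, with probability ``mutation_rate``, replaced
    by a uniform random base (possibly the same one, so at rate 1 the
    expected per-site difference is 3/4).
    """
    if base_length < 1:
        raise ValueError("base_length must be >= 1")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(DNA))
    base = rng.integers(0, len(letters), size=base_length)
    records = ["".join(letters[base])]
    for _ in range(n_copies - 1):
        copy = base.copy()
        hit = rng.random(base_length) < mutation_rate
        copy[hit] = rng.integers(0, len(letters), size=int(hit.sum()))
        records.append("".join(letters[copy]))
    names = [f"copy{i}" for i in range(len(records))]
    return _assemble(f"pangenome-{base_length}x{n_copies}", records, names)


def sample_patterns(corpus: Corpus, n: int, length: int, seed: int) -> QuerySet:
    """Sample ``n`` substrings of ``length`` from within records."""
    rng = np.random.default_rng(seed)
    windows = [
        (lo, hi) for lo, hi in corpus.record_spans if hi - lo >= length
    ]
    if not windows or length < 1:
        raise ValueError(f"no record can host a pattern of length {length}")
    patterns, prov = [], []
    for _ in range(n):
        lo, hi = windows[int(rng.integers(0, len(windows)))]
        start = int(rng.integers(lo, hi - length + 1))
        patterns.append(corpus.text[start : start + length])
        prov.append((start, length))
    return QuerySet(patterns, prov, seed)


def mutate_pattern(pattern: str, n_edits: int, seed: int) -> str:
    """Substitute ``n_edits`` positions; used to produce likely-absent queries."""
    rng = np.random.default_rng(seed)
    chars = list(pattern)
    for pos in rng.choice(len(chars), size=min(n_edits, len(chars)), replace=False):
        old = chars[pos]
        choices = [c for c in DNA if c != old] or list(DNA)
        chars[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def naive_count(text: str, pattern: str) -> int:
    """Overlapping occurrence count by direct scan (the test oracle)."""
    if pattern == "":
        return len(text)
    n = 0
    start = text.find(pattern)
    while start != -1:
        n += 1
        start = text.find(pattern, start + 1)
    return n


def write_patterns(patterns: list[str], path) -> None:
    Path(path).write_text("\n".join(patterns) + "\n")


def read_patterns(path) -> list[str]:
    """Patterns one-per-line, or FASTA if the file starts with '>'."""
    path = Path(path)
    head = path.read_text()
    if head.startswith(">"):
        return [str(r.seq).upper() for r in SeqIO.parse(io.StringIO(head), "fasta")]
    return [line.strip().upper() for line in head.splitlines() if line.strip()]
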