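# phrasefm

Exact `count` queries on DNA texts with a **two-level FM-index over a
prefix-free parse**.

A standard FM-index answers `count(Q)` — the number of (possibly
overlapping) occurrences of a pattern Q in an indexed text S — by
backward search, paying at least one rank query per character of Q.
`phrasefm` parses S into phrases delimited by *trigger strings*
(length-`w` windows whose Karp–Rabin fingerprint is 0 mod `p`), builds
an FM-index of the text **and** an FM-index of the parse, and links them
with a bitvector B marking the BWT rows of S that start at phrase
boundaries. A query is then searched character by character only at its
two ends and **one whole phrase per step** across its middle, with
`rank`/`select` on B hopping between the levels. Counts are exact and
identical to plain backward search; only the number of rank queries
changes. The parameters `w` and `p` tune the average phrase length, so
the approach pays off for patterns long enough to span several phrases
(hundreds of characters) on repetitive collections such as pangenomes.

## Worked example

The package ships a 41-character text that is small enough to check by
hand. With `w=2` and explicit triggers `AA`, `CG`, `TA`:

```python
from phrasefm import ParseParams, build_index, count_trace

text = "TCCAGAAGAGTATCTCCTCGACATGTTGAAGACATATGAT$"
params = ParseParams(w=2, mode="explicit",
                     explicit_triggers=frozenset({"AA", "CG", "TA"}))
idx = build_index(text, params)
print(idx.dictionary.phrases)
print(idx.parse.ids)
t = count_trace(idx, "CAGAAGAGTATCTCCTCGACATGTTGAAGACATAT")
print(t.encoding, t.count)
```

prints

```
('$TCCAGAA', 'AAGACATA', 'AAGAGTA', 'CGACATGTTGAA', 'TATCTCCTCG', 'TATGAT$T')
(0, 2, 4, 3, 1, 5)
PartialEncoding(alpha='CAGAA', ids=(2, 4, 3, 1), beta='TAT') 1
```

The dictionary holds the six phrases of the parse in lexicographic
order (`$` sorts lowest), the parse lists their ranks along the text,
and the query decomposes into a prefix `CAGAA` ending at its first
trigger, four complete phrases, and a suffix `TAT` starting at its last
trigger. The count query backward-searches `TAT` in the text index
(rows [31..32]), maps down to the parse index (rows [4..5]), consumes
the phrase IDs 2 4 3 1 right-to-left (row [2]), maps back up (row [2])
and finishes with `CAG` — `CAGAA` minus the trigger already matched —
landing on row [14]: one occurrence. `phrasefm selftest` runs exactly
this chain and verifies every interval.

The same machinery at realistic scale:

```python
from phrasefm import ParseParams, build_index, count
from phrasefm.workbench import generate_pangenome, sample_patterns

corpus = generate_pangenome(50_000, 20, 0.005, seed=301)  # ~1 Mb, 20 genomes
idx = build_index(corpus.text, ParseParams(w=6, p=50))
q = sample_patterns(corpus, 1, 125, seed=1).patterns[0]
print(count(idx, q))   # 13 — the 125 bp window survives unmutated in 13 of 20 copies
```

## Command line

```
phrasefm build --input genomes.fa --w 6 --p 50 --output genomes.pfm
phrasefm count --index genomes.pfm --patterns queries.txt --output counts.tsv
phrasefm selftest
```

FASTA records are uppercased and concatenated with `#` separators (never
matched by sampled patterns); plain-text input is indexed as a single
record. `count` emits one `pattern<TAB>count` row per query. Defaults
`w=6, p=50` suit repetitive megabase-scale collections; see
`docs/methods.md` for how to choose them.

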