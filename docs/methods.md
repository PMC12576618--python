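# Methods

## The problem

A count query on an FM-index backward-searches a pattern Q one character
at a time, performing at least one rank query (and in practice one cache
miss) per character. Word-based indexes amortize this by consuming whole
words per step, but DNA has no word boundaries. `phrasefm` imposes
boundaries with *prefix-free parsing* and runs backward search at two
levels: character by character only at the two ends of the pattern, and
phrase by phrase across its middle. The answer is always the exact number
of (possibly overlapping) occurrences — the two-level route changes the
work per query, never the result, and the test suite pins this
equivalence against a naive scan oracle on every configuration it runs.

## Prefix-free parsing

Fix a window length `w >= 2` and a modulus `p >= 1`. A length-`w` window
is a **trigger string** when its Karp–Rabin fingerprint is divisible by
`p`; the window starting at the terminal sentinel `$` is a trigger by
definition. The text `S[0..n-1]` (sentinel-terminated, `$` unique and
smallest) is extended cyclically to `S' = $ S[0..n-2] $ S[0..w-2]` and
scanned; consecutive trigger occurrences delimit **phrases** that start
and end with a trigger and contain none inside. The sorted set of
distinct phrases is the **dictionary D**; the text rewritten as the
sequence of phrase ranks is the **parse P**. Consecutive phrases overlap
by exactly `w` characters, and a trigger inside a phrase would have been
a cut point, so no phrase is a proper prefix of another: D is
prefix-free. This prefix-freeness is what lets phrase IDs inherit the
lexicographic order of their phrases, which the whole construction rests
on.

Expected phrase length is governed by `p` (roughly one trigger every `p`
windows for a well-mixed hash), so `w` and `p` tune the trade-off
between the dictionary size and how many characters each phrase-level
step consumes.

### Trigger selection modes

- **hash** (default): polynomial rolling hash
  `f(s) = sum_i ord(s_i) * b^(w-1-i) mod M` with base `b = 256` and
  modulus `M = 2^61 - 1`. The constants are stored in the index header,
  because pattern parsing at query time must use the identical function.
- **explicit**: the trigger set is enumerated by name. This exists so
  that small hand-worked examples (where triggers are chosen for
  legibility, not by hash) are reproducible bit for bit; it is also how
  the self-test and the acceptance script drive the index.

Every window position that matches is a boundary, so overlapping trigger
occurrences (e.g. `AA` inside `AAA`) produce short phrases of length
`w+1`; this is legal and covered by tests (`p = 1` makes *every* window a
trigger).

## The two-level index

For a text S with parse P the index holds:

- `fm_text`: FM-index of S (suffix array built by prefix doubling, then
  BWT, cumulative counts `C`, rank support).
- `fm_parse`: FM-index of P rotated so that the sentinel-anchored phrase
  (ID 0, unique because `$` is unique) is the final symbol and can act
  as the terminal of the phrase-level text.
- `marks` (B): a length-`n` bitvector marking the rows of the BWT matrix
  of S whose rotations start at a phrase boundary. It has exactly `|P|`
  ones, and its ones are bunched into at most as many runs as there are
  distinct trigger strings in S. Because phrase IDs sort like their
  phrases and D is prefix-free, the i-th marked row of S corresponds to
  the i-th row of the BWT matrix of P; `rank1`/`select1` on B therefore
  convert intervals between levels in both directions.
- `phrase_map` (M): Karp–Rabin fingerprints of the dictionary phrases,
  each bucket storing the phrase characters. Lookups verify character by
  character, so a string outside D maps to NULL with certainty, not just
  with high probability — count is deterministic and exact, at the cost
  of storing D (trivial at the scales this package targets).

## Counting

A pattern Q is scanned with the same trigger function (no sentinel
window, no wrap) and decomposed into its **partial encoding**: the
shortest prefix `alpha` ending at the first trigger, the IDs of the
complete phrases between consecutive triggers, and the shortest suffix
`beta` from the last trigger onward. If Q starts (ends) at a trigger,
`alpha` (`beta`) is empty; a suffix ending with a trigger is a complete
phrase, not a `beta`. If any complete phrase is absent from D, Q cannot
occur: count 0.

The query then proceeds:

1. fewer than two triggers in Q (no complete phrase): plain
   character-level backward search of all of Q;
2. otherwise, backward-search `beta` in `fm_text` (empty -> 0). Every
   matching row starts with a trigger occurrence, hence is marked; map
   the interval to the parse level with `rank1`. If `beta` is empty,
   start from the full parse range instead;
3. backward-search the phrase IDs right-to-left in `fm_parse`
   (empty -> 0);
4. map back to the text level with `select1`;
5. if `alpha` is non-empty, drop its trailing `w` characters (the
   trigger already matched as the head of the first complete phrase) and
   finish the character-level search with the remainder;
6. the answer is the size of the final interval.

Conventions: intervals are 0-based inclusive `[lo..hi]`, empty iff
`lo > hi`; the empty pattern returns `n` (it prefixes every rotation);
occurrences are counted in the linear text — since the sentinel is
unique and excluded from patterns, no match can cross the cyclic wrap,
so this agrees with the rotation view. Patterns are uppercased like the
text; characters outside the indexed alphabet yield count 0.

## Numerical and data-structure choices

- **Suffix arrays** are built by prefix doubling over numpy sorts
  (O(n log n)); correctness is contracted against a quadratic
  comparison-sort oracle in the tests. At the megabase scales this
  package targets, construction takes a few seconds.
- **Rank support**: the character-level BWT (alphabet of a few symbols)
  uses a dense `(n+1) x sigma` cumulative-occurrence table; the
  phrase-level BWT (alphabet `|D|`, potentially thousands) uses
  per-symbol sorted position lists with binary search. The crossover is
  at alphabet size 64.
- **The mark bitvector** stores the sorted positions of its ones;
  `rank1` is a binary search, `select1` an array access. No attempt is
  made at O(log log n) machinery — the functional contract is what the
  package guarantees.
- **Symbol order**: sentinel < separator (`#`) < ordinary characters.
  Multi-record FASTA input is concatenated with one `#` per junction;
  separators are ordinary alphabet symbols to the index but are excluded
  from generated patterns. Input is uppercased; characters outside
  {A,C,G,T} (e.g. N) are retained as ordinary symbols.
- **Serialization** is a single self-describing file: a JSON header
  (format version, w, p, mode, triggers, hash constants, alphabet,
  dictionary, array manifest) followed by raw little-endian arrays. The
  layout has no timestamps, so rebuilding the same input with the same
  parameters yields byte-identical files. The suffix array is not
  stored; count queries never need it.

## Synthetic data

`generate_pangenome` emulates a repetitive collection (many genomes of
one species): a uniform random DNA base sequence plus point-mutated
copies, each site of a copy replaced with probability `mutation_rate` by
a uniform random base (so at rate 1 the expected per-site divergence is
3/4). Records are joined with `#` and terminated by `$`; query patterns
are sampled from within records so they are guaranteed present, and
`mutate_pattern` derives likely-absent variants. This captures the
repetitiveness that makes phrase-level search profitable, but not real
genome features — indels, rearrangements, N runs, skewed base
composition — so passing tests demonstrate exactness of counting, not
biological realism of the corpus model.

Test and acceptance problem sizes are desk-scale by design: randomized
equivalence sweeps use corpora of 1k–200k characters (228
configurations across w in {2..10}, p in {1..101}, pattern lengths
5–1000), structural invariants are verified by brute-force expansion on
texts up to ~5k, and a ~1 Mb pangenome smoke run checks that the
two-level and single-level routes agree. Wall-clock speedups versus
other indexes are hardware-dependent and are deliberately not measured.

## Limitations

- count only: locate queries and suffix-array sampling are out of scope.
- The dictionary is stored verbatim (exactness over the probabilistic
  hash-only membership variant); memory is proportional to |D| phrases.
- Plain (not run-length-compressed) structures throughout; inputs are
  parsed in memory, not streamed.
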