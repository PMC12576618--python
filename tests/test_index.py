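"""Two-level index: marking bitvector, level maps, count, serialization."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import (
    EXAMPLE_QUERY,
    EXAMPLE_TEXT,
    cyclic_expansion,
    naive_occurrences,
    naive_suffix_array,
    rotation,
)
from phrasefm import (
    IndexLoadError,
    Interval,
    ParseParams,
    build_index,
    count,
    count_single_level,
    count_trace,
    load_index,
    map_to_parse,
    map_to_text,
    save_index,
    trigger_aligned,
)
from phrasefm.index import MarkBitvector


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def small_indexes():
    """A spread of (text, params, index) triples used by several tests."""
    rng = np.random.default_rng(2024)
    out = []
    example_params = ParseParams(
        w=2, mode="explicit", explicit_triggers=frozenset({"AA", "CG", "TA"})
    )
    out.append((EXAMPLE_TEXT, example_params, build_index(EXAMPLE_TEXT, example_params)))
    for n, w, p in [(200, 2, 1), (400, 2, 5), (800, 4, 11), (1500, 6, 31), (999, 3, 2)]:
        text = random_dna(rng, n) + "$"
        params = ParseParams(w=w, p=p)
        out.append((text, params, build_index(text, params)))
    return out


INDEXES = small_indexes()


class TestMarkBitvector:
    def test_rank_select_inverse_on_ones(self):
        bv = MarkBitvector(10, np.array([0, 3, 4, 9]))
        for i in bv.ones:
            assert bv.select1(bv.rank1(int(i)) + 1) == i
        assert bv.rank1(0) == 0 and bv.rank1(10) == 4
        assert bv.num_runs == 3

    def test_bounds_errors(self):
        bv = MarkBitvector(5, np.array([2]))
        with pytest.raises(IndexError):
            bv.select1(2)
        with pytest.raises(IndexError):
            bv.rank1(6)


class TestBuildIndex:
    def test_worked_example_shapes(self, example_index):
        assert len(example_index.dictionary) == 6
        assert len(example_index.parse) == 6
        assert example_index.marks.num_ones == 6
        # marked rows of the text BWT matrix, frozen from a brute-force
        # scan of all 41 rotations
        assert example_index.marks.ones.tolist() == [0, 1, 2, 19, 31, 32]

    @pytest.mark.parametrize("text,params,idx", INDEXES)
    def test_ones_count_equals_parse_length(self, text, params, idx):
        assert idx.marks.num_ones == len(idx.parse)

    @pytest.mark.parametrize("text,params,idx", INDEXES)
    def test_run_bound(self, text, params, idx):
        """Runs of 1s in B never exceed the distinct triggers in the text."""
        sp = "$" + text[:-1] + "$" + text[: params.w - 1]
        # every phrase start is a trigger occurrence; the sentinel-anchored
        # window is occ_starts[0], so this is the full distinct-trigger set
        distinct = {sp[s : s + params.w] for s in idx.parse.occ_starts}
        assert idx.marks.num_runs <= len(distinct)

    @pytest.mark.parametrize("text,params,idx", INDEXES)
    def test_row_correspondence_by_expansion(self, text, params, idx):
        """Row i of the parse BWT matrix expands to the rotation of the
        text at the row of the i-th mark (the two-level correspondence)."""
        sa = naive_suffix_array(idx.alphabet.encode(text).tolist())
        m = len(idx.rotated_parse)
        rot = list(idx.rotated_parse)
        order = sorted(range(m), key=lambda t: rot[t:] + rot[:t])
        for i, t in enumerate(order):
            expanded = cyclic_expansion(idx.dictionary, rot, t, params.w)
            row = idx.marks.select1(i + 1)
            assert expanded == rotation(text, sa[row])


class TestLevelMaps:
    def test_worked_example_chain(self, example_index):
        iv = Interval(31, 32)
        assert trigger_aligned(example_index, iv)
        piv = map_to_parse(example_index, iv)
        assert (piv.lo, piv.hi) == (4, 5)
        assert map_to_text(example_index, Interval(2, 2)) == Interval(2, 2)

    def test_full_text_range_is_not_aligned(self, example_index):
        n = example_index.n
        assert not trigger_aligned(example_index, Interval(0, n - 1))

    def test_unaligned_interval_rejected(self, example_index):
        with pytest.raises(ValueError):
            map_to_parse(example_index, Interval(0, example_index.n - 1))

    def test_out_of_range_parse_interval(self, example_index):
        with pytest.raises(IndexError):
            map_to_text(example_index, Interval(0, 99))

    @pytest.mark.parametrize("text,params,idx", INDEXES[:3])
    def test_round_trip_on_marked_runs(self, text, params, idx):
        ones = idx.marks.ones
        # map every maximal run of marked rows down and back up
        splits = np.flatnonzero(np.diff(ones) > 1)
        run_starts = np.concatenate([[0], splits + 1])
        run_ends = np.concatenate([splits, [len(ones) - 1]])
        for a, b in zip(run_starts, run_ends):
            iv = Interval(int(ones[a]), int(ones[b]))
            assert map_to_text(idx, map_to_parse(idx, iv)) == iv

    @pytest.mark.parametrize("text,params,idx", INDEXES[:3])
    def test_alignment_agrees_with_bit_scan(self, text, params, idx):
        bits = idx.marks.to_bits()
        rng = np.random.default_rng(5)
        for _ in range(50):
            lo = int(rng.integers(0, idx.n))
            hi = int(rng.integers(lo, min(idx.n, lo + 8)))
            assert trigger_aligned(idx, Interval(lo, hi)) == bool(
                bits[lo : hi + 1].all()
            )


class TestCount:
    def test_worked_example_interval_chain(self, example_index):
        t = count_trace(example_index, EXAMPLE_QUERY)
        assert (t.beta_interval.lo, t.beta_interval.hi) == (31, 32)
        assert (t.parse_start.lo, t.parse_start.hi) == (4, 5)
        assert (t.parse_final.lo, t.parse_final.hi) == (2, 2)
        assert (t.mapped_back.lo, t.mapped_back.hi) == (2, 2)
        assert (t.final.lo, t.final.hi) == (14, 14)
        assert t.count == 1 == naive_occurrences(EXAMPLE_TEXT, EXAMPLE_QUERY)

    def test_empty_pattern_counts_every_rotation(self, example_index):
        assert count(example_index, "") == example_index.n

    def test_absent_pattern(self, example_index):
        assert count(example_index, "GAATTTTTTAAG") == 0
        assert count(example_index, "NNN") == 0  # outside the alphabet

    @pytest.mark.parametrize("text,params,idx", INDEXES)
    def test_equals_oracle_and_single_level(self, text, params, idx):
        """Exactness on sampled, mutated, short and trigger-free patterns."""
        rng = np.random.default_rng(77)
        body = text[:-1]
        patterns = ["", "A", "TA", "GGGG", body[: params.w], body[-params.w :]]
        for length in (3, 8, 20, 60):
            if length >= len(body):
                continue
            for _ in range(4):
                start = int(rng.integers(0, len(body) - length + 1))
                q = body[start : start + length]
                patterns.append(q)
                qm = list(q)
                qm[int(rng.integers(0, length))] = "T"
                patterns.append("".join(qm))
        for q in patterns:
            expected = naive_occurrences(text, q)
            assert count(idx, q) == expected, (q, params)
            assert count_single_level(idx, q) == expected

    def test_counts_invariant_to_parameters(self):
        """The same pattern counts identically under every (w, p)."""
        rng = np.random.default_rng(11)
        text = random_dna(rng, 600) + "$"
        queries = [text[i : i + L] for i, L in [(3, 9), (100, 30), (250, 80), (0, 4)]]
        results = []
        for w, p in [(2, 1), (2, 7), (4, 11), (6, 31), (8, 50), (10, 101)]:
            idx = build_index(text, ParseParams(w=w, p=p))
            results.append([count(idx, q) for q in queries])
        assert all(r == results[0] for r in results)
        assert results[0] == [naive_occurrences(text, q) for q in queries]


class TestPhraseMapExactness:
    def test_random_probes_never_collide(self, example_index):
        """Phrase-shaped strings outside the dictionary all map to None."""
        rng = np.random.default_rng(99)
        phrases = set(example_index.dictionary.phrases)
        hits = 0
        for _ in range(10_000):
            length = int(rng.integers(3, 15))
            probe = "".join(rng.choice(list("ACGT"), size=length))
            got = example_index.phrase_map.lookup(probe)
            if probe in phrases:
                hits += 1
                assert example_index.dictionary.phrases[got] == probe
            else:
                assert got is None
        # membership lookups of true phrases still succeed
        for pid, phrase in enumerate(example_index.dictionary.phrases):
            assert example_index.phrase_map.lookup(phrase) == pid


class TestSerialization:
    def test_round_trip_preserves_counts(self, tmp_path):
        rng = np.random.default_rng(13)
        text = random_dna(rng, 700) + "$"
        idx = build_index(text, ParseParams(w=4, p=11))
        path = tmp_path / "idx.pfm"
        save_index(idx, path)
        idx2 = load_index(path)
        for _ in range(100):
            length = int(rng.integers(1, 40))
            start = int(rng.integers(0, len(text) - 1 - length))
            q = text[start : start + length]
            assert count(idx2, q) == count(idx, q)

    def test_round_trip_on_worked_example(self, example_index, tmp_path):
        path = tmp_path / "ex.pfm"
        save_index(example_index, path)
        t = count_trace(load_index(path), EXAMPLE_QUERY)
        assert (t.beta_interval.lo, t.beta_interval.hi) == (31, 32)
        assert (t.final.lo, t.final.hi) == (14, 14) and t.count == 1

    def test_corrupted_header_raises_load_error(self, tmp_path):
        bad = tmp_path / "bad.pfm"
        bad.write_bytes(b"phrasefm-index\n" + (12345).to_bytes(8, "little") + b"junk")
        with pytest.raises(IndexLoadError):
            load_index(bad)
        notmine = tmp_path / "other.bin"
        notmine.write_bytes(b"\x00\x01\x02")
        with pytest.raises(IndexLoadError):
            load_index(notmine)
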