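import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import naive_match
from lesmon.motifs import (
    MOTIF_ALPHABET,
    SequencePool,
    UTRStore,
    build_annotation_index,
    enumerate_motifs,
    find_occurrences,
    match_motif,
    read_utrs,
    reverse_complement,
    scramble_sequences,
)

rna = st.text(alphabet="ACGU", min_size=0, max_size=60)
patterns = st.text(alphabet=MOTIF_ALPHABET, min_size=1, max_size=8)


# ---------------------------------------------------------------------------
# reading


def test_read_utrs_truncation_and_rna_conversion(tmp_path):
    fasta = tmp_path / "utrs.fa"
    long_seq = "ACGT" * 155  # 620 nt
    fasta.write_text(f">P1 some description\n{long_seq}\n>P2\nATGC\n")
    store = read_utrs(fasta, truncate_to=500)
    assert store.weight("P1") == 500
    assert store.records["P2"] == ("AUGC",)
    assert "T" not in store.merged("P1")


def test_read_utrs_merges_variants_with_separator(tmp_path):
    fasta = tmp_path / "utrs.fa"
    fasta.write_text(">P\nAAA\n>P\nCCC\n")
    store = read_utrs(fasta)
    assert store.records["P"] == ("AAA", "CCC")
    assert store.weight("P") == 6
    # matches are found inside variants but never across the join
    assert [p for p, _, _ in find_occurrences(store, "AA")] == ["P", "P"]
    assert find_occurrences(store, "AC") == []


def test_read_utrs_drops_empty_records(tmp_path):
    fasta = tmp_path / "utrs.fa"
    fasta.write_text(">P1\nACGU\n>P2\n\n>P3\nGG\n")
    store = read_utrs(fasta)
    assert store.proteins == ["P1", "P3"]


def test_masked_characters_never_match():
    store = UTRStore(records={"P": ("ACNGU",)})
    # N in the sequence is masked: no motif symbol matches it, so only the
    # windows "AC" and "GU" match motif "NN"
    assert find_occurrences(store, "NN") == [("P", 0, 0), ("P", 0, 3)]


# ---------------------------------------------------------------------------
# enumeration


@pytest.mark.parametrize("alphabet", ["AC", "ACGU", MOTIF_ALPHABET])
@pytest.mark.parametrize("length", [1, 2, 3, 4])
def test_enumeration_is_exhaustive_and_unique(alphabet, length):
    if len(alphabet) ** length > 10_000:
        pytest.skip("covered by the motif-space acceptance check")
    motifs = list(enumerate_motifs(length, alphabet))
    assert len(motifs) == len(alphabet) ** length
    assert len(set(motifs)) == len(motifs)


def test_enumeration_order():
    assert list(enumerate_motifs(2, "AC")) == ["AA", "AC", "CA", "CC"]
    assert len(list(enumerate_motifs(1))) == 7


# ---------------------------------------------------------------------------
# matching


@pytest.mark.parametrize(
    "pattern, seq, expected",
    [
        ("NCGCYAUU", "AAGCGCCAUUAA", [2]),  # matches a GCGCCAUU instance
        ("YCGYYAUY", "CCGCCAUC", [0]),  # matches a CCGCCAUC instance
        ("RY", "AUAC", [0, 2]),
        ("AA", "AAAA", [0, 1, 2]),  # overlapping matches all reported
        ("N", "ACGU", [0, 1, 2, 3]),
        ("ACGU", "ACG", []),  # sequence shorter than motif
    ],
)
def test_match_examples(pattern, seq, expected):
    assert match_motif(pattern, seq) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(pattern=patterns, seq=rna)
def test_bitmask_matching_equals_naive_scan(pattern, seq):
    assert match_motif(pattern, seq) == naive_match(pattern, seq)


@pytest.mark.parametrize(
    "pattern, expected", [("AUGC", "GCAU"), ("R", "Y"), ("NRY", "RYN")]
)
def test_reverse_complement_examples(pattern, expected):
    assert reverse_complement(pattern) == expected


@settings(deadline=None, derandomize=True, max_examples=100)
@given(pattern=patterns)
def test_reverse_complement_is_involution(pattern):
    assert reverse_complement(reverse_complement(pattern)) == pattern


def _rc_seq(seq):
    return seq.translate(str.maketrans("ACGU", "UGCA"))[::-1]


@settings(deadline=None, derandomize=True, max_examples=100)
@given(pattern=patterns, seq=rna)
def test_occurrences_mirror_on_reverse_complement_strand(pattern, seq):
    fwd = len(match_motif(pattern, seq))
    rc = len(match_motif(reverse_complement(pattern), _rc_seq(seq)))
    assert fwd == rc


# ---------------------------------------------------------------------------
# annotation index


def test_annotation_presence_vs_occurrence_counts():
    store = UTRStore(
        records={"P1": ("AAACGAAACG",), "P2": ("AACGAA",), "P3": ("GGGGGG",)}
    )
    index = build_annotation_index(store, ["ACG", "CCC"], max_proteins=1500)
    entry = index.entries["ACG"]
    assert entry.proteins == frozenset({"P1", "P2"})  # presence per protein
    assert entry.n_occurrences_fwd == 3  # two in P1, one in P2
    assert entry.n_occurrences_rc == len(match_motif("CGU", store.merged("P1"))) + len(
        match_motif("CGU", store.merged("P2"))
    )
    assert "CCC" not in index  # zero-occurrence motifs dropped


def test_annotation_exclusion_flag():
    store = UTRStore(records={f"P{i}": ("ACGU",) for i in range(4)})
    index = build_annotation_index(store, ["ACGU"], max_proteins=3)
    assert index.entries["ACGU"].excluded  # 4 proteins > 3
    assert len(index.entries["ACGU"].proteins) == 4  # counts retained
    assert index.assessable_motifs() == []


def test_all_n_motif_matches_every_long_enough_protein(small_fixture):
    store = small_fixture.store
    index = build_annotation_index(store, ["N" * 8], max_proteins=10**6)
    eligible = {
        p for p in store.proteins
        if any(len(v) >= 8 for v in store.records[p])
    }
    assert index.entries["N" * 8].proteins == frozenset(eligible)


# ---------------------------------------------------------------------------
# scrambling


def _window_multisets(seq, window):
    return [sorted(seq[i : i + window]) for i in range(0, len(seq), window)]


def test_scramble_preserves_window_composition():
    store = UTRStore(records={"P": ("ACGUACGUACGUACGUACGUACGUA",)})  # 25 nt
    out = scramble_sequences(store, window=10, seed=5)
    orig, scram = store.records["P"][0], out.records["P"][0]
    assert len(scram) == 25
    assert _window_multisets(orig, 10) == _window_multisets(scram, 10)


def test_scramble_homopolymer_unchanged():
    store = UTRStore(records={"P": ("A" * 10,)})
    assert scramble_sequences(store, window=10, seed=1).records["P"] == ("A" * 10,)


def test_scramble_determinism():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGU"), 200))
    store = UTRStore(records={"P1": (seq,), "P2": (seq[:77],)})
    a = scramble_sequences(store, window=10, seed=3)
    b = scramble_sequences(store, window=10, seed=3)
    c = scramble_sequences(store, window=10, seed=4)
    assert a.records == b.records
    assert a.records != c.records


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seq=st.text(alphabet="ACGU", min_size=1, max_size=80),
       window=st.integers(min_value=1, max_value=12))
def test_scramble_window_invariants(seq, window):
    store = UTRStore(records={"P": (seq,)})
    out = scramble_sequences(store, window=window, seed=0).records["P"][0]
    assert len(out) == len(seq)
    assert _window_multisets(seq, window) == _window_multisets(out, window)


# ---------------------------------------------------------------------------
# pooled scanning consistency


def test_pool_scan_agrees_with_per_sequence_match(small_fixture):
    store = small_fixture.store
    pool = SequencePool(store)
    for pattern in ["ACGU", "RYN", small_fixture.spec.planted_motif]:
        via_pool = {}
        for protein, variant, offset in pool.occurrences(pattern):
            via_pool.setdefault(protein, []).append((variant, offset))
        for p in store.proteins:
            expected = [
                (vi, off)
                for vi, variant in enumerate(store.records[p])
                for off in match_motif(pattern, variant)
            ]
            assert via_pool.get(p, []) == expected
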