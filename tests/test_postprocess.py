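import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import exact_binom_upper, hypergeom_upper_bruteforce, naive_average_linkage
from lesmon.postprocess import (
    DISJOINT_DISTANCE,
    bh_adjust,
    build_family_tree,
    conservation_fold,
    conserved_background_fraction,
    cut_families,
    motif_distance,
    read_bed,
    strand_specificity,
    term_enrichment,
)


class FakeIndex:
    def __init__(self, sets):
        self.sets = sets

    def proteins_of(self, motif):
        return self.sets[motif]


# ---------------------------------------------------------------------------
# motif distance and families


def test_motif_distance_formula():
    v = {"a", "b", "c"}
    assert motif_distance(v, v) == 0.0  # identical sets
    assert motif_distance({"a"}, v) == 0.0  # subset: denominator is the min
    v1 = {f"x{i}" for i in range(10)}
    v2 = {f"x{i}" for i in range(5)} | {f"y{i}" for i in range(35)}
    assert motif_distance(v1, v2) == pytest.approx(1.0)  # s = 5/10 = 0.5
    assert motif_distance({"a"}, {"b"}) == DISJOINT_DISTANCE
    with pytest.raises(ValueError):
        motif_distance(set(), {"a"})


def test_identical_sets_merge_first_and_at_zero():
    sets = {"m1": frozenset({"a", "b"}), "m2": frozenset({"a", "b"}),
            "m3": frozenset({"x", "y"})}
    tree = build_family_tree(["m1", "m2", "m3"], FakeIndex(sets))
    first = tree.linkage_matrix[0]
    assert {int(first[0]), int(first[1])} == {0, 1}  # the identical pair
    assert first[2] == 0.0


def test_average_linkage_heights_match_naive_agglomeration():
    rng = np.random.default_rng(21)
    proteins = [f"p{i}" for i in range(40)]
    sets = {
        f"m{j:02d}": frozenset(rng.choice(proteins, size=rng.integers(3, 15), replace=False))
        for j in range(20)
    }
    motifs = sorted(sets)
    tree = build_family_tree(motifs, FakeIndex(sets))
    n = len(motifs)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = motif_distance(sets[motifs[i]], sets[motifs[j]])
    ref = naive_average_linkage(dmat)
    assert np.allclose(sorted(tree.linkage_matrix[:, 2]), ref, rtol=1e-9)


@pytest.mark.parametrize("target_k", [1, 5, 12])
def test_family_count_after_cut(target_k):
    rng = np.random.default_rng(8)
    proteins = [f"p{i}" for i in range(30)]
    sets = {
        f"m{j:02d}": frozenset(rng.choice(proteins, size=8, replace=False))
        for j in range(12)
    }
    # duplicate protein sets force tied (zero) merge heights
    sets["m12"] = sets["m00"]
    sets["m13"] = sets["m00"]
    motifs = sorted(sets)
    tree = build_family_tree(motifs, FakeIndex(sets))
    pvalues = {m: (i + 1) / 100 for i, m in enumerate(motifs)}
    fams = cut_families(tree, target_k, pvalues)
    assert fams.n_families == min(target_k, len(motifs))
    assert set(fams.assignments) == set(motifs)


def test_family_representatives():
    sets = {"aa": frozenset({"x"}), "bb": frozenset({"x"}), "cc": frozenset({"q"})}
    tree = build_family_tree(sorted(sets), FakeIndex(sets))
    pvalues = {"aa": 0.5, "bb": 0.001, "cc": 0.2}
    one = cut_families(tree, 1, pvalues)
    assert list(one.representatives.values()) == ["bb"]  # global best p
    singles = cut_families(tree, 3, pvalues)
    assert singles.n_families == 3
    assert sorted(singles.representatives.values()) == ["aa", "bb", "cc"]
    # tied p-values break lexicographically
    tie = cut_families(tree, 1, {"aa": 0.1, "bb": 0.1, "cc": 0.1})
    assert list(tie.representatives.values()) == ["aa"]


# ---------------------------------------------------------------------------
# conservation


def test_conservation_midpoint_boundary():
    # a length-8 occurrence at offset 10 has middle position 14
    elements = {"seq": [(14, 15)]}
    hit = conservation_fold([("seq", 10)], elements, 0.27, length=8)
    assert hit.cons_fraction == 1.0
    assert hit.fold == pytest.approx(1 / 0.27)
    miss = conservation_fold([("seq", 10)], {"seq": [(15, 20)]}, 0.27, length=8)
    assert miss.cons_fraction == 0.0 and miss.fold == 0.0


def test_conservation_no_occurrences_marked_unavailable():
    ann = conservation_fold([], {"seq": [(0, 5)]}, 0.27, length=8)
    assert not ann.available


def test_conservation_invariant_to_interval_splitting():
    occs = [("s", i) for i in range(0, 30, 3)]
    whole = conservation_fold(occs, {"s": [(5, 25)]}, 0.5, length=8)
    split = conservation_fold(occs, {"s": [(5, 11), (11, 17), (17, 25)]}, 0.5, length=8)
    assert whole.cons_fraction == split.cons_fraction
    assert whole.fold == split.fold


def test_background_fraction_merges_overlaps(small_fixture):
    class TinyStore:
        proteins = ["P1", "P2"]

        def weight(self, p):
            return 100

    frac = conserved_background_fraction(TinyStore(), {"P1": [(0, 30), (20, 50)], "P2": []})
    assert frac == pytest.approx(50 / 200)


def test_read_bed_roundtrip(tmp_path):
    bed = tmp_path / "cons.bed"
    bed.write_text("# header\nP1\t5\t20\nP1\t0\t3\nP2\t7\t9\n")
    elements = read_bed(bed)
    assert elements == {"P1": [(0, 3), (5, 20)], "P2": [(7, 9)]}
    bad = tmp_path / "bad.bed"
    bad.write_text("P1\t9\t5\n")
    with pytest.raises(ValueError):
        read_bed(bad)


# ---------------------------------------------------------------------------
# strand specificity


def test_strand_ratio_and_orientation():
    res = strand_specificity(150, 100)
    assert res.ratio == pytest.approx(1.5)
    assert res.pvalue < 0.01
    # reverse-biased motif: one-sided upper tail gives p near 1
    assert strand_specificity(100, 150).pvalue > 0.99
    assert strand_specificity(5, 0).ratio == float("inf")
    with pytest.raises(ValueError):
        strand_specificity(0, 0)


def test_strand_ratio_inverts_under_reverse_complement_counts():
    a, b = strand_specificity(120, 80), strand_specificity(80, 120)
    assert a.ratio == pytest.approx(1 / b.ratio)


@pytest.mark.parametrize(
    "n, fwd", [(100, 60), (200, 120), (500, 270), (1000, 540), (150, 80)]
)
def test_strand_normal_approximation_close_to_exact_binomial(n, fwd):
    approx = strand_specificity(fwd, n - fwd).pvalue
    exact = exact_binom_upper(n, fwd)
    assert abs(approx - exact) / exact < 0.10


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])  # single p unchanged
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)
    # hand-computed step-up: sorted p (0.01, 0.03, 0.04), raw m*p/i =
    # (0.03, 0.045, 0.04), monotone from the top -> (0.03, 0.04, 0.04)
    assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])


def test_bh_properties():
    rng = np.random.default_rng(12)
    p = np.sort(rng.random(50))
    adj = bh_adjust(p)
    assert (np.diff(adj) >= -1e-12).all()  # monotone on sorted input
    assert (adj >= p - 1e-12).all() and (adj <= 1).all()
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# term enrichment


def test_enrichment_edge_cases():
    background = {f"g{i}" for i in range(20)}
    core = {f"g{i}" for i in range(5)}
    full = term_enrichment(core, background, {"everything": set(background)})
    assert full["pvalue"].iloc[0] == pytest.approx(1.0)
    # empty intersection with a term larger than background - core
    disjoint = term_enrichment(core, background, {"rest": {f"g{i}" for i in range(5, 20)}})
    assert disjoint["pvalue"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        term_enrichment({"zz"}, background, {})
    empty_bg_term = term_enrichment(core, background, {"alien": {"not_here"}})
    assert len(empty_bg_term) == 0  # terms with no background members skipped


def test_enrichment_matches_hypergeometric_tail():
    background = {f"g{i}" for i in range(30)}
    term = {f"g{i}" for i in range(6)}
    core = {f"g{i}" for i in range(6)}  # core = all term members
    frame = term_enrichment(core, background, {"t": term})
    expected = hypergeom_upper_bruteforce(30, 6, 6, 6)
    assert frame["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-12)


def test_enrichment_exact_for_random_small_tables():
    rng = np.random.default_rng(31)
    for _ in range(30):
        n_bg = int(rng.integers(10, 51))
        background = {f"g{i}" for i in range(n_bg)}
        term = set(rng.choice(sorted(background), size=rng.integers(1, n_bg), replace=False))
        core = set(rng.choice(sorted(background), size=rng.integers(1, n_bg // 2 + 1), replace=False))
        frame = term_enrichment(core, background, {"t": term})
        expected = hypergeom_upper_bruteforce(n_bg, len(term), len(core), len(core & term))
        assert frame["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)
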