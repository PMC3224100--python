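"""SSR mining: motif canonicalisation, class thresholds, compound merging,
and equivalence with an exhaustive brute-force scanner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estpoly import Contig
from estpoly.ssr_miner import (
    SsrLocus,
    SsrRules,
    canonical_motif,
    find_perfect_ssrs,
    merge_compound,
    min_locus_length,
    ssr_summary,
)

from oracles import brute_force_ssrs


# ---------------------------------------------------------------------------
# canonical_motif
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "word,expected",
    [
        ("GAC", "ACG"),
        ("CAG", "AGC"),
        ("ATAT", "AT"),
        ("ACGACG", "ACG"),
        ("AT", "AT"),
        ("TTCTTC", "CTT"),
    ],
)
def test_canonical_motif_smallest_rotation_of_primitive_root(word, expected):
    assert canonical_motif(word) == expected


@pytest.mark.parametrize("word", ["AAA", "AA", "TTTT", "CCCCCC"])
def test_canonical_motif_rejects_mononucleotide(word):
    with pytest.raises(ValueError, match="mononucleotide"):
        canonical_motif(word)


@pytest.mark.parametrize("word", ["ANA", "acg", "A-C"])
def test_canonical_motif_rejects_non_acgt(word):
    with pytest.raises(ValueError):
        canonical_motif(word)


@given(st.text(alphabet="ACGT", min_size=2, max_size=6))
@settings(max_examples=200, deadline=None)
def test_canonical_motif_is_rotation_invariant(word):
    try:
        c = canonical_motif(word)
    except ValueError:
        return  # mononucleotide root
    for i in range(len(word)):
        assert canonical_motif(word[i:] + word[:i]) == c


# ---------------------------------------------------------------------------
# find_perfect_ssrs: class thresholds and structure
# ---------------------------------------------------------------------------

FLANK_L = "GATTCGTACGGTTAGCATCG"  # 20 nt, no repeats
FLANK_R = "TGCATCAGGATCCATACGTC"


def _mine(insert, rules=None):
    contig = Contig("c", FLANK_L + insert + FLANK_R)
    return find_perfect_ssrs(contig, rules)


@pytest.mark.parametrize(
    "insert,expected",
    [
        ("AC" * 6, [("AC", 6, 12)]),     # dinucleotide at its minimum of 6 units
        ("AC" * 5, []),                   # one unit below threshold: nothing
        ("AGC" * 4, [("AGC", 4, 12)]),    # trinucleotide minimum of 4 units
        ("AGC" * 3, []),
        ("AGCT" * 3, [("AGCT", 3, 12)]),  # tetranucleotide minimum 3
        ("AGCT" * 2, []),
        ("AACGT" * 3, [("AACGT", 3, 15)]),
        ("AACGTC" * 3, [("AACGTC", 3, 18)]),
        ("A" * 15, []),                   # mononucleotide runs out of scope
    ],
)
def test_class_minimum_repeat_thresholds(insert, expected):
    loci = _mine(insert)
    got = [(l.motif, l.repeats, l.length) for l in loci]
    want = [(canonical_motif(m), r, ln) for (m, r, ln) in expected]
    assert got == want


def test_locus_coordinates_and_partial_trailing_unit():
    # (AC)x6 plus a dangling 'A': repeats stay 6, span stays 12
    loci = _mine("AC" * 6 + "A" + "GGTT")
    assert len(loci) == 1
    l = loci[0]
    assert (l.start, l.end, l.repeats) == (20, 32, 6)


def test_runs_broken_at_n():
    # 5+5 units split by N: neither fragment reaches 6 units
    loci = _mine("AC" * 5 + "N" + "AC" * 5)
    assert loci == []
    # 6 units before the N still qualify
    loci = _mine("AC" * 6 + "N" + "AC" * 3)
    assert [(l.motif, l.repeats) for l in loci] == [("AC", 6)]


def test_reported_motifs_are_canonical_and_strand_preserved():
    loci = _mine("GA" * 8)
    assert [(l.motif, l.repeats) for l in loci] == [("AG", 8)]
    # reverse complement of AG is CT: mined as its own motif, not folded
    loci = _mine("CT" * 8)
    assert [(l.motif, l.repeats) for l in loci] == [("CT", 8)]


def test_rules_validation():
    with pytest.raises(ValueError):
        SsrRules(min_repeats={2: 1, 3: 4, 4: 3, 5: 3, 6: 3})
    with pytest.raises(ValueError):
        SsrRules(compound_max_gap=-1)
    with pytest.raises(ValueError):
        SsrRules(motif_lengths={1, 2})


def test_min_locus_length_under_default_rules():
    assert min_locus_length(SsrRules()) == 12
    assert min_locus_length(SsrRules(min_repeats={2: 8, 3: 5, 4: 3, 5: 3, 6: 3})) == 12


# ---------------------------------------------------------------------------
# Oracle equivalence (small sample here; the large sweep is in acceptance)
# ---------------------------------------------------------------------------

def test_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(99)
    for _ in range(40):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        loci = find_perfect_ssrs(Contig("c", seq))
        got = {(l.start, l.end, l.motif, l.repeats) for l in loci}
        assert got == brute_force_ssrs(seq)


def test_matches_brute_force_on_repeat_dense_sequences():
    rng = np.random.default_rng(7)
    motifs = ["AC", "AGC", "AT", "AAG", "ACGT", "AACGT"]
    for _ in range(40):
        parts = []
        for _ in range(6):
            parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, 15)))
            m = motifs[rng.integers(len(motifs))]
            parts.append(m * int(rng.integers(2, 9)))
        seq = "".join(parts)
        loci = find_perfect_ssrs(Contig("c", seq))
        got = {(l.start, l.end, l.motif, l.repeats) for l in loci}
        assert got == brute_force_ssrs(seq)


@given(st.text(alphabet="ACGTN", min_size=20, max_size=120))
@settings(max_examples=150, deadline=None)
def test_no_reported_locus_violates_class_minimum_or_primitivity(seq):
    rules = SsrRules()
    for l in find_perfect_ssrs(Contig("c", seq), rules):
        k = len(l.motif)
        assert l.repeats >= rules.min_repeats[k]
        assert canonical_motif(l.motif) == l.motif
        assert l.end - l.start == l.repeats * k
        # the reported span really is a perfect repeat of the motif (some rotation)
        tract = seq[l.start : l.end]
        rotations = {l.motif[i:] + l.motif[:i] for i in range(k)}
        assert tract[:k] in rotations and tract == tract[:k] * l.repeats


# ---------------------------------------------------------------------------
# Compound merging
# ---------------------------------------------------------------------------

def _locus(start, motif, reps, cid="c"):
    return SsrLocus(cid, start, start + reps * len(motif), motif, reps)


@pytest.mark.parametrize(
    "gap,n_expected,classes",
    [
        (10, 1, ["compound"]),  # boundary inclusive: <=10 merges
        (11, 2, ["perfect", "perfect"]),
        (0, 1, ["compound"]),   # immediately adjacent loci merge
    ],
)
def test_compound_gap_boundary(gap, n_expected, classes):
    a = _locus(38, "AC", 6)          # ends at 50
    b = _locus(50 + gap, "AGC", 4)
    merged = merge_compound([a, b])
    assert [m.ssr_class for m in merged] == classes
    assert len(merged) == n_expected
    if n_expected == 1:
        m = merged[0]
        assert (m.start, m.end) == (38, b.end)
        assert m.components == (("AC", 6, 38, 50), ("AGC", 4, b.start, b.end))


def test_compound_merge_is_idempotent_and_partitions_chains():
    loci = [_locus(0, "AC", 6), _locus(20, "AGC", 4), _locus(100, "AT", 7)]
    merged = merge_compound(loci)
    assert [m.ssr_class for m in merged] == ["compound", "perfect"]
    perfect_out = [m for m in merged if m.ssr_class == "perfect"]
    assert merge_compound(perfect_out) == perfect_out
    # every base of a compound lies in a component or a gap <= max gap
    comp = merged[0]
    for (m1, _r1, _s1, e1), (_m2, _r2, s2, _e2) in zip(comp.components, comp.components[1:]):
        assert 0 <= s2 - e1 <= 10


def test_compound_merge_rejects_unsorted_or_overlapping():
    with pytest.raises(ValueError, match="sorted"):
        merge_compound([_locus(50, "AC", 6), _locus(0, "AC", 6)])
    with pytest.raises(ValueError, match="overlap"):
        merge_compound([_locus(0, "AC", 6), _locus(5, "AGC", 4)])
    with pytest.raises(ValueError, match="multiple contigs"):
        merge_compound([_locus(0, "AC", 6, "c1"), _locus(50, "AC", 6, "c2")])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_ssr_summary_tallies():
    loci = [_locus(0, "AC", 6), _locus(50, "AT", 7), _locus(100, "TA", 6),
            _locus(150, "AGC", 4), _locus(200, "CTG", 5)]
    s = ssr_summary(loci)
    assert s["total"] == 5
    assert s["by_motif_length"] == {2: 3, 3: 2}
    assert sum(s["length_counts"].values()) == 5
    assert s["min_possible_length"] == 12
    assert s["min_length"] >= 12


def test_ssr_summary_empty():
    s = ssr_summary([])
    assert s["total"] == 0 and s["by_motif_length"] == {}
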