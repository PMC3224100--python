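"""SNP caller: site alleles, the quality posterior vs an exact-rational
oracle, per-sample status rules, the filter cascade, isolation, class codes,
ts/tv and summaries."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estpoly import Contig, GenotypePanel
from estpoly.io_formats import PileupColumn
from estpoly.snp_caller import (
    SnpFilterParams,
    apply_filters,
    call_snps,
    classify_code,
    genotype_membership,
    isolation_filter,
    make_candidate,
    polymorphism_quality,
    sample_status,
    site_allele_counts,
    snp_summaries,
    ts_tv,
)

from oracles import exact_posterior

PANEL = GenotypePanel(("g1", "g2", "g3"))


def _col(counts, pos=500, cid="c1"):
    """counts: {sample: {base: n}}; missing samples/bases filled with 0."""
    full = {
        s: {b: counts.get(s, {}).get(b, 0) for b in "ACGT"} for s in PANEL.samples
    }
    return PileupColumn(cid, pos, full)


# ---------------------------------------------------------------------------
# site_allele_counts
# ---------------------------------------------------------------------------

def test_top_two_alleles_by_pooled_count():
    col = _col({"g1": {"A": 10, "G": 8}, "g2": {"A": 5, "G": 4, "C": 1}})
    pooled, major, minor = site_allele_counts(col)
    assert (major, minor) == ("A", "G")
    assert pooled == {"A": 15, "C": 1, "G": 12, "T": 0}


def test_tie_broken_alphabetically():
    col = _col({"g1": {"G": 10, "A": 10}})
    _, major, minor = site_allele_counts(col)
    assert (major, minor) == ("A", "G")


def test_monomorphic_column_has_no_minor():
    _, major, minor = site_allele_counts(_col({"g1": {"A": 30}}))
    assert major == "A" and minor is None


def test_all_zero_column_errors():
    with pytest.raises(ValueError, match="all-zero"):
        site_allele_counts(_col({}))


# ---------------------------------------------------------------------------
# polymorphism_quality
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "maj,mnr,above",
    [(20, 0, False), (15, 12, True), (15, 1, False)],
)
def test_quality_posterior_spec_points(maj, mnr, above):
    q = polymorphism_quality(maj, mnr, 0.01)
    assert (q > 0.99) is above
    if mnr == 0:
        assert q < 0.5


def test_quality_matches_exact_rational_oracle_on_sample_grid():
    for maj in (1, 5, 10, 20, 40, 60):
        for mnr in range(0, maj + 1, 3):
            got = polymorphism_quality(maj, mnr, 0.01)
            want = float(exact_posterior(maj, mnr, Fraction(1, 100)))
            assert got == pytest.approx(want, abs=1e-9)


@given(st.integers(1, 80), st.integers(0, 40))
@settings(max_examples=120, deadline=None)
def test_quality_monotone_in_minor_count(maj, mnr):
    if mnr + 1 > maj:
        return
    q1 = polymorphism_quality(maj, mnr, 0.01)
    q2 = polymorphism_quality(maj, mnr + 1, 0.01)
    assert 0.0 <= q1 <= 1.0
    assert q2 >= q1


def test_quality_input_validation():
    with pytest.raises(ValueError):
        polymorphism_quality(0, 0)
    with pytest.raises(ValueError):
        polymorphism_quality(10, 2, error_rate=0.0)


# ---------------------------------------------------------------------------
# sample_status
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "g1_counts,expected_status,expected_major",
    [
        ({"A": 10, "G": 10}, "P", None),   # balanced within sample
        ({"A": 20}, "M", "A"),             # fixed
        ({"A": 2, "G": 1}, "N", None),     # depth 3 < 5
        ({"A": 19, "G": 1}, "M", "A"),     # frac 0.05 < 0.2
        ({"A": 16, "G": 4}, "P", "A"),     # exactly at count and frac thresholds
        ({"A": 17, "G": 3}, "M", "A"),     # count 3 < 4
    ],
)
def test_within_sample_status_rule(g1_counts, expected_status, expected_major):
    col = _col({"g1": g1_counts, "g2": {"A": 10}, "g3": {"G": 10}})
    statuses = sample_status(col, "A", "G", SnpFilterParams(), PANEL)
    st_g1 = statuses[0]
    assert st_g1.sample == "g1"
    assert st_g1.status == expected_status
    if expected_major is not None and expected_status == "M":
        assert st_g1.major_allele == expected_major


def test_status_n_iff_depth_below_threshold():
    col = _col({"g1": {"A": 5}, "g2": {"A": 4}, "g3": {"A": 6, "G": 4}})
    statuses = sample_status(col, "A", "G", SnpFilterParams(), PANEL)
    assert [s.status for s in statuses] == ["M", "N", "P"]
    assert [s.depth for s in statuses] == [5, 4, 10]


# ---------------------------------------------------------------------------
# classify_code and ts_tv
# ---------------------------------------------------------------------------

def test_classify_code_concatenates_in_panel_order():
    col = _col({"g1": {"A": 10, "G": 10}, "g2": {"A": 20}, "g3": {"G": 20}})
    statuses = sample_status(col, "A", "G", SnpFilterParams(), PANEL)
    assert classify_code(statuses, PANEL) == "PMM"


def test_classify_code_length_mismatch_errors():
    col = _col({"g1": {"A": 10}, "g2": {"A": 10}, "g3": {"A": 10}})
    statuses = sample_status(col, "A", "G", SnpFilterParams(), PANEL)
    with pytest.raises(ValueError):
        classify_code(statuses[:2], PANEL)


def test_ts_tv_exhaustive_partition():
    import itertools

    ts_pairs = {frozenset(p) for p in itertools.combinations("ACGT", 2)
                if ts_tv(*p) == "ts"}
    assert ts_pairs == {frozenset("AG"), frozenset("CT")}
    for a, b in itertools.combinations("ACGT", 2):
        assert ts_tv(a, b) == ts_tv(b, a)
    with pytest.raises(ValueError):
        ts_tv("A", "A")


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def _candidate(counts, pos=500, contig_len=2000, params=None):
    col = _col(counts, pos=pos)
    return make_candidate(col, contig_len, PANEL, params or SnpFilterParams())


def test_fails_avg_cov_only():
    # pooled A:15/G:12 over 3 samples: avg 9 < 10, everything else passes
    cand = _candidate({
        "g1": {"A": 5, "G": 4}, "g2": {"A": 5, "G": 4}, "g3": {"A": 5, "G": 4},
    })
    passing = apply_filters([cand], {"c1": 2000}, PANEL, SnpFilterParams())
    assert passing == []
    assert cand.filters_failed == ["min_avg_cov"]


def test_fails_minor_cov():
    cand = _candidate({"g1": {"A": 8, "G": 5}, "g2": {"A": 7, "G": 4}, "g3": {"A": 15}})
    apply_filters([cand], {"c1": 2000}, PANEL, SnpFilterParams())
    assert "min_minor_cov" in cand.filters_failed


def test_fails_flank_near_contig_end():
    cand = _candidate(
        {"g1": {"A": 10, "G": 5}, "g2": {"A": 10, "G": 5}, "g3": {"A": 5, "G": 5}},
        pos=50,
    )
    apply_filters([cand], {"c1": 2000}, PANEL, SnpFilterParams())
    assert "min_flank" in cand.filters_failed
    assert cand.flank == 50


def test_identical_fixed_majors_is_not_a_snp():
    # all samples M with the same major allele (minor frac 4/25 < 0.2):
    # no inter-sample contrast even though pooled counts pass
    cand = _candidate({
        "g1": {"A": 21, "G": 4}, "g2": {"A": 21, "G": 4}, "g3": {"A": 21, "G": 4},
    })
    assert cand.class_code == "MMM"
    apply_filters([cand], {"c1": 2000}, PANEL, SnpFilterParams())
    assert "not_inter_sample_polymorphic" in cand.filters_failed


def test_two_fixed_samples_with_different_majors_is_a_snp():
    cand = _candidate({
        "g1": {"A": 15}, "g2": {"G": 15}, "g3": {"A": 14, "G": 1},
    })
    passing = apply_filters([cand], {"c1": 2000}, PANEL, SnpFilterParams())
    assert passing == [cand]
    assert cand.class_code == "MMM"
    assert cand.filters_failed == []


# ---------------------------------------------------------------------------
# Isolation
# ---------------------------------------------------------------------------

def _cands_at(positions):
    return [
        _candidate(
            {"g1": {"A": 10}, "g2": {"G": 15}, "g3": {"A": 10, "G": 5}}, pos=p
        )
        for p in positions
    ]


@pytest.mark.parametrize(
    "positions,kept",
    [
        ([200, 220], []),          # 20 nt apart: BOTH removed
        ([200, 230], [200, 230]),  # exactly 30: boundary inclusive, both kept
        ([200], [200]),            # lone candidate kept
        ([200, 220, 400], [400]),  # close pair removed, distant one survives
    ],
)
def test_isolation_symmetric_removal(positions, kept):
    out = isolation_filter(_cands_at(positions), 30, contig_length=2000)
    assert [c.pos for c in out] == kept


def test_isolation_field_distance_or_sentinel():
    a, b = _cands_at([200, 260])
    out = isolation_filter([a, b], 30, contig_length=2000)
    assert [c.isolation for c in out] == [60, 60]
    (lone,) = isolation_filter(_cands_at([500]), 30, contig_length=2000)
    assert lone.isolation == 2000


# ---------------------------------------------------------------------------
# End-to-end call_snps invariants on simulated data
# ---------------------------------------------------------------------------

def test_called_snps_satisfy_all_emission_invariants(sim_small):
    sim, pileups = sim_small
    params = SnpFilterParams()
    snps = call_snps(pileups, sim.contigs, sim.panel, params)
    assert snps
    by_contig = {}
    for s in snps:
        assert s.minor_count >= params.min_minor_cov
        assert s.major_count >= params.min_major_cov
        assert s.flank >= params.min_flank
        assert s.quality >= params.min_quality
        assert s.allele_major != s.allele_minor
        assert len(s.class_code) == len(sim.panel.samples)
        assert set(s.class_code) <= set("MPN")
        assert s.class_code != "N" * len(sim.panel.samples)
        if set(s.class_code) == {"M"}:
            majors = {st.major_allele for st in s.statuses if st.status == "M"}
            assert len(majors) >= 2
        by_contig.setdefault(s.contig_id, []).append(s.pos)
    for positions in by_contig.values():
        positions.sort()
        for a, b in zip(positions, positions[1:]):
            assert b - a >= params.min_isolation


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _mk_snp(cid, pos, tstv="ts", code="PMM"):
    """Build a candidate whose per-sample counts realise the wanted class code."""
    m_major = ["A", "G"]
    counts, m_i = {}, 0
    for sample, letter in zip(("g1", "g2", "g3"), code):
        if letter == "P":
            counts[sample] = {"A": 10, "G": 10}
        elif letter == "M":
            counts[sample] = {m_major[m_i % 2]: 20}
            m_i += 1
        else:
            counts[sample] = {"A": 2}
    cand = _candidate(counts, pos=pos)
    assert cand.class_code == code
    cand.contig_id = cid
    cand.tstv = tstv
    return cand


def test_density_per_kb_uses_snp_bearing_contigs():
    contigs = [Contig("c1", "A" * 3000), Contig("c2", "A" * 2000), Contig("c3", "A" * 9000)]
    snps = [_mk_snp("c1", p) for p in (200, 400, 600, 800, 1000, 1200)] + [
        _mk_snp("c2", p) for p in (300, 600, 900, 1200)
    ]
    s = snp_summaries(snps, contigs)
    assert s["n_snps"] == 10
    assert s["density_per_kb"] == pytest.approx(10 / 5.0)  # c3 bears no SNPs
    assert s["mean_snps_per_contig"] == pytest.approx(5.0)
    assert s["n_contigs_multi_snp"] == 2


def test_rollup_buckets_m_p_and_mixed():
    contigs = [Contig("c1", "A" * 2000)]
    snps = [_mk_snp("c1", 200, code="PMM"), _mk_snp("c1", 400, code="MPM")]
    s = snp_summaries(snps, contigs)
    # sample g1 saw P then M on c1 -> M+P bucket; g3 saw M,M -> M bucket
    assert s["per_sample_rollup"]["g1"] == {"M": 0, "P": 0, "M+P": 1}
    assert s["per_sample_rollup"]["g2"] == {"M": 0, "P": 0, "M+P": 1}
    assert s["per_sample_rollup"]["g3"] == {"M": 1, "P": 0, "M+P": 0}


def test_ts_tv_counts_partition_snp_set():
    contigs = [Contig("c1", "A" * 2000)]
    snps = [_mk_snp("c1", 100 * i, tstv="ts" if i % 3 else "tv") for i in range(1, 10)]
    s = snp_summaries(snps, contigs)
    assert s["ts_count"] + s["tv_count"] == s["n_snps"] == 9


def test_empty_summary_is_zeros():
    s = snp_summaries([], [Contig("c1", "ACGT" * 100)])
    assert s["n_snps"] == 0 and s["density_per_kb"] == 0.0


# ---------------------------------------------------------------------------
# Genotype membership
# ---------------------------------------------------------------------------

def test_genotype_membership_venn_cells_partition_contigs(sim_small):
    sim, pileups = sim_small
    presence, sharing = genotype_membership(pileups, sim.panel)
    assert sum(sharing.values()) == len(pileups)
    # at 40x everything is covered by all three samples except deletions
    assert presence and all(len(p) == 3 for p in presence.values())


def test_genotype_membership_absent_sample():
    from estpoly.io_formats import ContigPileup

    pl = ContigPileup("c1", 100, ("g1", "g2", "g3"))
    pl.add("g1", 10, "A", 5)
    pl.add("g3", 20, "C", 2)
    presence, sharing = genotype_membership({"c1": pl}, PANEL)
    assert presence["c1"] == frozenset({"g1", "g3"})
    assert sharing[("g1", "g3")] == 1
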