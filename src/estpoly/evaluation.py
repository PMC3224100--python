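"""Truth-closure metrics: compare detector output against planted truth.

A planted SNP counts toward the recall denominator only when its observed
pileup satisfies every calling threshold (coverage, flank, quality, contrast):
sites starved of minor-allele reads by sampling noise are excluded, exactly as
a caller cannot be expected to find them.  Eligibility is recomputed here from
the observed counts through the public site-level ops; isolation eligibility
is guaranteed by the generator's SNP spacing (40 nt > the 30 nt threshold)
rather than re-derived.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

from .io_formats import ContigPileup, GenotypePanel
from .snp_caller import (
    SnpFilterParams,
    _has_contrast,
    polymorphism_quality,
    sample_status,
    site_allele_counts,
)


def ssr_recall(truth_ssrs, mined) -> Dict:
    """Fraction of planted SSR loci recovered exactly (span, motif, repeats)."""
    found = {(m.contig_id, m.start, m.end, m.motif, m.repeats) for m in mined}
    n = len(truth_ssrs)
    hit = sum(
        1
        for t in truth_ssrs
        if (t.contig_id, t.start, t.end, t.motif, t.repeats) in found
    )
    return {"n_truth": n, "n_recovered": hit, "recall": hit / n if n else 1.0}


def indel_metrics(truth_indels, detected, min_len: int = 3, max_len: int = 50) -> Dict:
    """Recall over in-bounds planted indels; out-of-bounds must stay absent."""
    det = {
        (d.contig_id, d.ref_start, d.length, frozenset(d.carriers)) for d in detected
    }
    in_bounds = [t for t in truth_indels if min_len <= t.length <= max_len]
    out_bounds = [t for t in truth_indels if not min_len <= t.length <= max_len]
    hit = sum(
        1
        for t in in_bounds
        if (t.contig_id, t.start, t.length, frozenset(t.carriers)) in det
    )
    leaked = sum(
        1
        for t in out_bounds
        if (t.contig_id, t.start, t.length, frozenset(t.carriers)) in det
    )
    return {
        "n_in_bounds": len(in_bounds),
        "n_recovered": hit,
        "recall": hit / len(in_bounds) if in_bounds else 1.0,
        "n_out_of_bounds": len(out_bounds),
        "n_out_of_bounds_detected": leaked,
    }


def snp_eligible(
    truth_snp,
    pileup: ContigPileup,
    panel: GenotypePanel,
    params: SnpFilterParams = None,
) -> bool:
    """Does the observed pileup at a planted SNP satisfy every threshold?"""
    params = params or SnpFilterParams()
    col = pileup.column(truth_snp.pos)
    pooled = col.pooled()
    if sum(pooled.values()) == 0:
        return False
    _pooled, major, minor = site_allele_counts(col)
    if minor is None or {major, minor} != {truth_snp.ref, truth_snp.alt}:
        return False
    if pooled[major] < params.min_major_cov or pooled[minor] < params.min_minor_cov:
        return False
    if col.depth_total / len(panel.samples) < params.min_avg_cov:
        return False
    flank = min(truth_snp.pos, pileup.length - 1 - truth_snp.pos)
    if flank < params.min_flank:
        return False
    if polymorphism_quality(pooled[major], pooled[minor], params.error_rate) < params.min_quality:
        return False
    statuses = sample_status(col, major, minor, params, panel)
    return _has_contrast(statuses)


def snp_metrics(
    truth_snps,
    called,
    pileups: Mapping[str, ContigPileup],
    panel: GenotypePanel,
    params: SnpFilterParams = None,
) -> Dict:
    """Recall against eligible planted SNPs and precision against all planted."""
    params = params or SnpFilterParams()
    planted = {(t.contig_id, t.pos) for t in truth_snps}
    called_pos = {(c.contig_id, c.pos) for c in called}
    eligible = [
        t
        for t in truth_snps
        if t.contig_id in pileups and snp_eligible(t, pileups[t.contig_id], panel, params)
    ]
    n_elig = len(eligible)
    tp_elig = sum(1 for t in eligible if (t.contig_id, t.pos) in called_pos)
    tp = sum(1 for key in called_pos if key in planted)
    fp = len(called_pos) - tp
    return {
        "n_planted": len(truth_snps),
        "n_eligible": n_elig,
        "n_called": len(called_pos),
        "tp": tp,
        "fp": fp,
        "recall": tp_elig / n_elig if n_elig else 1.0,
        "precision": tp / len(called_pos) if called_pos else 1.0,
    }
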