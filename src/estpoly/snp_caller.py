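"""Multi-sample SNP calling from per-genotype pileups.

The filter cascade mirrors stringent EST-SNP discovery from pooled
transcriptome alignments: a biallelic site passes when the pooled major and
minor alleles each reach 10 reads, average per-sample coverage reaches 10, the
site lies at least 100 nt from either contig end, the polymorphism posterior
reaches 0.99, inter-sample contrast exists, and no other candidate sits within
30 nt (both members of a close pair are removed).

Per genotype, a site is classed ``P`` (intra-sample polymorphic: both alleles
seen within the sample's reads), ``M`` (intra-sample monomorphic) or ``N``
(insufficient depth); concatenating the letters in panel order yields class
codes such as ``PMM``.

Quality model
-------------
The polymorphism posterior contrasts two hypotheses on the top-two pooled
allele counts with equal priors:

* H0 (monomorphic): every read is the major allele except sequencing errors,
  each specific alternative base arising at rate e/3;
* H1 (balanced biallelic): each read is major or minor with probability
  (1-e)/2 + e/6 each (a 50/50 site perturbed by the same error process).

With counts (n_maj, n_min) the posterior is L1/(L0+L1) where
L0 = (1-e)^n_maj (e/3)^n_min and L1 = ((1-e)/2 + e/6)^(n_maj+n_min); binomial
coefficients cancel.  The posterior is monotone non-decreasing in the minor
count at fixed depth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import BASES, Contig, ContigPileup, GenotypePanel, PileupColumn

TRANSITIONS = (frozenset("AG"), frozenset("CT"))


@dataclass(frozen=True)
class SnpFilterParams:
    """Thresholds of the SNP filter cascade.

    ``min_major_cov``/``min_minor_cov``/``min_avg_cov``/``min_flank``/
    ``min_quality``/``min_isolation`` follow the published cascade for
    EST-SNP discovery; ``error_rate``, the within-sample polymorphism rule
    (``within_minor_count``, ``within_minor_frac``) and ``min_sample_depth``
    are this package's configurable defaults, chosen to be robust at
    10-60x transcript depth.
    """

    min_major_cov: int = 10
    min_minor_cov: int = 10
    min_avg_cov: float = 10.0
    min_flank: int = 100
    min_quality: float = 0.99
    min_isolation: int = 30
    error_rate: float = 0.01
    within_minor_count: int = 4
    within_minor_frac: float = 0.2
    min_sample_depth: int = 5
    #: report flag: mark sites whose total depth reaches this (20x convention)
    high_depth: int = 20

    def __post_init__(self) -> None:
        for name in ("min_major_cov", "min_minor_cov", "min_avg_cov", "min_flank",
                     "min_isolation", "within_minor_count", "min_sample_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_quality", "error_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if not 0.0 <= self.within_minor_frac <= 1.0:
            raise ValueError("within_minor_frac must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SnpFilterParams":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass(frozen=True)
class GenotypeSiteStatus:
    """Per-sample intra-sample polymorphism status at one site."""

    sample: str
    status: str  # M | P | N
    major_allele: Optional[str]
    depth: int


@dataclass
class SnpCandidate:
    """A biallelic site with pooled alleles, per-sample statuses and verdicts."""

    contig_id: str
    pos: int  # 0-based
    allele_major: str
    allele_minor: str
    per_sample_counts: Mapping[str, Mapping[str, int]]
    quality: float
    flank: int
    depth_total: int
    statuses: Tuple[GenotypeSiteStatus, ...]
    class_code: str
    tstv: str
    isolation: Optional[int] = None
    filters_failed: List[str] = field(default_factory=list)

    @property
    def major_count(self) -> int:
        return sum(c[self.allele_major] for c in self.per_sample_counts.values())

    @property
    def minor_count(self) -> int:
        return sum(c[self.allele_minor] for c in self.per_sample_counts.values())


# ---------------------------------------------------------------------------
# Site-level operations
# ---------------------------------------------------------------------------

def site_allele_counts(col: PileupColumn):
    """Pooled base counts and the top-two alleles (ties broken alphabetically).

    Returns ``(pooled, major, minor)`` with ``minor`` None when only one base
    is observed.  Third/fourth alleles remain in depth but are never alleles.
    """
    pooled = col.pooled()
    if sum(pooled.values()) == 0:
        raise ValueError(f"all-zero pileup column at {col.contig_id}:{col.pos}")
    ranked = sorted(BASES, key=lambda b: (-pooled[b], b))
    major = ranked[0]
    minor = ranked[1] if pooled[ranked[1]] > 0 else None
    return pooled, major, minor


def polymorphism_quality(n_major: int, n_minor: int, error_rate: float = 0.01) -> float:
    """Posterior probability the site is balanced-biallelic rather than
    monomorphic-with-errors (equal priors; see module docstring)."""
    n = n_major + n_minor
    if n <= 0:
        raise ValueError("major + minor counts must be positive")
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0,1)")
    e = error_rate
    l0 = n_major * math.log(1.0 - e) + (n_minor * math.log(e / 3.0) if n_minor else 0.0)
    l1 = n * math.log((1.0 - e) / 2.0 + e / 6.0)
    d = l0 - l1
    if d > 40.0:
        return math.exp(-d)  # 1/(1+exp(d)) to within exp(-2d)
    return 1.0 / (1.0 + math.exp(d))


def sample_status(
    col: PileupColumn,
    major: str,
    minor: Optional[str],
    params: SnpFilterParams = None,
    panel: GenotypePanel = None,
) -> Tuple[GenotypeSiteStatus, ...]:
    """Per-sample M/P/N status at a site given the pooled site alleles.

    ``N``: sample depth below ``min_sample_depth``.  ``P``: the sample's
    second-ranked site allele reaches ``within_minor_count`` reads and
    ``within_minor_frac`` of the sample depth.  Otherwise ``M`` with the
    sample's majority site allele.
    """
    params = params or SnpFilterParams()
    samples = panel.samples if panel is not None else tuple(col.counts)
    out = []
    for s in samples:
        counts = col.counts[s]
        depth = sum(counts.values())
        if depth < params.min_sample_depth:
            out.append(GenotypeSiteStatus(s, "N", None, depth))
            continue
        c_major = counts.get(major, 0)
        c_minor = counts.get(minor, 0) if minor is not None else 0
        if c_major >= c_minor:
            first, second, c2 = major, minor, c_minor
        else:
            first, second, c2 = minor, major, c_major
        if (
            second is not None
            and c2 >= params.within_minor_count
            and c2 >= params.within_minor_frac * depth
        ):
            out.append(GenotypeSiteStatus(s, "P", first, depth))
        else:
            out.append(GenotypeSiteStatus(s, "M", first, depth))
    return tuple(out)


def classify_code(statuses: Sequence[GenotypeSiteStatus], panel: GenotypePanel = None) -> str:
    """Concatenate status letters in panel order (e.g. ``PMM``)."""
    if panel is not None and len(statuses) != len(panel.samples):
        raise ValueError(
            f"{len(statuses)} statuses for a {len(panel.samples)}-sample panel"
        )
    return "".join(s.status for s in statuses)


def ts_tv(a: str, b: str) -> str:
    """``ts`` for A/G or C/T pairs, ``tv`` for the other four; symmetric."""
    if a == b:
        raise ValueError(f"identical alleles {a!r}")
    if a not in BASES or b not in BASES:
        raise ValueError(f"invalid bases {a!r}/{b!r}")
    return "ts" if frozenset((a, b)) in TRANSITIONS else "tv"


def _has_contrast(statuses: Sequence[GenotypeSiteStatus]) -> bool:
    """Inter-sample polymorphism: >=1 P sample, or >=2 M samples whose major
    alleles differ."""
    if any(s.status == "P" for s in statuses):
        return True
    majors = {s.major_allele for s in statuses if s.status == "M"}
    return len(majors) >= 2


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def apply_filters(
    candidates: Sequence[SnpCandidate],
    contig_lengths: Mapping[str, int],
    panel: GenotypePanel,
    params: SnpFilterParams = None,
) -> List[SnpCandidate]:
    """Apply every non-isolation filter; returns passing candidates.

    ``filters_failed`` on each candidate records every violated rule, so the
    rejected candidates remain inspectable.
    """
    params = params or SnpFilterParams()
    passing = []
    for cand in candidates:
        failed = []
        if cand.major_count < params.min_major_cov:
            failed.append("min_major_cov")
        if cand.minor_count < params.min_minor_cov:
            failed.append("min_minor_cov")
        if cand.depth_total / len(panel.samples) < params.min_avg_cov:
            failed.append("min_avg_cov")
        if cand.flank < params.min_flank:
            failed.append("min_flank")
        if cand.quality < params.min_quality:
            failed.append("min_quality")
        if not _has_contrast(cand.statuses):
            failed.append("not_inter_sample_polymorphic")
        cand.filters_failed = cand.filters_failed + [
            f for f in failed if f not in cand.filters_failed
        ]
        if not failed:
            passing.append(cand)
    return passing


def isolation_filter(
    candidates: Sequence[SnpCandidate],
    min_isolation: int = 30,
    contig_length: Optional[int] = None,
) -> List[SnpCandidate]:
    """Remove BOTH members of any same-contig pair closer than ``min_isolation``.

    Sets each candidate's ``isolation`` to the distance to its nearest other
    candidate (a lone candidate gets the contig length as sentinel).  Symmetric
    removal avoids order dependence.
    """
    cands = sorted(candidates, key=lambda c: (c.contig_id, c.pos))
    by_contig: Dict[str, List[SnpCandidate]] = {}
    for c in cands:
        by_contig.setdefault(c.contig_id, []).append(c)
    kept = []
    for cid, group in by_contig.items():
        positions = [c.pos for c in group]
        for i, c in enumerate(group):
            dists = []
            if i > 0:
                dists.append(positions[i] - positions[i - 1])
            if i < len(group) - 1:
                dists.append(positions[i + 1] - positions[i])
            if dists:
                iso = min(dists)
            else:
                iso = contig_length if contig_length is not None else None
            c.isolation = iso
            if iso is None or iso >= min_isolation:
                kept.append(c)
            else:
                if "min_isolation" not in c.filters_failed:
                    c.filters_failed.append("min_isolation")
    kept.sort(key=lambda c: (c.contig_id, c.pos))
    return kept


# ---------------------------------------------------------------------------
# End-to-end calling
# ---------------------------------------------------------------------------

def make_candidate(
    col: PileupColumn,
    contig_length: int,
    panel: GenotypePanel,
    params: SnpFilterParams = None,
) -> Optional[SnpCandidate]:
    """Assemble a SnpCandidate from a pileup column (None if monoallelic)."""
    params = params or SnpFilterParams()
    pooled, major, minor = site_allele_counts(col)
    if minor is None:
        return None
    statuses = sample_status(col, major, minor, params, panel)
    quality = polymorphism_quality(pooled[major], pooled[minor], params.error_rate)
    flank = min(col.pos, contig_length - 1 - col.pos)
    return SnpCandidate(
        contig_id=col.contig_id,
        pos=col.pos,
        allele_major=major,
        allele_minor=minor,
        per_sample_counts={s: dict(c) for s, c in col.counts.items()},
        quality=quality,
        flank=flank,
        depth_total=col.depth_total,
        statuses=statuses,
        class_code=classify_code(statuses, panel),
        tstv=ts_tv(major, minor),
    )


def call_snps(
    pileups: Mapping[str, ContigPileup],
    contigs: Sequence[Contig],
    panel: GenotypePanel,
    params: SnpFilterParams = None,
) -> List[SnpCandidate]:
    """Full cascade over all contigs.

    Candidates are the columns whose pooled top-two counts already satisfy the
    allele-count thresholds; isolation is applied over that (pre-quality) set,
    removing both members of close pairs, and the remaining filters run last.
    """
    params = params or SnpFilterParams()
    out: List[SnpCandidate] = []
    for contig in contigs:
        pl = pileups.get(contig.id)
        if pl is None:
            continue
        pooled = pl.pooled()
        srt = np.sort(pooled, axis=1)
        mask = (srt[:, -1] >= params.min_major_cov) & (srt[:, -2] >= params.min_minor_cov)
        cands = []
        for pos in np.flatnonzero(mask):
            cand = make_candidate(pl.column(int(pos)), contig.length, panel, params)
            if cand is not None:
                cands.append(cand)
        isolated = isolation_filter(cands, params.min_isolation, contig.length)
        out.extend(apply_filters(isolated, {contig.id: contig.length}, panel, params))
    out.sort(key=lambda c: (c.contig_id, c.pos))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def snp_summaries(
    snps: Sequence[SnpCandidate],
    contigs: Sequence[Contig],
    params: SnpFilterParams = None,
) -> Dict:
    """Density, per-contig counts, class-code histogram, per-sample rollup.

    Density uses the summed length of SNP-bearing contigs as denominator.  The
    per-sample rollup buckets each SNP-bearing contig, per sample, into
    M-only, P-only or M+P by the statuses of its SNPs (N statuses ignored).
    """
    lengths = {c.id: c.length for c in contigs}
    per_contig: Counter = Counter()
    class_hist: Counter = Counter()
    ts_count = tv_count = 0
    n_high_depth = 0
    high = (params or SnpFilterParams()).high_depth
    sample_letters: Dict[str, Dict[str, set]] = {}
    for s in snps:
        per_contig[s.contig_id] += 1
        class_hist[s.class_code] += 1
        if s.tstv == "ts":
            ts_count += 1
        else:
            tv_count += 1
        if s.depth_total >= high:
            n_high_depth += 1
        for st in s.statuses:
            if st.status in ("M", "P"):
                sample_letters.setdefault(st.sample, {}).setdefault(
                    s.contig_id, set()
                ).add(st.status)
    bearing = list(per_contig)
    total_kb = sum(lengths[cid] for cid in bearing) / 1000.0
    rollup: Dict[str, Dict[str, int]] = {}
    for sample, per_cid in sample_letters.items():
        buckets = {"M": 0, "P": 0, "M+P": 0}
        for letters in per_cid.values():
            if letters == {"M"}:
                buckets["M"] += 1
            elif letters == {"P"}:
                buckets["P"] += 1
            else:
                buckets["M+P"] += 1
        rollup[sample] = buckets
    n = len(snps)
    return {
        "n_snps": n,
        "ts_count": ts_count,
        "tv_count": tv_count,
        "ts_fraction": ts_count / n if n else 0.0,
        "snps_per_contig": dict(per_contig),
        "n_contigs_with_snps": len(bearing),
        "n_contigs_multi_snp": sum(1 for v in per_contig.values() if v >= 2),
        "mean_snps_per_contig": n / len(bearing) if bearing else 0.0,
        "density_per_kb": n / total_kb if total_kb else 0.0,
        "class_histogram": dict(class_hist),
        "per_sample_rollup": rollup,
        "n_high_depth": n_high_depth,
    }


def genotype_membership(
    pileups: Mapping[str, ContigPileup],
    panel: GenotypePanel,
    min_reads: int = 1,
):
    """Which samples have reads on each contig, plus Venn-cell sharing counts.

    A sample is present on a contig when at least ``min_reads`` of its counted
    bases align anywhere on it.  Returns ``(presence, sharing)`` where
    presence maps contig id -> frozenset of samples and sharing counts contigs
    per presence set; the sharing cells partition the contigs.
    """
    presence: Dict[str, frozenset] = {}
    sharing: Counter = Counter()
    for cid, pl in pileups.items():
        present = frozenset(
            s for s in panel.samples if int(pl.sample_depth(s).sum()) >= min_reads
        )
        presence[cid] = present
        sharing[tuple(sorted(present))] += 1
    return presence, sharing
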