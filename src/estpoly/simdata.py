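"""Seeded simulator: contigs, genotype haplotypes, planted truth, pileups.

Emulates the study design upstream of marker discovery: a small panel of
genotype samples of differing heterozygosity (one RIL-pool-like sample whose
reads mix two haplotypes roughly 50/50, plus inbred-like samples with a single
haplotype), contigs with planted SSR tracts across motif lengths 2-6, planted
biallelic SNPs at ~1.36 per kb, planted deletions spanning the 3-50 nt
detector bounds, and per-position read counts at 10-60x with ~0.5-1% base
error.

Reads are modeled as independent per-position base draws (pileup-level
simulation) because every downstream computation is columnar; a thin wrapper
still emits a valid SAM subset with 1-nt reads for interface testing.

Planted features are recorded in reference coordinates, so truth is exact by
construction: SSR tracts are inserted (not discovered by chance) with their
flanking bases adjusted so no chance repeat extends or displaces them, indels
are deletions in single non-reference carrier samples with generous gap-free
clearance, and SNPs keep 100 nt of contig flank and 40 nt spacing so every
planted site can satisfy the caller's flank and isolation thresholds.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .indel_polymorphism import GappedAlignment
from .io_formats import BASES, Contig, ContigPileup, GenotypePanel, atomic_open
from .ssr_miner import SsrLocus, SsrRules, canonical_motif, find_perfect_ssrs, is_primitive

_IDX = np.arange(4, dtype=np.int8)


@dataclass(frozen=True)
class SamplePlan:
    """One simulated genotype sample.

    ``heterozygosity`` is the fraction of reads drawn from the second
    haplotype: 0 for an inbred-like sample (near-zero within-sample
    polymorphism), up to 0.5 for a RIL-pool-like sample.
    """

    name: str
    heterozygosity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heterozygosity <= 0.5:
            raise ValueError("heterozygosity must be in [0, 0.5]")


DEFAULT_SAMPLES = (
    SamplePlan("RILpool", 0.5),
    SamplePlan("inbredA", 0.0),
    SamplePlan("inbredB", 0.0),
)

# Per-contig expected planted SSR tracts by motif length (trimers most common).
DEFAULT_SSR_RATES: Mapping[int, float] = {2: 0.2, 3: 0.3, 4: 0.12, 5: 0.08, 6: 0.08}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated panel.  ``seed`` is mandatory."""

    seed: int
    n_contigs: int = 100
    contig_length: int = 2000
    samples: Tuple[SamplePlan, ...] = DEFAULT_SAMPLES
    snp_rate_per_kb: float = 1.36
    #: probability a planted SNP is a transition (A<->G, C<->T); EST SNP sets
    #: show a strong transition excess, ~69% of sites
    transition_bias: float = 0.69
    indel_lengths: Tuple[int, ...] = (2, 3, 5, 9, 14, 50, 51)
    indels_per_contig: float = 1.0
    ssr_rates: Mapping[int, float] = None  # type: ignore[assignment]
    ssr_indel_fraction: float = 0.35
    depth: float = 40.0
    error_rate: float = 0.005
    base_quality: int = 30
    min_snp_spacing: int = 40
    snp_margin: int = 100
    indel_margin: int = 30
    rules: SsrRules = field(default_factory=SsrRules)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        object.__setattr__(self, "samples", tuple(self.samples))
        rates = dict(DEFAULT_SSR_RATES if self.ssr_rates is None else self.ssr_rates)
        object.__setattr__(self, "ssr_rates", rates)
        if self.n_contigs <= 0 or self.contig_length <= 0:
            raise ValueError("n_contigs and contig_length must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0,1)")
        if any(r < 0 for r in rates.values()) or self.snp_rate_per_kb < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.transition_bias <= 1.0:
            raise ValueError("transition_bias must be in [0,1]")
        if len(self.samples) < 2:
            raise ValueError("need at least 2 samples")

    @property
    def panel(self) -> GenotypePanel:
        return GenotypePanel(tuple(s.name for s in self.samples))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "samples" in doc:
            doc["samples"] = tuple(
                SamplePlan(d["name"], float(d.get("heterozygosity", 0.0)))
                for d in doc["samples"]
            )
        for key in ("indel_lengths",):
            if key in doc:
                doc[key] = tuple(int(x) for x in doc[key])
        if "ssr_rates" in doc:
            doc["ssr_rates"] = {int(k): float(v) for k, v in doc["ssr_rates"].items()}
        return cls(**doc)


@dataclass(frozen=True)
class TruthSnp:
    contig_id: str
    pos: int  # 0-based reference coordinate
    ref: str
    alt: str
    #: per-sample genotype in panel order: (allele1, allele2)
    genotypes: Tuple[Tuple[str, Tuple[str, str]], ...]


@dataclass(frozen=True)
class TruthIndel:
    contig_id: str
    start: int  # 0-based reference coordinate
    length: int
    carriers: Tuple[str, ...]
    in_ssr: bool


@dataclass
class TruthSet:
    ssrs: List[SsrLocus]
    snps: List[TruthSnp]
    indels: List[TruthIndel]


@dataclass
class SimulatedPanel:
    """Output of :func:`simulate_panel`."""

    config: SimConfig
    contigs: List[Contig]
    #: sample -> contig id -> (2, L) int8 haplotype base indices, -1 = deleted
    haplotypes: Dict[str, Dict[str, np.ndarray]]
    truth: TruthSet

    @property
    def panel(self) -> GenotypePanel:
        return self.config.panel


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[i] for i in codes)


def _random_primitive_motif(rng: np.random.Generator, k: int) -> np.ndarray:
    while True:
        m = rng.integers(0, 4, size=k, dtype=np.int8)
        word = _decode(m)
        if len(set(word)) > 1 and is_primitive(word):
            return m


def _find_slot(
    rng: np.random.Generator,
    length: int,
    span: int,
    occupied: List[Tuple[int, int]],
    lo: int,
    hi: int,
    pad: int,
    tries: int = 200,
) -> Optional[int]:
    """A start position in [lo, hi - span] whose padded interval avoids
    ``occupied``; None if no slot found."""
    if hi - span < lo:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi - span + 1))
        a, b = s - pad, s + span + pad
        if all(b <= os_ or a >= oe for os_, oe in occupied):
            return s
    return None


def _plant_ssrs(rng, seq, cid, cfg, occupied, feature_mask):
    """Insert SSR tracts by overwriting reference segments; returns truth loci."""
    L = len(seq)
    planted: List[SsrLocus] = []
    for k in sorted(cfg.ssr_rates):
        minrep = cfg.rules.min_repeats.get(k)
        if minrep is None:
            continue
        for _ in range(rng.poisson(cfg.ssr_rates[k])):
            reps = int(rng.integers(minrep, minrep + 7))
            span = reps * k
            s = _find_slot(rng, L, span, occupied, lo=40, hi=L - 40, pad=15)
            if s is None:
                continue
            motif = _random_primitive_motif(rng, k)
            tract = np.tile(motif, reps)
            seq[s : s + span] = tract
            # guard bases: break periodic extension on either side
            left_bad = int(motif[k - 1])
            seq[s - 1] = (left_bad + 1 + int(rng.integers(3))) % 4
            right_bad = int(motif[0])
            seq[s + span] = (right_bad + 1 + int(rng.integers(3))) % 4
            occupied.append((s - 15, s + span + 15))
            feature_mask[s - 1 : s + span + 1] = True
            planted.append(
                SsrLocus(cid, s, s + span, canonical_motif(_decode(motif)), reps)
            )
    return planted


def _scrub_chance_repeats(rng, seq, contig_id, cfg, planted, feature_mask, max_rounds=25):
    """Redraw non-feature flank bases until every planted tract is mined exactly.

    A chance repeat in the random flanks can, with tiny probability, overlap a
    planted tract and displace it during overlap resolution; redrawing the
    offending window keeps truth exact without touching any planted feature.
    """
    keys = {(t.start, t.end, t.motif, t.repeats) for t in planted}
    for _ in range(max_rounds):
        mined = find_perfect_ssrs(Contig(contig_id, _decode(seq)), cfg.rules)
        found = {(m.start, m.end, m.motif, m.repeats) for m in mined}
        missing = [t for t in planted if (t.start, t.end, t.motif, t.repeats) not in found]
        if not missing:
            return
        for t in missing:
            lo, hi = max(0, t.start - 20), min(len(seq), t.end + 20)
            for p in range(lo, hi):
                if not feature_mask[p]:
                    seq[p] = int(rng.integers(0, 4))
    raise RuntimeError(f"could not scrub chance repeats on {contig_id}")


def _plant_indels(rng, cid, L, cfg, planted_ssrs, occupied_indels, sample_names):
    """Choose deletion intervals (generic + inside SSR tracts); returns truth."""
    truth: List[TruthIndel] = []
    carriers_pool = sample_names[1:]  # reference-frame sample never a carrier

    # generic indels, clear of SSR tracts and each other
    avoid = [(t.start - 30, t.end + 30) for t in planted_ssrs]
    n_generic = rng.poisson(cfg.indels_per_contig)
    for _ in range(n_generic):
        ln = int(cfg.indel_lengths[rng.integers(len(cfg.indel_lengths))])
        s = _find_slot(
            rng, L, ln, avoid + occupied_indels, lo=cfg.indel_margin,
            hi=L - cfg.indel_margin, pad=35,
        )
        if s is None:
            continue
        carrier = carriers_pool[int(rng.integers(len(carriers_pool)))]
        occupied_indels.append((s - 35, s + ln + 35))
        truth.append(TruthIndel(cid, s, ln, (carrier,), in_ssr=False))

    # SSR-tract indels: delete whole motif units from a carrier's tract
    for tract in planted_ssrs:
        if rng.random() >= cfg.ssr_indel_fraction:
            continue
        k = len(tract.motif)
        reps = tract.repeats
        minrep = cfg.rules.min_repeats[k]
        feasible = [m for m in range(1, reps - minrep + 1) if 3 <= m * k <= 14]
        if not feasible:
            continue
        m = feasible[int(rng.integers(len(feasible)))]
        ln = m * k
        j = int(rng.integers(0, reps - m + 1))
        s = tract.start + j * k
        if not all(s + ln + 26 <= a or s - 26 >= b for a, b in occupied_indels):
            continue
        if s < cfg.indel_margin or s + ln > L - cfg.indel_margin:
            continue
        carrier = carriers_pool[int(rng.integers(len(carriers_pool)))]
        occupied_indels.append((s - 26, s + ln + 26))
        truth.append(TruthIndel(cid, s, ln, (carrier,), in_ssr=True))
    return truth


def _plant_snps(rng, cid, L, seq, cfg, indel_intervals):
    """Pick spaced SNP positions away from indels; assign alleles and genotypes."""
    truth: List[TruthSnp] = []
    n = rng.poisson(cfg.snp_rate_per_kb * L / 1000.0)
    chosen: List[int] = []
    for _ in range(n):
        for _try in range(60):
            p = int(rng.integers(cfg.snp_margin, L - cfg.snp_margin))
            if any(abs(p - q) < cfg.min_snp_spacing for q in chosen):
                continue
            if any(a - 5 <= p < b + 5 for a, b in indel_intervals):
                continue
            chosen.append(p)
            break
    chosen.sort()
    transition_of = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for p in chosen:
        ref_i = int(seq[p])
        ref = BASES[ref_i]
        if rng.random() < cfg.transition_bias:
            alt = transition_of[ref]
        else:
            tv = [b for b in BASES if b != ref and b != transition_of[ref]]
            alt = tv[int(rng.integers(2))]
        while True:
            genos = []
            for sp in cfg.samples:
                if rng.random() < sp.heterozygosity:
                    genos.append((sp.name, (ref, alt)))
                else:
                    allele = alt if rng.random() < 0.5 else ref
                    genos.append((sp.name, (allele, allele)))
            hom_alleles = {g[1][0] for g in genos if g[1][0] == g[1][1]}
            any_het = any(g[1][0] != g[1][1] for g in genos)
            if any_het or len(hom_alleles) >= 2:
                break
        truth.append(TruthSnp(cid, p, ref, alt, tuple(genos)))
    return truth


def simulate_panel(cfg: SimConfig) -> SimulatedPanel:
    """Generate reference contigs, per-sample haplotypes and the truth set."""
    rng = np.random.default_rng(cfg.seed)
    sample_names = tuple(s.name for s in cfg.samples)
    contigs: List[Contig] = []
    haplotypes: Dict[str, Dict[str, np.ndarray]] = {s: {} for s in sample_names}
    truth = TruthSet([], [], [])
    base_idx = {b: i for i, b in enumerate(BASES)}

    for ci in range(cfg.n_contigs):
        cid = f"contig{ci + 1:04d}"
        L = cfg.contig_length
        seq = rng.integers(0, 4, size=L, dtype=np.int8)
        occupied: List[Tuple[int, int]] = []
        feature_mask = np.zeros(L, dtype=bool)

        planted_ssrs = _plant_ssrs(rng, seq, cid, cfg, occupied, feature_mask)
        _scrub_chance_repeats(rng, seq, cid, cfg, planted_ssrs, feature_mask)

        occupied_indels: List[Tuple[int, int]] = []
        planted_indels = _plant_indels(
            rng, cid, L, cfg, planted_ssrs, occupied_indels, sample_names
        )
        indel_intervals = [(t.start, t.start + t.length) for t in planted_indels]
        planted_snps = _plant_snps(rng, cid, L, seq, cfg, indel_intervals)

        contigs.append(Contig(cid, _decode(seq)))
        truth.ssrs.extend(planted_ssrs)
        truth.indels.extend(planted_indels)
        truth.snps.extend(planted_snps)

        # build haplotypes: (2, L) base indices, -1 = deleted
        for name in sample_names:
            hap = np.vstack([seq.copy(), seq.copy()])
            haplotypes[name][cid] = hap
        for snp in planted_snps:
            for name, (a1, a2) in snp.genotypes:
                hap = haplotypes[name][cid]
                hap[0, snp.pos] = base_idx[a1]
                hap[1, snp.pos] = base_idx[a2]
        for indel in planted_indels:
            for carrier in indel.carriers:
                hap = haplotypes[carrier][cid]
                hap[:, indel.start : indel.start + indel.length] = -1

    return SimulatedPanel(cfg, contigs, haplotypes, truth)


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

def simulate_pileup(
    sim: SimulatedPanel,
    seed: Optional[int] = None,
) -> Dict[str, ContigPileup]:
    """Per position and sample: read depth ~ Poisson(cfg.depth); each read
    drawn from the sample's haplotype mix and flipped to a uniform other base
    with probability ``error_rate``.  Deleted haplotype positions contribute
    no reads."""
    cfg = sim.config
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 17])
    e = cfg.error_rate
    pileups: Dict[str, ContigPileup] = {}
    samples = tuple(s.name for s in cfg.samples)
    het = {s.name: s.heterozygosity for s in cfg.samples}

    for contig in sim.contigs:
        L = contig.length
        pl = ContigPileup(contig.id, L, samples)
        for name in samples:
            hap = sim.haplotypes[name][contig.id]
            n = rng.poisson(cfg.depth, size=L)
            n2 = rng.binomial(n, het[name])
            counts = np.zeros((L, 4), dtype=np.int64)
            for h, nh in ((0, n - n2), (1, n2)):
                bases = hap[h]
                alive = bases >= 0
                nh = np.where(alive, nh, 0)
                if e > 0:
                    err = rng.binomial(nh, e)
                else:
                    err = np.zeros(L, dtype=np.int64)
                correct = nh - err
                pos = np.arange(L)
                b = np.where(alive, bases, 0)
                np.add.at(counts, (pos, b), np.where(alive, correct, 0))
                if e > 0:
                    e1 = rng.binomial(err, 1.0 / 3.0)
                    e2 = rng.binomial(err - e1, 0.5)
                    e3 = err - e1 - e2
                    for off, cnt in ((1, e1), (2, e2), (3, e3)):
                        np.add.at(counts, (pos, (b + off) % 4), np.where(alive, cnt, 0))
            pl.counts[name] = counts.astype(np.int32)
        pileups[contig.id] = pl
    return pileups


def pileup_to_sam(
    pileups: Mapping[str, ContigPileup],
    contigs: Sequence[Contig],
    panel: GenotypePanel,
    path,
    base_quality: int = 30,
) -> None:
    """Emit the pileup as a valid SAM subset with 1-nt reads (interface
    testing on small simulations; the TSV dialect scales better)."""
    qchar = chr(33 + base_quality)
    rg_of = {}
    for rg, s in panel.read_group_map.items():
        rg_of.setdefault(s, rg)
    with atomic_open(path) as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{c.length}\n")
        for s in panel.samples:
            fh.write(f"@RG\tID:{rg_of[s]}\tSM:{s}\n")
        i = 0
        for c in contigs:
            pl = pileups.get(c.id)
            if pl is None:
                continue
            pooled = pl.pooled()
            for pos in np.flatnonzero(pooled.sum(axis=1) > 0):
                for s in panel.samples:
                    row = pl.counts[s][pos]
                    for bi in range(4):
                        for _ in range(int(row[bi])):
                            i += 1
                            fh.write(
                                f"r{i}\t0\t{c.id}\t{int(pos) + 1}\t60\t1M\t*\t0\t0\t"
                                f"{BASES[bi]}\t{qchar}\tRG:Z:{rg_of[s]}\n"
                            )


# ---------------------------------------------------------------------------
# Truth alignments
# ---------------------------------------------------------------------------

def write_gapped_truth_alignment(sim: SimulatedPanel) -> Dict[str, GappedAlignment]:
    """Per-contig gapped consensus alignments with gap columns exactly at the
    planted indels.  Rows follow panel order; each row is the sample's first
    haplotype with ``-`` at deleted positions (coordinates are known, so the
    alignment is trivially exact)."""
    out: Dict[str, GappedAlignment] = {}
    for contig in sim.contigs:
        rows = []
        for sp in sim.config.samples:
            hap = sim.haplotypes[sp.name][contig.id][0]
            row = "".join("-" if b < 0 else BASES[b] for b in hap)
            rows.append((sp.name, row))
        out[contig.id] = GappedAlignment(contig.id, tuple(rows))
    return out


# ---------------------------------------------------------------------------
# Truth serialisation (plain TSV)
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: TruthSet, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    with atomic_open(os.path.join(outdir, "truth_ssrs.tsv")) as fh:
        fh.write("#contig\tstart\tend\tmotif\trepeats\n")
        for t in truth.ssrs:
            fh.write(f"{t.contig_id}\t{t.start}\t{t.end}\t{t.motif}\t{t.repeats}\n")
    with atomic_open(os.path.join(outdir, "truth_snps.tsv")) as fh:
        fh.write("#contig\tpos\tref\talt\tgenotypes\n")
        for t in truth.snps:
            g = ";".join(f"{s}:{a1}/{a2}" for s, (a1, a2) in t.genotypes)
            fh.write(f"{t.contig_id}\t{t.pos}\t{t.ref}\t{t.alt}\t{g}\n")
    with atomic_open(os.path.join(outdir, "truth_indels.tsv")) as fh:
        fh.write("#contig\tstart\tlength\tcarriers\tin_ssr\n")
        for t in truth.indels:
            fh.write(
                f"{t.contig_id}\t{t.start}\t{t.length}\t{','.join(t.carriers)}\t"
                f"{int(t.in_ssr)}\n"
            )
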