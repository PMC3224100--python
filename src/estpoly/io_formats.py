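"""Readers, writers and pileup construction for contig marker discovery.

Coordinate conventions: everything in memory is 0-based, half-open.  VCF and
GFF3 output use their native 1-based, inclusive conventions; the shift happens
only at the file boundary.

The pileup is the central container: per contig, per genotype sample, a dense
``(length, 4)`` array of A/C/G/T read counts.  It can be built from a tagged
SAM subset (read groups identify samples) or from a plain TSV dialect so that
every downstream stage is testable without binary alignment files.
"""

from __future__ import annotations

import hashlib
import math
import os
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence

import numpy as np
import pysam
import yaml

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
VALID_CHARS = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """A consensus sequence; the coordinate frame for all loci."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected uppercase A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenotypePanel:
    """Ordered genotype samples and the read-group -> sample mapping.

    The sample order is meaningful: per-site class codes (e.g. ``PMM``)
    concatenate per-sample statuses in this order.
    """

    samples: tuple
    read_group_map: Mapping[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        if len(samples) < 2:
            raise ValueError("panel needs at least 2 samples")
        if len(set(samples)) != len(samples):
            raise ValueError("panel sample ids must be unique")
        rg = self.read_group_map
        if rg is None:
            rg = {s: s for s in samples}
        rg = dict(rg)
        unknown = set(rg.values()) - set(samples)
        if unknown:
            raise ValueError(f"read groups map to unknown samples: {sorted(unknown)}")
        object.__setattr__(self, "read_group_map", rg)

    def sample_for_read_group(self, rg: str) -> str:
        try:
            return self.read_group_map[rg]
        except KeyError:
            raise ValueError(f"unknown read group {rg!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "GenotypePanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "samples" not in doc:
            raise ValueError(f"panel config {path}: expected a mapping with 'samples'")
        return cls(tuple(doc["samples"]), doc.get("read_groups"))

    def to_yaml(self, path) -> None:
        with atomic_open(path) as fh:
            yaml.safe_dump(
                {"samples": list(self.samples), "read_groups": dict(self.read_group_map)},
                fh,
                sort_keys=False,
            )


@dataclass(frozen=True)
class PileupColumn:
    """Per-position, per-sample base counts at one contig position."""

    contig_id: str
    pos: int
    counts: Mapping[str, Mapping[str, int]]

    @property
    def depth_per_sample(self) -> Dict[str, int]:
        return {s: sum(c.values()) for s, c in self.counts.items()}

    @property
    def depth_total(self) -> int:
        return sum(self.depth_per_sample.values())

    def pooled(self) -> Dict[str, int]:
        out = {b: 0 for b in BASES}
        for c in self.counts.values():
            for b, n in c.items():
                out[b] += n
        return out


class ContigPileup:
    """Dense per-sample base counts along one contig."""

    def __init__(self, contig_id: str, length: int, samples: Sequence[str]):
        if length <= 0:
            raise ValueError("contig length must be positive")
        self.contig_id = contig_id
        self.length = length
        self.samples = tuple(samples)
        self.counts: Dict[str, np.ndarray] = {
            s: np.zeros((length, 4), dtype=np.int32) for s in self.samples
        }

    def add(self, sample: str, pos: int, base: str, n: int = 1) -> None:
        if sample not in self.counts:
            raise ValueError(f"unknown sample {sample!r}")
        if not 0 <= pos < self.length:
            raise ValueError(
                f"position {pos} outside contig {self.contig_id!r} (length {self.length})"
            )
        self.counts[sample][pos, BASE_INDEX[base]] += n

    def pooled(self) -> np.ndarray:
        out = np.zeros((self.length, 4), dtype=np.int64)
        for arr in self.counts.values():
            out += arr
        return out

    def depth_total(self) -> np.ndarray:
        return self.pooled().sum(axis=1)

    def sample_depth(self, sample: str) -> np.ndarray:
        return self.counts[sample].sum(axis=1)

    def column(self, pos: int) -> PileupColumn:
        if not 0 <= pos < self.length:
            raise ValueError(f"position {pos} outside contig {self.contig_id!r}")
        counts = {
            s: {BASES[i]: int(arr[pos, i]) for i in range(4)}
            for s, arr in self.counts.items()
        }
        return PileupColumn(self.contig_id, pos, counts)

    def iter_columns(self) -> Iterator[PileupColumn]:
        """Yield a column for every position covered by at least one counted base."""
        covered = np.flatnonzero(self.depth_total() > 0)
        for pos in covered:
            yield self.column(int(pos))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[Contig]:
    """Read contigs from FASTA, uppercasing sequences.

    Rejects duplicate ids, empty sequences, characters outside A/C/G/T/N and
    sequence data appearing before the first header (with the line number).
    """
    contigs: List[Contig] = []
    seen = set()
    cur_id = None
    cur_parts: List[str] = []
    cur_line = 0

    def flush():
        if cur_id is None:
            return
        seq = "".join(cur_parts)
        if not seq:
            raise ValueError(f"{path}: record {cur_id!r} (line {cur_line}) has an empty sequence")
        contigs.append(Contig(cur_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                cur_line = lineno
                if not cur_id:
                    raise ValueError(f"{path}: line {lineno}: header without an id")
                if cur_id in seen:
                    raise ValueError(f"{path}: line {lineno}: duplicate contig id {cur_id!r}")
                seen.add(cur_id)
                cur_parts = []
            else:
                if cur_id is None:
                    raise ValueError(f"{path}: line {lineno}: sequence before first FASTA header")
                chunk = line.upper()
                bad = set(chunk) - VALID_CHARS
                if bad:
                    raise ValueError(
                        f"{path}: line {lineno}: invalid characters {sorted(bad)!r} in {cur_id!r}"
                    )
                cur_parts.append(chunk)
        flush()
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path, width: int = 70) -> None:
    with atomic_open(path) as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pileup construction
# ---------------------------------------------------------------------------

def build_pileup(
    sam_path,
    panel: GenotypePanel,
    min_base_quality: int = 20,
) -> Dict[str, ContigPileup]:
    """Build per-contig pileups from a tagged SAM subset.

    Only aligned (matched) bases contribute; bases below ``min_base_quality``
    and N bases are excluded from counts and depth.  Reads whose alignments
    contain indels contribute only their matched bases: indels are never
    called from reads here (they come from consensus alignments).
    """
    pileups: Dict[str, ContigPileup] = {}
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=True) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for read in sam:
            if read.is_unmapped:
                continue
            if not read.has_tag("RG"):
                raise ValueError(f"read {read.query_name!r} has no RG tag")
            sample = panel.sample_for_read_group(read.get_tag("RG"))
            ref = read.reference_name
            length = lengths[ref]
            if read.reference_end is not None and read.reference_end > length:
                raise ValueError(
                    f"read {read.query_name!r} extends beyond contig {ref!r} end"
                )
            if ref not in pileups:
                pileups[ref] = ContigPileup(ref, length, panel.samples)
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in BASE_INDEX:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                pileups[ref].add(sample, rpos, base)
    return pileups


def read_tsv_pileup(
    path,
    panel: GenotypePanel,
    contig_lengths: Mapping[str, int],
) -> Dict[str, ContigPileup]:
    """Read the TSV pileup dialect.

    Columns: contig, pos (1-based), sample, countA, countC, countG, countT.
    Defined bit-exact so tests need no binary alignment files.
    """
    pileups: Dict[str, ContigPileup] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            cid, pos1, sample = parts[0], int(parts[1]), parts[2]
            if sample not in panel.samples:
                raise ValueError(f"{path}: line {lineno}: unknown sample {sample!r}")
            if cid not in contig_lengths:
                raise ValueError(f"{path}: line {lineno}: unknown contig {cid!r}")
            length = contig_lengths[cid]
            pos = pos1 - 1
            if not 0 <= pos < length:
                raise ValueError(f"{path}: line {lineno}: position outside contig {cid!r}")
            if cid not in pileups:
                pileups[cid] = ContigPileup(cid, length, panel.samples)
            for i, nstr in enumerate(parts[3:7]):
                n = int(nstr)
                if n < 0:
                    raise ValueError(f"{path}: line {lineno}: negative count")
                if n:
                    pileups[cid].counts[sample][pos, i] += n
    return pileups


def write_tsv_pileup(pileups: Mapping[str, ContigPileup], path) -> None:
    with atomic_open(path) as fh:
        fh.write("#contig\tpos\tsample\tcountA\tcountC\tcountG\tcountT\n")
        for cid in sorted(pileups):
            pl = pileups[cid]
            for sample in pl.samples:
                arr = pl.counts[sample]
                covered = np.flatnonzero(arr.sum(axis=1) > 0)
                for pos in covered:
                    a, c, g, t = (int(x) for x in arr[pos])
                    fh.write(f"{cid}\t{pos + 1}\t{sample}\t{a}\t{c}\t{g}\t{t}\n")


# ---------------------------------------------------------------------------
# VCF / GFF3 output
# ---------------------------------------------------------------------------

def _phred(quality) -> str:
    if quality is None:
        return "."
    q = min(max(quality, 0.0), 1.0)
    return f"{min(999.0, -10.0 * math.log10(max(1.0 - q, 1e-100))):.2f}"


def write_snp_vcf(snps, contigs: Sequence[Contig], panel: GenotypePanel, path,
                  extra_header_lines: Sequence[str] = ()) -> None:
    """Write SNP candidates as VCF v4.2.

    REF is the panel-majority (pooled major) allele: for de-novo EST contigs
    there is no external reference genome, so the contig consensus frame and
    the pooled major allele define REF.  INFO carries TSTV, CLASS, FLANK, ISO
    and total depth; per-sample depths go in the DP FORMAT field.
    """
    lengths = {c.id: c.length for c in contigs}
    order = {c.id: i for i, c in enumerate(contigs)}
    for s in snps:
        if s.contig_id not in lengths:
            raise ValueError(f"SNP on unknown contig {s.contig_id!r}")
        if not 0 <= s.pos < lengths[s.contig_id]:
            raise ValueError(
                f"SNP position {s.pos} outside contig {s.contig_id!r}"
            )
    rows = sorted(snps, key=lambda s: (order[s.contig_id], s.pos))
    with atomic_open(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        from . import __version__

        fh.write(f"##source=estpoly-{__version__}\n")
        for line in extra_header_lines:
            fh.write(f"##{line}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c.id},length={c.length}>\n")
        fh.write('##INFO=<ID=TSTV,Number=1,Type=String,Description="Transition (ts) or transversion (tv)">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Per-sample M/P/N status code in panel order">\n')
        fh.write('##INFO=<ID=FLANK,Number=1,Type=Integer,Description="Distance in nt to the nearest contig end">\n')
        fh.write('##INFO=<ID=ISO,Number=1,Type=Integer,Description="Distance in nt to the nearest other candidate on the contig">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across samples">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Per-sample read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for s in rows:
            filt = "PASS" if not s.filters_failed else ";".join(s.filters_failed)
            iso = "." if s.isolation is None else str(s.isolation)
            info = (
                f"TSTV={s.tstv};CLASS={s.class_code};FLANK={s.flank};ISO={iso};"
                f"DP={s.depth_total}"
            )
            depths = "\t".join(
                str(sum(s.per_sample_counts[smp].values())) for smp in panel.samples
            )
            fh.write(
                f"{s.contig_id}\t{s.pos + 1}\t.\t{s.allele_major}\t{s.allele_minor}\t"
                f"{_phred(s.quality)}\t{filt}\t{info}\tDP\t{depths}\n"
            )


def write_ssr_gff3(ssrs, contigs: Sequence[Contig], path,
                   extra_header_lines: Sequence[str] = ()) -> None:
    """Write SSR loci as GFF3 (type ``microsatellite``, 1-based inclusive)."""
    lengths = {c.id: c.length for c in contigs}
    order = {c.id: i for i, c in enumerate(contigs)}
    for s in ssrs:
        if s.contig_id not in lengths:
            raise ValueError(f"SSR on unknown contig {s.contig_id!r}")
        if not (0 <= s.start < s.end <= lengths[s.contig_id]):
            raise ValueError(
                f"SSR locus [{s.start},{s.end}) outside contig {s.contig_id!r}"
            )
    rows = sorted(ssrs, key=lambda s: (order[s.contig_id], s.start))
    with atomic_open(path) as fh:
        fh.write("##gff-version 3\n")
        for line in extra_header_lines:
            fh.write(f"#{line}\n")
        for c in contigs:
            fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for i, s in enumerate(rows, 1):
            attrs = [
                f"ID=ssr{i:06d}",
                f"motif={s.motif}",
                f"repeats={s.repeats}",
                f"ssr_class={s.ssr_class}",
            ]
            if s.components:
                comp = ",".join(
                    f"{m}:{r}:{st + 1}-{en}" for (m, r, st, en) in s.components
                )
                attrs.append(f"components={comp}")
            fh.write(
                f"{s.contig_id}\testpoly\tmicrosatellite\t{s.start + 1}\t{s.end}\t"
                f".\t+\t.\t{';'.join(attrs)}\n"
            )


def read_ssr_gff3(path):
    """Read back SSR loci written by :func:`write_ssr_gff3`."""
    from .ssr_miner import SsrLocus

    loci = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            cid, _, ftype, start1, end1 = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ftype != "microsatellite":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            components = None
            if "components" in attrs:
                components = tuple(
                    (m, int(r), int(span.split("-")[0]) - 1, int(span.split("-")[1]))
                    for m, r, span in (c.split(":") for c in attrs["components"].split(","))
                )
            loci.append(
                SsrLocus(
                    contig_id=cid,
                    start=int(start1) - 1,
                    end=int(end1),
                    motif=attrs["motif"],
                    repeats=int(attrs["repeats"]),
                    ssr_class=attrs["ssr_class"],
                    components=components,
                )
            )
    return loci


# ---------------------------------------------------------------------------
# Small shared helpers
# ---------------------------------------------------------------------------

@contextmanager
def atomic_open(path):
    """Write to ``path`` atomically: all-or-nothing on error."""
    tmp = os.fspath(path) + ".tmp"
    fh = open(tmp, "w")
    try:
        yield fh
        fh.close()
        os.replace(tmp, path)
    except BaseException:
        fh.close()
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
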