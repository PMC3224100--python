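"""Indel detection in per-contig multi-genotype consensus alignments.

Re-implements the polymorphic-marker rule for gapped assemblies: a gap run
carried by a proper subset of genotype rows, 3-50 nt long, with at least
25 nt of gap-free alignment on each side, is an indel candidate.  Candidates
overlapping an SSR locus are flagged as candidate polymorphic SSRs; the indel
length is then the allele-length difference between carrier and non-carrier
genotypes.

Flanks are required gap-free in ALL rows, but substitutions inside flanks are
allowed -- those are SNPs and belong to the read-level caller.  Gap runs shared
by every row would be alignment artifacts; the alignment container rejects
all-gap columns outright.

The reference frame for reported coordinates is the first row's ungapped
sequence (panel order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ssr_miner import SsrLocus

_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class GappedAlignment:
    """Equal-length gapped per-genotype consensus rows for one contig."""

    contig_id: str
    rows: Tuple[Tuple[str, str], ...]  # (sample id, gapped sequence)

    def __post_init__(self) -> None:
        rows = tuple((s, seq.upper()) for s, seq in self.rows)
        object.__setattr__(self, "rows", rows)
        if len(rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        names = [s for s, _ in rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample ids in alignment")
        ncol = len(rows[0][1])
        if ncol == 0:
            raise ValueError("alignment has zero columns")
        for s, seq in rows:
            if len(seq) != ncol:
                raise ValueError(f"row {s!r} length {len(seq)} != {ncol}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"row {s!r}: invalid characters {sorted(bad)!r}")
        gap = self._gap_matrix(rows, ncol)
        if bool(gap.all(axis=0).any()):
            raise ValueError("alignment contains an all-gap column")

    @staticmethod
    def _gap_matrix(rows, ncol) -> np.ndarray:
        mat = np.zeros((len(rows), ncol), dtype=bool)
        for i, (_s, seq) in enumerate(rows):
            mat[i] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("-")
        return mat

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def sample_ids(self) -> Tuple[str, ...]:
        return tuple(s for s, _ in self.rows)

    def gap_matrix(self) -> np.ndarray:
        return self._gap_matrix(self.rows, self.column_count)


@dataclass(frozen=True)
class IndelCandidate:
    """A gap event between genotype consensi (alignment columns, half-open)."""

    contig_id: str
    column_start: int
    column_end: int
    length: int
    carriers: Tuple[str, ...]
    left_flank: int
    right_flank: int
    #: reference-row (first row, ungapped) coordinates of the event
    ref_start: int
    ref_end: int
    ssr_overlap: Optional[SsrLocus] = None
    overlap_motif: Optional[str] = None
    in_frame: Optional[bool] = None


def read_gapped_fasta(path, contig_id: str = None) -> GappedAlignment:
    """Read an aligned FASTA (rows = per-genotype consensi) into an alignment."""
    import os

    rows: List[Tuple[str, str]] = []
    name, parts = None, []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    rows.append((name, "".join(parts)))
                name, parts = line[1:].split()[0], []
            elif name is not None:
                parts.append(line)
    if name is not None:
        rows.append((name, "".join(parts)))
    if contig_id is None:
        contig_id = os.path.basename(os.fspath(path)).split(".")[0]
    return GappedAlignment(contig_id, tuple(rows))


def write_gapped_fasta(aln: GappedAlignment, path, width: int = 70) -> None:
    from .io_formats import atomic_open

    with atomic_open(path) as fh:
        for sample, seq in aln.rows:
            fh.write(f">{sample}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_indels(
    aln: GappedAlignment,
    min_len: int = 3,
    max_len: int = 50,
    min_flank: int = 25,
) -> List[IndelCandidate]:
    """Emit every maximal gap run meeting the length and flank bounds.

    A run is one maximal interval of ``-`` in one row; runs with identical
    column spans are reported once with the carrier list.  Carriers must be a
    proper subset of rows.  Flanks count consecutive columns adjacent to the
    run that are gap-free in all rows, so two nearby gap runs reject each
    other when separated by fewer than ``min_flank`` columns.
    """
    gap = aln.gap_matrix()
    nrow, ncol = gap.shape
    anygap = gap.any(axis=0)

    # length of the gap-free column run ending at c / starting at c
    left_run = np.zeros(ncol, dtype=np.int64)
    right_run = np.zeros(ncol, dtype=np.int64)
    acc = 0
    for c in range(ncol):
        acc = 0 if anygap[c] else acc + 1
        left_run[c] = acc
    acc = 0
    for c in range(ncol - 1, -1, -1):
        acc = 0 if anygap[c] else acc + 1
        right_run[c] = acc

    # ungapped reference-row position before each column
    ref_before = np.concatenate(([0], np.cumsum(~gap[0])))

    runs: Dict[Tuple[int, int], List[str]] = {}
    for i, (sample, _seq) in enumerate(aln.rows):
        row = gap[i].astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row, [0]))))
        for s, e in zip(edges[0::2], edges[1::2]):
            runs.setdefault((int(s), int(e)), []).append(sample)

    out: List[IndelCandidate] = []
    for (s, e), carriers in sorted(runs.items()):
        if len(carriers) == nrow:
            continue  # shared by all rows: alignment artifact, not an indel
        length = e - s
        if not min_len <= length <= max_len:
            continue
        lf = int(left_run[s - 1]) if s > 0 else 0
        rf = int(right_run[e]) if e < ncol else 0
        if lf < min_flank or rf < min_flank:
            continue
        out.append(
            IndelCandidate(
                contig_id=aln.contig_id,
                column_start=s,
                column_end=e,
                length=length,
                carriers=tuple(carriers),
                left_flank=lf,
                right_flank=rf,
                ref_start=int(ref_before[s]),
                ref_end=int(ref_before[e]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# SSR overlap annotation
# ---------------------------------------------------------------------------

def _overlap_nt(indel: IndelCandidate, start: int, end: int) -> int:
    """Overlap between an indel's reference span and [start, end).

    A zero-length reference span (gap in the reference row) is treated as an
    insertion point covering one position.
    """
    a, b = indel.ref_start, max(indel.ref_end, indel.ref_start + 1)
    return max(0, min(b, end) - max(a, start))


def annotate_ssr_overlap(
    indels: Sequence[IndelCandidate],
    ssrs: Sequence[SsrLocus],
) -> List[IndelCandidate]:
    """Attach the best-overlapping SSR locus (if any) to each indel.

    ``in_frame`` is true when the indel length is a whole number of motif
    units of the overlapping repeat (for compound loci, of the component with
    the largest overlap).
    """
    out: List[IndelCandidate] = []
    for indel in indels:
        best, best_ov, best_motif = None, 0, None
        for ssr in ssrs:
            if ssr.contig_id != indel.contig_id:
                raise ValueError(
                    f"contig mismatch: indel on {indel.contig_id!r}, "
                    f"SSR on {ssr.contig_id!r}"
                )
            ov = _overlap_nt(indel, ssr.start, ssr.end)
            if ov > best_ov:
                best, best_ov = ssr, ov
                if ssr.components:
                    comp_best, comp_ov = ssr.motif, 0
                    for motif, _r, st, en in ssr.components:
                        c_ov = _overlap_nt(indel, st, en)
                        if c_ov > comp_ov:
                            comp_best, comp_ov = motif, c_ov
                    best_motif = comp_best
                else:
                    best_motif = ssr.motif
        if best is None:
            out.append(replace(indel, ssr_overlap=None, overlap_motif=None, in_frame=None))
        else:
            out.append(
                replace(
                    indel,
                    ssr_overlap=best,
                    overlap_motif=best_motif,
                    in_frame=(indel.length % len(best_motif) == 0),
                )
            )
    return out


def polymorphic_ssr_report(
    indels: Sequence[IndelCandidate],
    samples: Sequence[str],
):
    """One row per SSR-overlapping indel with per-sample allele lengths.

    The allele length is the SSR tract length in each genotype: non-carriers
    keep the full span, carriers lose the indel length.  The allele difference
    equals the indel length.  Rows sorted by contig then position.
    """
    import pandas as pd

    rows = []
    for indel in indels:
        if indel.ssr_overlap is None:
            continue
        ssr = indel.ssr_overlap
        full = ssr.length
        row = {
            "contig": indel.contig_id,
            "position": indel.ref_start + 1,  # 1-based for the report
            "motif": indel.overlap_motif,
            "ssr_start": ssr.start + 1,
            "ssr_end": ssr.end,
            "indel_length": indel.length,
            "allele_diff_nt": indel.length,
            "in_frame": bool(indel.in_frame),
            "carriers": ",".join(indel.carriers),
        }
        for s in samples:
            row[f"allele_len_{s}"] = full - indel.length if s in indel.carriers else full
        rows.append(row)
    cols = [
        "contig", "position", "motif", "ssr_start", "ssr_end",
        "indel_length", "allele_diff_nt", "in_frame", "carriers",
    ] + [f"allele_len_{s}" for s in samples]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["contig", "position"], kind="stable").reset_index(drop=True)
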