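"""Perfect-microsatellite mining and compound-repeat merging.

Detects maximal uninterrupted tandem repeats of primitive 2-6 nt motifs under
per-motif-length minimum unit counts (dinucleotides need 6 units,
trinucleotides 4, tetra- through hexanucleotides 3), then merges loci that lie
within a fixed gap (default 10 nt) of each other into compound repeats.

Motifs are reported as the lexicographically smallest rotation of their
primitive root; reverse complements are NOT folded together because transcript
strand is meaningful for ESTs (an AG repeat is not a CT repeat).
Mononucleotide runs are out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import Contig

_ACGT = frozenset("ACGT")

DEFAULT_MIN_REPEATS: Mapping[int, int] = {2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SsrRules:
    """Motif-class thresholds for the repeat search."""

    motif_lengths: FrozenSet[int] = frozenset({2, 3, 4, 5, 6})
    min_repeats: Mapping[int, int] = None  # type: ignore[assignment]
    compound_max_gap: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif_lengths", frozenset(self.motif_lengths))
        mr = dict(DEFAULT_MIN_REPEATS if self.min_repeats is None else self.min_repeats)
        missing = self.motif_lengths - set(mr)
        if missing:
            raise ValueError(f"min_repeats missing motif lengths {sorted(missing)}")
        if any(v < 2 for v in mr.values()):
            raise ValueError("all min_repeats must be >= 2")
        if any(k < 2 or k > 6 for k in self.motif_lengths):
            raise ValueError("motif lengths must be within 2..6")
        if self.compound_max_gap < 0:
            raise ValueError("compound_max_gap must be >= 0")
        object.__setattr__(self, "min_repeats", mr)

    @classmethod
    def from_yaml(cls, path) -> "SsrRules":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        if "motif_lengths" in doc:
            kwargs["motif_lengths"] = frozenset(int(k) for k in doc["motif_lengths"])
        if "min_repeats" in doc:
            kwargs["min_repeats"] = {int(k): int(v) for k, v in doc["min_repeats"].items()}
        if "compound_max_gap" in doc:
            kwargs["compound_max_gap"] = int(doc["compound_max_gap"])
        return cls(**kwargs)


@dataclass(frozen=True)
class SsrLocus:
    """A perfect or compound microsatellite locus (0-based, half-open)."""

    contig_id: str
    start: int
    end: int
    motif: str
    repeats: int
    ssr_class: str = "perfect"
    #: for compound loci: ordered (motif, repeats, start, end) per component
    components: Optional[Tuple[Tuple[str, int, int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.ssr_class not in ("perfect", "compound"):
            raise ValueError(f"invalid ssr_class {self.ssr_class!r}")
        if self.ssr_class == "perfect":
            if self.end - self.start != self.repeats * len(self.motif):
                raise ValueError(
                    f"perfect locus span {self.end - self.start} != "
                    f"{self.repeats} x {len(self.motif)}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


def default_rules() -> SsrRules:
    return SsrRules()


def min_locus_length(rules: SsrRules = None) -> int:
    """Shortest locus any motif class can emit: min over k of k*min_repeats[k].

    Under the default thresholds this is 12 nt (dinucleotide 2x6 = trimer
    3x4 = tetramer 4x3 = 12).
    """
    rules = rules or SsrRules()
    return min(k * rules.min_repeats[k] for k in rules.motif_lengths)


# ---------------------------------------------------------------------------
# Motif canonicalisation
# ---------------------------------------------------------------------------

def primitive_root(word: str) -> str:
    """Shortest word w such that ``word`` is a whole-number repetition of w."""
    n = len(word)
    for d in range(1, n + 1):
        if n % d == 0 and word == word[:d] * (n // d):
            return word[:d]
    return word  # unreachable


def is_primitive(word: str) -> bool:
    return primitive_root(word) == word


def canonical_motif(word: str) -> str:
    """Canonical form of a repeat unit: smallest rotation of the primitive root.

    Strand is preserved (no reverse-complement folding).  Words whose
    primitive root is a single base are rejected: mononucleotide repeats are
    not a supported motif class.
    """
    if not 2 <= len(word) <= 6:
        raise ValueError(f"motif length must be 2..6, got {len(word)}")
    if set(word) - _ACGT:
        raise ValueError(f"motif {word!r} contains non-ACGT characters")
    root = primitive_root(word)
    if len(root) == 1:
        raise ValueError(f"mononucleotide motifs are unsupported ({word!r})")
    return min(root[i:] + root[:i] for i in range(len(root)))


# ---------------------------------------------------------------------------
# Perfect repeat detection
# ---------------------------------------------------------------------------

def _periodic_runs(codes: np.ndarray, valid: np.ndarray, k: int):
    """Maximal runs where codes[x] == codes[x+k] with both positions valid.

    Yields (start, stop) in match-array space: the sequence segment
    [start, stop + k) is k-periodic over ACGT.
    """
    if len(codes) <= k:
        return
    ok = (codes[:-k] == codes[k:]) & valid[:-k] & valid[k:]
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.astype(np.int8), [0]))))
    for s, e in zip(edges[0::2], edges[1::2]):
        yield int(s), int(e)


def find_perfect_ssrs(contig: Contig, rules: SsrRules = None) -> List[SsrLocus]:
    """Find maximal perfect SSRs meeting per-class minimum unit counts.

    Partial trailing units are not counted; runs containing N are broken at
    the N and each fragment evaluated independently.  Overlapping candidate
    runs of different motif classes are resolved greedily: longest span first,
    ties by leftmost start, then shortest motif.
    """
    rules = rules or SsrRules()
    seq = contig.sequence
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (codes == ord("A")) | (codes == ord("C")) | (codes == ord("G")) | (codes == ord("T"))

    candidates = []  # (start, end, k, motif, repeats)
    for k in sorted(rules.motif_lengths):
        minrep = rules.min_repeats[k]
        for s, e in _periodic_runs(codes, valid, k):
            total = (e - s) + k
            repeats = total // k
            if repeats < minrep:
                continue
            word = seq[s : s + k]
            if not is_primitive(word):
                continue  # caught at its primitive-root length instead
            candidates.append((s, s + repeats * k, k, canonical_motif(word), repeats))

    # Greedy overlap resolution: longest span, then leftmost, then shortest motif.
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: List[Tuple[int, int, int, str, int]] = []
    occupied: List[Tuple[int, int]] = []
    for cand in candidates:
        s, e = cand[0], cand[1]
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        chosen.append(cand)
        occupied.append((s, e))
    chosen.sort(key=lambda c: c[0])
    return [
        SsrLocus(contig.id, s, e, motif, repeats)
        for (s, e, _k, motif, repeats) in chosen
    ]


# ---------------------------------------------------------------------------
# Compound merging
# ---------------------------------------------------------------------------

def merge_compound(ssrs: Sequence[SsrLocus], rules: SsrRules = None) -> List[SsrLocus]:
    """Merge chains of perfect loci separated by <= compound_max_gap nt.

    Input must be sorted, non-overlapping perfect loci on one contig.
    Maximal chains of two or more loci become a single compound locus spanning
    first start to last end; singleton chains pass through unchanged, so the
    perfect + compound output partitions the input chains.
    """
    rules = rules or SsrRules()
    ssrs = list(ssrs)
    if not ssrs:
        return []
    contig_ids = {s.contig_id for s in ssrs}
    if len(contig_ids) > 1:
        raise ValueError(f"loci span multiple contigs: {sorted(contig_ids)}")
    for prev, cur in zip(ssrs, ssrs[1:]):
        if cur.start < prev.start:
            raise ValueError("input loci must be sorted by start")
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping loci [{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )

    out: List[SsrLocus] = []
    chain: List[SsrLocus] = [ssrs[0]]
    for cur in ssrs[1:]:
        if cur.start - chain[-1].end <= rules.compound_max_gap:
            chain.append(cur)
        else:
            out.append(_collapse_chain(chain))
            chain = [cur]
    out.append(_collapse_chain(chain))
    return out


def _collapse_chain(chain: List[SsrLocus]) -> SsrLocus:
    if len(chain) == 1:
        return chain[0]
    components = tuple((c.motif, c.repeats, c.start, c.end) for c in chain)
    return SsrLocus(
        contig_id=chain[0].contig_id,
        start=chain[0].start,
        end=chain[-1].end,
        motif=chain[0].motif,
        repeats=sum(c.repeats for c in chain),
        ssr_class="compound",
        components=components,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def ssr_summary(ssrs: Sequence[SsrLocus], rules: SsrRules = None) -> Dict:
    """Tabulate loci: counts by motif length, repeat/length distributions."""
    rules = rules or SsrRules()
    by_motif_length: Counter = Counter()
    repeat_counts: Counter = Counter()
    lengths: Counter = Counter()
    n_perfect = n_compound = 0
    for s in ssrs:
        lengths[s.length] += 1
        if s.ssr_class == "perfect":
            n_perfect += 1
            by_motif_length[len(s.motif)] += 1
            repeat_counts[s.repeats] += 1
        else:
            n_compound += 1
            for motif, reps, _st, _en in s.components or ():
                by_motif_length[len(motif)] += 1
                repeat_counts[reps] += 1
    return {
        "total": len(ssrs),
        "n_perfect": n_perfect,
        "n_compound": n_compound,
        "by_motif_length": dict(by_motif_length),
        "repeat_counts": dict(repeat_counts),
        "length_counts": dict(lengths),
        "min_length": min(lengths) if lengths else 0,
        "max_length": max(lengths) if lengths else 0,
        "min_possible_length": min_locus_length(rules),
    }


def summary_table(summary: Dict):
    """Render an ssr_summary dict as a tidy DataFrame (one row per motif length)."""
    import pandas as pd

    rows = [
        {"motif_length": k, "n_loci": n}
        for k, n in sorted(summary["by_motif_length"].items())
    ]
    return pd.DataFrame(rows, columns=["motif_length", "n_loci"])
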