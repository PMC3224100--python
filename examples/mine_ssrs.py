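"""Mine perfect and compound microsatellites from a couple of contigs.

Builds two small contigs in memory: one with a clean (AC)7 dinucleotide
repeat, one with an (AGC)4 and an (AT)6 repeat only 8 nt apart, which the
miner merges into a compound locus because adjacent repeats separated by
10 nt or less count as one compound microsatellite.
"""

from estpoly import Contig, find_perfect_ssrs, merge_compound, ssr_summary

FLANK = "GATTCGTACGGTTAGCATCGTGACTATGCA"

contigs = [
    Contig("c1", FLANK + "AC" * 7 + FLANK),
    Contig("c2", FLANK + "AGC" * 4 + "TTGCGTTG" + "AT" * 6 + FLANK),
]

all_loci = []
for contig in contigs:
    perfect = find_perfect_ssrs(contig)
    loci = merge_compound(perfect)
    all_loci.extend(loci)
    for locus in loci:
        print(
            f"{contig.id}  [{locus.start},{locus.end})  ({locus.motif})x{locus.repeats}"
            f"  {locus.ssr_class}"
            + (
                "  components: "
                + ", ".join(f"({m})x{r}@{s}" for m, r, s, _ in locus.components)
                if locus.components
                else ""
            )
        )

summary = ssr_summary(all_loci)
print(f"\n{summary['total']} loci: {summary['n_perfect']} perfect, "
      f"{summary['n_compound']} compound")
print(f"shortest possible locus under these rules: {summary['min_possible_length']} nt")
# The compound locus on c2 spans both component repeats plus the 8-nt gap;
# coordinates are 0-based half-open, so a (AC)x7 starting at 30 ends at 44.
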