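"""Find an in-silico polymorphic SSR: an indel inside a repeat tract.

Builds a 3-genotype consensus alignment in which genotype g3 lost three AGC
units (9 nt) from a 10-unit tract.  The detector accepts the gap because it is
3-50 nt long with at least 25 gap-free columns on each side; the overlap
annotation then marks it in-frame (9 is a whole number of 3-nt units) and the
report translates it into per-genotype allele lengths.
"""

from estpoly import Contig, find_perfect_ssrs
from estpoly.indel_polymorphism import (
    GappedAlignment,
    annotate_ssr_overlap,
    detect_indels,
    polymorphic_ssr_report,
)

FLANK_L = "GATTCGTACGGTTAGCATCGTGACTATGCA"
FLANK_R = "TGCATCAGGATCCATACGTCAGGTTACGGA"

tract = "AGC" * 10
reference = FLANK_L + tract + FLANK_R
aln = GappedAlignment(
    "c1",
    (
        ("g1", reference),
        ("g2", reference),
        ("g3", FLANK_L + "AGC" * 7 + "-" * 9 + FLANK_R),
    ),
)

ssrs = find_perfect_ssrs(Contig("c1", reference))
indels = annotate_ssr_overlap(detect_indels(aln), ssrs)
report = polymorphic_ssr_report(indels, ["g1", "g2", "g3"])
print(report.to_string(index=False))
# allele_diff_nt is the indel length (9 nt); g3's allele is 9 nt shorter than
# the 30-nt tract carried by g1/g2, and in_frame=True says the difference is a
# whole number of motif units -- the classic genotyping-friendly SSR allele.
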