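# Methods

This note records the models and procedures `estpoly` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one reasonable reading
existed.

## Coordinate conventions

All in-memory coordinates are 0-based half-open; VCF and GFF3 writers shift to
their native 1-based conventions at the file boundary, and tests verify that
parsed coordinates map back exactly. Sample order in a `GenotypePanel` is
semantic: per-site class codes concatenate per-sample statuses in that order.

## SSR mining

A perfect locus is a maximal run of a *primitive* motif (a unit that is not
itself a repetition of a shorter word) of length k ∈ {2..6}, with at least
min_repeats[k] complete units: 6 for dinucleotides, 4 for trinucleotides, 3
for tetra/penta/hexanucleotides. Partial trailing units are excluded from the
span, so span = repeats × k always. Runs are broken at N and each fragment
evaluated independently. Consequences worth noting:

* the shortest attainable locus is min_k k·min_repeats[k] = 12 nt;
* mononucleotide runs are out of scope by construction (a period-1 root is
  rejected during canonicalisation);
* motifs are normalised to the smallest rotation of the primitive root, and
  reverse complements are *not* folded together — transcript strand carries
  meaning for ESTs, and grouping AG with CT is left to downstream reporting.

Where candidate runs of different motif lengths overlap (rare, e.g. a
dinucleotide run embedded in a longer context), resolution is deterministic:
longest span wins, ties go to the leftmost start, then the shortest motif.
The scanner is validated by exact locus-set equality against an exhaustive
brute-force oracle (every start × motif-length × repeat-count combination by
plain substring comparison) on 1,000 seeded random 1-kb sequences.

Adjacent loci with an inter-locus gap ≤ 10 nt (inclusive) merge into compound
loci; merging is idempotent and chains partition the input. For a compound
locus the `motif`/`repeats` fields hold the first component's motif and the
summed unit count — per-component detail lives in `components`. Interrupted
repeats are not modelled as single loci; they surface only through compound
merging.

## Indel detection in consensus alignments

Input is one gapped alignment per contig whose rows are per-genotype consensi
(alphabet `ACGTN-`, equal lengths, no all-gap columns). A candidate is a
maximal gap run present in a proper subset of rows, with length in [3, 50] and
at least 25 gap-free columns — gap-free in *all* rows — immediately on each
side. Decisions behind that reading:

* "flanking sequence" is interpreted as gap-free, not identical: substitutions
  in flanks are SNPs and belong to the read-level caller, and requiring
  identity would silently couple the two detectors;
* two distinct gap runs closer than 25 columns reject each other (each breaks
  the other's flank) — conservative and order-independent;
* a run shared by every row would be an alignment artifact; the container
  forbids the all-gap columns that would produce one;
* identical column spans in several rows are reported once with the carrier
  list.

Reported coordinates are in the first row's ungapped frame (the panel's first
sample). A gap in that reference row projects to a zero-length span and is
treated as a one-position insertion point for overlap purposes. An indel
overlapping an SSR locus by ≥ 1 nt becomes a candidate polymorphic SSR;
`in_frame` records whether the length is a whole number of motif units (for
compound loci, of the best-overlapping component). All candidates are
reported with the flag rather than filtered on it — whether genotyping-grade
polymorphic SSRs should be restricted to in-frame differences is a downstream
choice.

## SNP calling

Pileups tally A/C/G/T per position per sample; bases below Q20 (configurable
— upstream aligner filtering conventions vary and none is canonical here), N
bases and deleted positions never count. Reads with indel-containing
alignments contribute matched bases only: indels are called from consensus
alignments, not from reads.

Site alleles are the top two pooled counts, ties alphabetical, giving
deterministic output for fixed input. The cascade then requires:

| filter | default | meaning |
|---|---|---|
| min_major_cov | 10 | pooled reads on the major allele |
| min_minor_cov | 10 | pooled reads on the minor allele |
| min_avg_cov | 10 | total site depth ÷ panel size |
| min_flank | 100 nt | distance to the nearer contig end |
| min_quality | 0.99 | polymorphism posterior (below) |
| min_isolation | 30 nt | distance to the nearest other candidate |
| contrast | — | ≥ 1 P sample, or ≥ 2 M samples with different majors |

"Average coverage" is defined as total site depth divided by panel size; a
separate report counter flags sites at ≥ 20× total depth, the conventional
high-confidence cut, without coupling it to the threshold. Isolation is
computed over the candidates that already passed the allele-count filters
(pre-quality) and removes *both* members of any pair closer than 30 nt;
symmetric removal avoids order dependence, and the surviving set provably has
pairwise distances ≥ 30 (asserted on every test run). A lone candidate's
isolation field carries the contig length as sentinel.

The quality model is a two-hypothesis Bayesian posterior on the top-two
counts with equal priors — H₀: monomorphic, each specific alternative base an
error at rate e/3 (default e = 0.01); H₁: balanced biallelic, each read
major/minor with probability (1−e)/2 + e/6. Binomial coefficients cancel, the
posterior is monotone in the minor count at fixed depth, and the
implementation (log-space, with an asymptotic branch beyond log-ratio 40)
matches an exact rational-arithmetic oracle to 10⁻⁹ over the full grid of
count pairs with depth ≤ 100.

Per-sample status: N below 5 reads; P when the sample's second site allele
has ≥ 4 reads *and* ≥ 20% of sample depth; else M with the sample's majority
allele. The 4-read/20% rule is this package's own (no canonical intra-sample
rule exists for pooled EST data); the defaults behave sensibly across
10–60× per-sample depth and are configurable. A site with every sample M on
the same allele is not a polymorphism and is rejected.

Summaries: ts/tv partition (transitions = A/G and C/T), SNPs per kb with the
summed length of SNP-bearing contigs as denominator (the natural denominator
for contig-anchored markers; using all contigs would deflate density by the
fraction of unpolymorphic contigs), per-contig counts, class-code histogram,
and a per-sample rollup bucketing each SNP-bearing contig into M-only, P-only
or M+P. Genotype membership (which samples have reads on which contig) is
tabulated as Venn cells that partition the contigs.

## Synthetic data

The generator emulates the study design upstream of marker discovery: by
default 100 contigs × 2 kb; a 3-sample panel of one RIL-pool-like sample
(reads drawn 50/50 from two haplotypes) and two inbred-like samples (single
haplotype); SNPs planted at 1.36/kb with a 69% transition bias (the excess
observed in EST SNP sets), 100-nt edge margins and 40-nt spacing; deletions of
{2, 3, 5, 9, 14, 50, 51} nt — deliberately straddling the 3–50 detector
bounds — in single non-reference carrier samples with ≥ 25 nt of gap-free
clearance guaranteed; SSR tracts at per-motif-length rates with trimers most
common; read depth Poisson(40) per sample per position with 0.5% uniform base
error at constant Q30.

Reads are independent per-position base draws, not full-length reads: all
downstream computation is columnar, so read length adds nothing to what the
tests can show; a wrapper emits an equivalent 1-nt-read SAM subset to
exercise the SAM interface. Truth is exact by construction: tracts are
inserted (not discovered), the two bases adjacent to each tract are set to
break periodic extension, and a per-contig QA pass redraws flank bases in the
rare case (~10⁻⁴ per tract) where a chance repeat in the random flank would
displace a planted locus. Planted indels appear as gap columns at known
coordinates, so the "alignment" needs no aligner and is exact.

What this does *not* emulate — and therefore what passing tests do not show
about real data: assembly and alignment error, chimeric contigs, coverage
that tracks expression level, position- and context-dependent sequencing
error, quality-score decay, duplicate reads, and indel alignment ambiguity in
real multiple alignments. The closed loop validates the detectors against
their stated rules, not the rules against biology.

Evaluation counts a planted SNP toward the recall denominator only when its
*observed* pileup satisfies every threshold (a site whose minor allele was
starved by sampling cannot be expected from any caller); eligibility is
recomputed from counts through the public site-level ops, while the quality
model itself is checked against the independent exact-arithmetic oracle.
Isolation eligibility follows from the generator's 40-nt spacing rather than
being re-derived.

## Problem sizes and numerics

The test suite and the acceptance script run the full study-scale panel
(100 × 2 kb, ≈ 270 planted SNPs) — generation, pileup simulation and calling
complete in a few seconds — plus a 1,000 × 1 kb oracle sweep for the SSR
scanner and the exhaustive depth-≤100 quality grid. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configuration yields byte-identical FASTA/pileup/truth files. Tie-breaks are
alphabetical everywhere an order is needed, and report writers omit
timestamps so repeated runs produce identical bodies.

## Known limitations

* Imperfect/interrupted SSRs are only visible as compound chains.
* The caller is strictly biallelic at a site; tri-allelic sites keep their
  third allele in depth but never as an allele.
* No genotype likelihoods or phasing: per-sample status is a threshold rule,
  appropriate for panel *discovery* rather than genotyping.
* Indels are detected between consensi only; read-level indel evidence is out
  of scope.
* The polymorphism posterior assumes a balanced 50/50 alternative; strongly
  unbalanced pools (allele fraction far from 0.5) lose power against H₀.
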