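# estpoly

Marker discovery from multi-genotype EST/transcriptome assemblies: perfect and
compound **SSR** (microsatellite) mining, **indel / polymorphic-SSR** detection
from gapped consensus alignments, and stringent **multi-sample SNP calling**
from read pileups — plus a seeded synthetic-data generator so every stage can
be validated against planted truth without external data.

## The problem

De-novo transcriptome assemblies built from several genetic backgrounds (for
example inbred lines plus a pooled cross of recombinant inbred lines) are a
rich substrate for co-dominant markers, but have no reference genome: the
assembled contig consensus is the only coordinate frame, coverage is uneven,
and within-sample heterozygosity differs drastically between an inbred line
and a RIL pool. `estpoly` implements the marker-discovery computations for
this setting as a reusable, testable library for anyone developing SSR/SNP
panels from pooled transcriptome sequencing.

## Methods in brief

**SSR mining.** A locus is a maximal uninterrupted run of a primitive 2–6 nt
motif with at least n_k full units, where n₂ = 6, n₃ = 4 and n₄ = n₅ = n₆ = 3
(so the shortest attainable locus is 12 nt). Motifs are reported as the
lexicographically smallest rotation of their primitive root; strand is
preserved. Adjacent loci ≤ 10 nt apart merge into *compound* repeats.

**Indels / polymorphic SSRs.** In a per-contig gapped alignment of genotype
consensi, a maximal gap run carried by a proper subset of rows is an indel
candidate when its length ℓ satisfies 3 ≤ ℓ ≤ 50 and ≥ 25 gap-free columns
flank it on each side. Candidates overlapping an SSR tract are candidate
polymorphic SSRs; ℓ is then the allele-length difference, flagged in-frame
when ℓ is a whole number of motif units.

**SNP calling.** Per site, reads are pooled across samples and the top-two
alleles taken (ties alphabetical). A site passes when pooled major ≥ 10 and
minor ≥ 10 reads, mean per-sample depth ≥ 10, distance to either contig end
≥ 100 nt, the polymorphism posterior ≥ 0.99, inter-sample contrast exists, and
no other candidate lies within 30 nt (both members of a close pair are
dropped). The posterior contrasts H₀ (monomorphic; a specific alternative
base arises at rate e/3 per read) with H₁ (balanced biallelic; each read shows
either allele with probability (1−e)/2 + e/6) at equal priors:

    P(biallelic | n_maj, n_min) = L1 / (L0 + L1),
    L0 = (1−e)^n_maj (e/3)^n_min,   L1 = ((1−e)/2 + e/6)^(n_maj+n_min)

Each genotype sample is classed **P** (both alleles within the sample: second
allele ≥ 4 reads and ≥ 20% of sample depth), **M** (monomorphic within, depth
≥ 5) or **N** (under-covered); concatenating letters in panel order yields
class codes such as `PMM` — pool heterozygous, both inbreds fixed. Sites are
also split into transitions (A/G, C/T) and transversions, and summarised as
SNPs per kb of SNP-bearing contig.

## Worked example

```bash
python examples/call_snps.py
```

prints, for a seeded 10-contig panel (one RIL-pool-like sample, two inbreds,
40× depth, 0.5% base error):

```
panel: RILpool, inbredA, inbredB
called 33 SNPs on 10 contigs (1.65 per kb)
transitions: 23  transversions: 10
class codes (panel order):
  PMM: 21
  MMM: 12
recall vs planted truth: 1.000, precision: 1.000
```

`PMM` sites are heterozygous in the pool and fixed in the inbreds — the
contrast a wild × cultivated cross produces; `MMM` sites are fixed differences
among lines. Every called site was planted by the simulator and every
eligible planted site was recovered. See `examples/` for SSR mining, the
polymorphic-SSR report and the simulator itself.

The same stages are available from the shell:

```bash
estpoly simulate --seed 7 --outdir sim/
estpoly ssr --fasta sim/contigs.fa --gff3 sim/ssr.gff3 --tsv sim/ssr_summary.tsv
estpoly polyssr --aln sim/aln --ssr-gff3 sim/ssr.gff3 --out sim/polyssr.tsv
estpoly snp --fasta sim/contigs.fa --pileup-tsv sim/pileup.tsv \
            --panel sim/panel.yml --vcf sim/snp.vcf --summary sim/snp_summary.tsv
estpoly run --config sim.yml --outdir out/   # all of the above in order
```

Inputs are plain FASTA, a read-group-tagged SAM subset or a TSV pileup
dialect, aligned FASTA for consensus alignments, and YAML for panel/rule
configuration; outputs are VCF v4.2, GFF3 and TSV reports.

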