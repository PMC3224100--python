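"""Generate a synthetic genotype panel and inspect the planted truth.

Everything derives from the seed: rerunning with the same SimConfig gives
byte-identical contigs, pileups and truth tables, which is what lets every
detector be validated against planted features.
"""

from collections import Counter

from estpoly import SimConfig, simulate_panel, simulate_pileup

cfg = SimConfig(seed=11, n_contigs=20)
sim = simulate_panel(cfg)
pileups = simulate_pileup(sim)

print(f"{len(sim.contigs)} contigs x {cfg.contig_length} nt")
print(f"planted SSR tracts: {len(sim.truth.ssrs)} "
      f"(by motif length: {dict(Counter(len(t.motif) for t in sim.truth.ssrs))})")
print(f"planted SNPs: {len(sim.truth.snps)} "
      f"(~{1000 * len(sim.truth.snps) / (len(sim.contigs) * cfg.contig_length):.2f} per kb)")
print(f"planted indels: {len(sim.truth.indels)} "
      f"(lengths: {sorted(set(t.length for t in sim.truth.indels))})")

depth = pileups[sim.contigs[0].id].depth_total()
print(f"mean total depth on contig 1: {depth.mean():.1f}x "
      f"(3 samples x {cfg.depth:.0f}x nominal)")

again = simulate_panel(cfg)
print("deterministic:", all(a.sequence == b.sequence
                            for a, b in zip(sim.contigs, again.contigs)))
# Indel lengths deliberately include 2 and 51 nt: just outside the 3-50 nt
# detector bounds, so the closed-loop tests can prove the boundaries hold.
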