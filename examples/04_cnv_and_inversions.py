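"""Intrachromosomal variants: coverage CNV segmentation, inversions,
deletions against a reference map.
"""
import hickar as hk
from hickar.edits import DerivativeKaryotype
from hickar.genome import Chromosome, GenomeModel

genome = GenomeModel((Chromosome("A", 40_000_000), Chromosome("B", 30_000_000)))
sim = lambda edits, seed: hk.simulate_map(
    hk.apply_edits(genome, edits) if edits else DerivativeKaryotype.identity(genome),
    hk.SimulationParams(bin_size=100_000, total_contacts=2e7, seed=seed),
)
reference = sim([], 50)

# heterozygous deletion -> coverage halves over the interval
m = sim([hk.KaryotypeEdit("deletion", "A", 10_000_000, 14_000_000)], 1)
for c in hk.cnv_segments(hk.coverage_track(m, normalized=True)):
    print(f"CNV {c.chrom}:{c.interval[0]:,}-{c.interval[1]:,} "
          f"log2={c.log2_ratio:.2f} {c.state}")

# homozygous inversion -> butterfly of enriched corners vs the reference
inv = [hk.KaryotypeEdit("inversion", "A", 15_000_000, 20_000_000,
                        affected_haplotype=h) for h in (0, 1)]
for c in hk.detect_inversion(sim(inv, 2), reference, "A"):
    print(f"inversion A:{c.donor_segment[0]:,}-{c.donor_segment[1]:,} "
          f"score={c.score:.2f}")

# homozygous deletion seen in the contact pattern: the flanks become
# adjacent, bridging the gap with enriched contacts
dele = [hk.KaryotypeEdit("deletion", "A", 25_000_000, 27_000_000,
                         affected_haplotype=h) for h in (0, 1)]
for c in hk.detect_cis_deletion(sim(dele, 3), reference, "A"):
    print(f"deletion A:{c.donor_segment[0]:,}-{c.donor_segment[1]:,} "
          f"({c.classification}) bridge={c.score:.2f}")
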