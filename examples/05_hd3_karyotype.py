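"""Reproduce the HD3-style genome-wide karyotype screen at desk scale.

Plants all 26 published interchromosomal translocations of the chicken HD3
cell line on a GalGal5-magnitude genome, simulates a deep 250 kb map, detects
the events, and estimates the chromosome number.  Takes a few minutes.
"""
import hickar as hk
from hickar import studies
from hickar.assembly import build_breakpoint_graph, reconstruct_derivatives, \
    estimate_chromosome_count
from hickar.qc import coverage_track

n_calls, calls = studies.hd3_translocation_count(seed=0)
print(f"detected {n_calls} interchromosomal events "
      f"(26 were planted from the published table)\n")
for c in sorted(calls, key=lambda c: (c.donor_chrom.zfill(2), c.donor_segment)):
    ins = c.acceptor_insertion
    site = ins if isinstance(ins, str) else f"{ins:,}"
    print(f"  t({c.donor_chrom};{c.acceptor_chrom})  "
          f"{c.donor_segment[0]:,}-{c.donor_segment[1]:,} -> {site}  "
          f"[{c.classification}]")

graph = build_breakpoint_graph(calls, studies.hd3_genome())
recon = reconstruct_derivatives(graph)
print(f"\n{len(recon)} candidate derivative chromosomes (ranked by evidence)")
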