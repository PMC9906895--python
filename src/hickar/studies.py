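"""Desk-scale reproduction studies of the HD3 karyotype analysis.

Each function builds the synthetic condition from the published coordinates
(:mod:`hickar.hd3`), runs the detector, and returns the measured quantity.
Simulation depths are chosen as the study's sequencing depth (~4.2e8 valid
pairs genome-wide) prorated to the simulated chromosome subset, which also
puts the fusion-adjacent expected counts above ~20 per 5 kb bin -- the regime
where breakpoints are recoverable to one bin.
"""
from __future__ import annotations

import numpy as np

from .edits import KaryotypeEdit, apply_edits
from .genome import GenomeModel, hd3_genome
from .hd3 import HD3_TRANSLOCATIONS, plant_hd3_karyotype, row_to_edit
from .simulate import SimulationParams, simulate_map
from .sv_trans import DetectionParams, SVCall, detect_translocations

FULL_DEPTH = 4.2e8  # the study's combined valid-pair count, order of magnitude


def _subset(names) -> GenomeModel:
    full = hd3_genome()
    return GenomeModel(tuple(c for c in full.chromosomes if c.name in names))


def hd3_translocation_count(seed: int = 0, bin_size: int = 250_000,
                            total_contacts: float = FULL_DEPTH
                            ) -> tuple[int, list[SVCall]]:
    """Plant all 26 tabulated interchromosomal events and count detections.

    The karyotype mixes conflict-free clone haplotypes with the wild type
    (see :func:`hickar.hd3.plant_hd3_karyotype`); detection runs genome-wide
    with the >=200 kb segment filter and default thresholds.
    """
    kt = plant_hd3_karyotype()
    params = SimulationParams(bin_size=bin_size, total_contacts=total_contacts,
                              seed=seed)
    m = simulate_map(kt, params)
    det = DetectionParams(min_segment_bp=200_000)
    calls = detect_translocations(m, params=det)
    return len(calls), calls


def t12_breakpoints(seed: int = 0, total_contacts: float = 5.0e7
                    ) -> tuple[int, int]:
    """Recover the t(1;2) donor breakpoint and acceptor insertion site.

    Simulates GGA1 + GGA2 only at 5 kb with the tabulated event (donor
    GGA1:180,580,000-194,260,000 into GGA2 q:149,470,000; moved, w = 0.5) and
    returns (donor breakpoint bp, acceptor insertion bp).
    """
    genome = _subset({"1", "2"})
    row = HD3_TRANSLOCATIONS[0]
    edit = row_to_edit(row)
    kt = apply_edits(genome, [edit])
    params = SimulationParams(bin_size=5_000, total_contacts=total_contacts,
                              seed=seed)
    m = simulate_map(kt, params)
    calls = detect_translocations(m)
    best = _pick(calls, donor="1", acceptor="2")
    return int(best.donor_breakpoint), int(best.acceptor_insertion)


def gga21_breakpoint(seed: int = 0, total_contacts: float = 2.5e7) -> int:
    """Recover the GGA21 breakpoint of the terminal-region translocation.

    Simulates GGA21 + GGA5 only at 5 kb, planting the tabulated GGA21 row
    (terminal 325 kb segment into GGA5 pter; moved, w = 0.5); returns the
    breakpoint on the GGA21 axis in bp.
    """
    genome = _subset({"21", "5"})
    row = next(r for r in HD3_TRANSLOCATIONS if r.donor == "21" and r.acceptor == "5")
    kt = apply_edits(genome, [row_to_edit(row)])
    params = SimulationParams(bin_size=5_000, total_contacts=total_contacts,
                              seed=seed)
    m = simulate_map(kt, params)
    calls = detect_translocations(m)
    best = _pick(calls, donor="21", acceptor="5")
    bp = best.donor_breakpoint
    if not isinstance(bp, (int, np.integer)):
        # terminal call: the breakpoint is the interior end of the segment
        bp = best.donor_segment[1]
    return int(bp)


def _pick(calls, donor, acceptor) -> SVCall:
    match = [c for c in calls
             if {c.donor_chrom, c.acceptor_chrom} == {donor, acceptor}]
    if not match:
        raise RuntimeError(f"no call recovered for pair ({donor}, {acceptor})")
    best = max(match, key=lambda c: c.score)
    if best.donor_chrom != donor:
        # mirrored roles: swap for reporting
        return SVCall(
            kind=best.kind,
            donor_chrom=best.acceptor_chrom,
            donor_segment=best.donor_segment,
            donor_breakpoint=best.acceptor_insertion,
            donor_orientation=best.donor_orientation,
            acceptor_chrom=best.donor_chrom,
            acceptor_insertion=best.donor_breakpoint,
            classification=best.classification,
            score=best.score,
        )
    return best
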