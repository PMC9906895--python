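import numpy as np
import pytest

import hickar as hk
from hickar.edits import DerivativeKaryotype
from hickar.genome import BinTable, Chromosome, GenomeModel
from hickar.simulate import expected_matrix
from hickar.sv_trans import DetectionParams, trans_enrichment


def simulate_edit(genome, edits, seed, contacts=3e7, bin_size=250_000, **pkw):
    kt = hk.apply_edits(genome, edits) if edits else DerivativeKaryotype.identity(genome)
    p = hk.SimulationParams(bin_size=bin_size, total_contacts=contacts, seed=seed, **pkw)
    return hk.simulate_map(kt, p)


@pytest.fixture(scope="module")
def insertion_calls(insertion_map):
    return hk.detect_translocations(insertion_map)


class TestTransEnrichment:
    def test_planted_segment_block(self, insertion_map):
        blocks = trans_enrichment(insertion_map, "chr2", "chr3")
        assert blocks
        spans = [b.intervalA for b in blocks]
        lo = min(s[0] for s in spans)
        hi = max(s[1] for s in spans)
        # enrichment confined to the planted donor segment
        assert lo >= 100_000_000 - 500_000
        assert hi <= 130_000_000 + 500_000

    def test_uninvolved_pair_empty(self, insertion_map):
        assert trans_enrichment(insertion_map, "chr1", "chr4") == []

    def test_axis_mirror_symmetry(self, insertion_map):
        fwd = trans_enrichment(insertion_map, "chr2", "chr3")
        rev = trans_enrichment(insertion_map, "chr3", "chr2")
        assert {(b.intervalA, b.intervalB) for b in fwd} == {
            (b.intervalB, b.intervalA) for b in rev
        }

    def test_z_threshold_monotonicity(self, insertion_map):
        counts = []
        for z in (4, 8, 16, 40):
            p = DetectionParams(enrichment_z_min=z)
            counts.append(len(trans_enrichment(insertion_map, "chr2", "chr3", p)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetect:
    def test_insertion_recovered_exactly(self, insertion_calls):
        assert len(insertion_calls) == 1
        c = insertion_calls[0]
        assert c.donor_chrom == "chr2"
        assert c.donor_segment == (100_000_000, 130_000_000)
        assert c.donor_breakpoint == 100_000_000
        assert c.donor_orientation == "+"
        assert c.acceptor_chrom == "chr3"
        assert c.acceptor_insertion == 50_000_000
        assert c.classification == "unbalanced"

    def test_orientation_flip_symmetry(self, toy_genome):
        e = hk.KaryotypeEdit("translocation", "chr2", 100_000_000, 130_000_000,
                             orientation="-", acceptor_chrom="chr3",
                             insertion=50_000_000)
        m = simulate_edit(toy_genome, [e], seed=2)
        calls = hk.detect_translocations(m)
        assert len(calls) == 1
        assert calls[0].donor_orientation == "-"
        assert calls[0].donor_breakpoint == 130_000_000
        assert calls[0].donor_segment == (100_000_000, 130_000_000)

    def test_reciprocal_classified_balanced(self, toy_genome):
        e = hk.KaryotypeEdit("translocation", "chr1", 120_000_000, 200_000_000,
                             acceptor_chrom="chr2", insertion=100_000_000,
                             balanced=True)
        calls = hk.detect_translocations(simulate_edit(toy_genome, [e], seed=5))
        assert len(calls) == 2
        assert all(c.classification == "balanced" for c in calls)
        bps = sorted({c.donor_breakpoint for c in calls} |
                     {c.acceptor_insertion for c in calls})
        assert any(abs(b - 120_000_000) <= 500_000 for b in bps)
        assert any(abs(b - 100_000_000) <= 500_000 for b in bps)

    def test_whole_micro_fusion_is_terminal(self, toy_genome):
        e = hk.KaryotypeEdit("translocation", "chr10", 0, 6_000_000,
                             acceptor_chrom="chr4", insertion="ter:q")
        calls = hk.detect_translocations(simulate_edit(toy_genome, [e], seed=3))
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "terminal_fusion"
        assert c.donor_chrom == "chr10"
        assert c.donor_breakpoint == "ter"
        assert c.acceptor_insertion == "ter:q"

    def test_translocated_duplication_classified(self, toy_genome):
        e = hk.KaryotypeEdit("translocation", "chr2", 130_000_000, 150_000_000,
                             acceptor_chrom="chr3", insertion="ter:q",
                             mode="duplicated")
        calls = hk.detect_translocations(simulate_edit(toy_genome, [e], seed=4))
        assert len(calls) == 1
        assert calls[0].classification == "translocated_duplication"

    def test_multiway_donor_two_calls(self, toy_genome):
        # the same donor region moves to different acceptors on the two
        # haplotypes (subclone heterogeneity)
        edits = [
            hk.KaryotypeEdit("translocation", "chr4", 10_000_000, 30_000_000,
                             acceptor_chrom="chr6", insertion="ter:q",
                             affected_haplotype=0),
            hk.KaryotypeEdit("translocation", "chr4", 10_000_000, 30_000_000,
                             acceptor_chrom="chr7", insertion="ter:q",
                             affected_haplotype=1),
        ]
        calls = hk.detect_translocations(simulate_edit(toy_genome, edits, seed=8))
        pairs = {(c.donor_chrom, c.acceptor_chrom) for c in calls}
        assert pairs == {("chr4", "chr6"), ("chr4", "chr7")}
        for c in calls:
            assert abs(c.donor_segment[0] - 10_000_000) <= 500_000

    def test_reference_veto_suppresses_shared_blocks(self, insertion_map):
        calls = hk.detect_translocations(insertion_map, reference_matrix=insertion_map)
        assert calls == []

    def test_no_call_below_min_segment(self, insertion_calls):
        p = DetectionParams()
        for c in insertion_calls:
            assert (c.donor_segment[1] - c.donor_segment[0] >= p.min_segment_bp
                    or c.block.intervalB[1] - c.block.intervalB[0] >= p.min_segment_bp)


class TestFalsePositiveControl:
    def test_identity_karyotype_yields_no_calls(self, toy_genome):
        """Zero SV calls on unrearranged maps in >= 95% of seeded runs."""
        bad = 0
        for seed in range(20):
            m = hk.simulate_map(
                toy_genome,
                hk.SimulationParams(bin_size=500_000, total_contacts=5e6, seed=seed),
            )
            params = DetectionParams(scan_bin=500_000, refine_bin=10_000,
                                     min_segment_bp=500_000)
            if hk.detect_translocations(m, params=params):
                bad += 1
        assert bad <= 1


class TestBreakpointPrecision:
    def test_recovery_within_one_bin_in_90pct_of_runs(self):
        """At fusion-adjacent depth >= 20 counts/bin, both breakpoints land
        within +-1 refine bin in at least 90% of seeded runs."""
        g = GenomeModel((Chromosome("A", 40_000_000), Chromosome("B", 30_000_000)))
        e = hk.KaryotypeEdit("translocation", "A", 20_000_000, 30_000_000,
                             acceptor_chrom="B", insertion=15_000_000)
        kt = hk.apply_edits(g, [e])
        bin_size = 20_000
        # depth chosen so the junction-adjacent expected count is >= 20
        probe = hk.SimulationParams(bin_size=bin_size, total_contacts=1.0, seed=0)
        bt = BinTable(g, bin_size)
        U = expected_matrix(kt, probe, bt)
        j_donor = bt.bin_id("A", 20_000_000)  # junction-side donor bin
        j_acc = bt.bin_id("B", 15_000_000 - bin_size)
        lam_unit = U[min(j_donor, j_acc), max(j_donor, j_acc)] / U.sum()
        contacts = 20.0 / lam_unit
        params = DetectionParams(scan_bin=200_000, refine_bin=bin_size,
                                 min_segment_bp=200_000)
        hits = 0
        runs = 10
        for seed in range(runs):
            m = hk.simulate_map(kt, hk.SimulationParams(
                bin_size=bin_size, total_contacts=contacts, seed=seed))
            calls = hk.detect_translocations(m, params=params)
            ok = any(
                abs(c.donor_segment[0] - 20_000_000) <= bin_size
                and abs(c.donor_segment[1] - 30_000_000) <= bin_size
                and abs(int(c.acceptor_insertion) - 15_000_000) <= bin_size
                for c in calls
                if isinstance(c.acceptor_insertion, (int, np.integer))
            )
            hits += ok
        assert hits >= 0.9 * runs
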