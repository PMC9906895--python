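import itertools

import numpy as np
import pytest

import hickar as hk
from hickar.edits import DerivativeKaryotype
from hickar.genome import BinTable, Chromosome, GenomeModel
from hickar.qc import CoverageTrack
from hickar.sv_cis import CNVParams, _binary_segmentation, inversion_score

G = GenomeModel((Chromosome("A", 40_000_000), Chromosome("B", 30_000_000)))


def simulate(edits, seed, **kw):
    kt = hk.apply_edits(G, edits) if edits else DerivativeKaryotype.identity(G)
    p = hk.SimulationParams(bin_size=100_000, total_contacts=2e7, seed=seed, **kw)
    return hk.simulate_map(kt, p)


@pytest.fixture(scope="module")
def reference_map():
    return simulate([], seed=50)


class TestCNVSegments:
    def test_het_deletion_boundaries(self):
        m = simulate([hk.KaryotypeEdit("deletion", "A", 10_000_000, 14_000_000)], 4)
        calls = hk.cnv_segments(hk.coverage_track(m, normalized=True))
        dels = [c for c in calls if c.state == "deletion_het"]
        assert len(dels) == 1
        assert abs(dels[0].interval[0] - 10_000_000) <= 100_000
        assert abs(dels[0].interval[1] - 14_000_000) <= 100_000
        assert dels[0].log2_ratio == pytest.approx(-1.0, abs=0.25)

    def test_terminal_amplification(self):
        edits = [
            hk.KaryotypeEdit("duplication", "B", 29_000_000, 30_000_000,
                             affected_haplotype=h)
            for h in (0, 1) for _ in range(2)
        ]
        m = simulate(edits, 5)
        calls = hk.cnv_segments(hk.coverage_track(m, normalized=True))
        amp = [c for c in calls if c.state == "amplification" and c.chrom == "B"]
        assert len(amp) == 1
        assert amp[0].interval[1] == 30_000_000
        assert abs(amp[0].interval[0] - 29_000_000) <= 200_000

    def test_flat_coverage_no_calls(self, reference_map):
        assert hk.cnv_segments(hk.coverage_track(reference_map, normalized=True)) == []

    def test_scaling_invariance(self):
        m = simulate([hk.KaryotypeEdit("deletion", "A", 10_000_000, 14_000_000)], 4)
        cov = hk.coverage_track(m, normalized=True)
        scaled = CoverageTrack(cov.bin_table, cov.values * 3.7)
        ref = CoverageTrack(cov.bin_table, np.full_like(cov.values, 3.7))
        a = hk.cnv_segments(cov)
        b = hk.cnv_segments(scaled, ref)
        assert [(c.interval, c.state) for c in a] == [(c.interval, c.state) for c in b]

    def test_segmentation_matches_exhaustive_two_changepoint_oracle(self):
        """Binary segmentation finds the exact SSE-optimal change points on
        clean step tracks of <= 30 bins (checked against enumeration)."""
        rng = np.random.default_rng(9)
        for trial in range(20):
            n = int(rng.integers(14, 31))
            c1 = int(rng.integers(2, n - 8))
            c2 = c1 + int(rng.integers(3, min(7, n - 2 - c1)))
            x = np.zeros(n)
            x[c1:c2] = rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 2.5)
            x += rng.normal(0, 0.05, n)

            def sse(bounds):
                return sum(
                    np.sum((x[a:b] - x[a:b].mean()) ** 2)
                    for a, b in zip(bounds[:-1], bounds[1:])
                )

            best = min(
                ((a, b) for a, b in itertools.combinations(range(2, n - 1), 2)
                 if b - a >= 2),
                key=lambda ab: sse([0, ab[0], ab[1], n]),
            )
            got = _binary_segmentation(x, penalty=0.5 * np.log(n), min_seg=2)
            assert tuple(got) == best, f"trial {trial}"


class TestInversions:
    @pytest.fixture(scope="class")
    def inv_maps(self, reference_map):
        hom = [hk.KaryotypeEdit("inversion", "A", 15_000_000, 20_000_000,
                                affected_haplotype=h) for h in (0, 1)]
        het = hom[:1]
        return {
            1.0: simulate(hom, 7),
            0.5: simulate(het, 9),
        }

    def test_homozygous_inversion_recovered(self, inv_maps, reference_map):
        calls = hk.detect_inversion(inv_maps[1.0], reference_map, "A")
        assert len(calls) == 1
        a, b = calls[0].donor_segment
        step = 4 * 100_000  # coarse-grid resolution, 2 grid steps tolerance
        assert abs(a - 15_000_000) <= 2 * step
        assert abs(b - 20_000_000) <= 2 * step

    def test_identity_vs_itself_empty(self, reference_map):
        assert hk.detect_inversion(reference_map, reference_map, "A") == []

    def test_score_monotone_in_mixture_weight(self, inv_maps, reference_map):
        s1 = inversion_score(inv_maps[1.0], reference_map, "A",
                             15_000_000, 20_000_000)
        s05 = inversion_score(inv_maps[0.5], reference_map, "A",
                              15_000_000, 20_000_000)
        s0 = inversion_score(reference_map, simulate([], 51), "A",
                             15_000_000, 20_000_000)
        assert s1 > s05 > s0
        assert s0 == pytest.approx(0.0, abs=0.15)

    def test_reference_required(self, reference_map):
        with pytest.raises(ValueError):
            hk.detect_inversion(reference_map, None, "A")


class TestCisDeletions:
    def test_homozygous_deletion_bridges_gap(self, reference_map):
        edits = [hk.KaryotypeEdit("deletion", "A", 10_000_000, 12_000_000,
                                  affected_haplotype=h) for h in (0, 1)]
        m = simulate(edits, 10)
        calls = hk.detect_cis_deletion(m, reference_map, "A")
        assert len(calls) == 1
        c = calls[0]
        assert c.classification == "homozygous"
        # Jaccard overlap with the planted interval
        lo = max(c.donor_segment[0], 10_000_000)
        hi = min(c.donor_segment[1], 12_000_000)
        union = max(c.donor_segment[1], 12_000_000) - min(c.donor_segment[0], 10_000_000)
        assert (hi - lo) / union > 0.8
        assert c.score > 0.5  # flanks became adjacent: bridge enrichment

    def test_het_deletion_flagged(self, reference_map):
        m = simulate([hk.KaryotypeEdit("deletion", "A", 10_000_000, 13_000_000)], 11)
        calls = hk.detect_cis_deletion(m, reference_map, "A")
        assert len(calls) == 1
        assert calls[0].classification == "heterozygous"

    def test_no_deletion_empty(self, reference_map):
        other = simulate([], 12)
        assert hk.detect_cis_deletion(other, reference_map, "A") == []
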