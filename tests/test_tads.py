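import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import hickar as hk
from hickar.edits import DerivativeKaryotype
from hickar.genome import BinTable, Chromosome, GenomeModel
from hickar.matrix import ContactMatrix
from hickar.tads import (
    Domain,
    DomainParams,
    DomainSet,
    _quality_table,
    segmentation_score,
)


def matrix_from_dense(block):
    n = len(block)
    g = GenomeModel((Chromosome("c", n * 50_000),))
    return ContactMatrix(BinTable(g, 50_000), sp.coo_matrix(np.triu(block)))


def brute_force_score(Q, min_len):
    """Exhaustive enumeration over all boundary placements of [0, n)."""
    n = Q.shape[1]
    best = 0.0
    # composition of n into blocks; each block is a domain (if it scores
    # positively and is long enough) or a gap
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [k + 1 for k in range(n - 1) if cuts[k]] + [n]
        score = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            l = hi - 1 - lo
            if hi - lo >= min_len and l < Q.shape[0]:
                q = Q[l, lo]
                if np.isfinite(q) and q > 0:
                    score += q
        best = max(best, score)
    return best


class TestDomainQuality:
    def test_constant_matrix_scores_center_to_zero(self):
        m = matrix_from_dense(np.full((30, 30), 5.0))
        for i, j in [(0, 3), (10, 15), (25, 29)]:
            assert hk.domain_quality(m, "c", i, j, 0.25) == pytest.approx(0.0, abs=1e-9)

    def test_dense_block_scores_positive(self):
        block = np.full((30, 30), 1.0)
        block[10:12, 10:12] = 50.0
        m = matrix_from_dense(block)
        assert hk.domain_quality(m, "c", 10, 11, 0.25) > 0

    def test_matches_direct_formula_on_toy(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 20, size=(6, 6)).astype(float)
        block = np.triu(raw) + np.triu(raw, 1).T
        m = matrix_from_dense(block)
        gamma = 0.3
        params = DomainParams(min_domain_bins=1, max_domain_mb=100)
        for i in range(6):
            for j in range(i, 6):
                l = j - i
                s = sum(
                    block[a, b] for a in range(i, j + 1) for b in range(a, j + 1)
                ) / (l + 1) ** gamma
                mus = [
                    sum(block[a, b] for a in range(i2, i2 + l + 1)
                        for b in range(a, i2 + l + 1)) / (l + 1) ** gamma
                    for i2 in range(6 - l)
                ]
                want = s - np.mean(mus)
                got = hk.domain_quality(m, "c", i, j, gamma, params)
                assert got == pytest.approx(want)

    def test_i_greater_than_j_rejected(self):
        m = matrix_from_dense(np.ones((25, 25)))
        with pytest.raises(ValueError):
            hk.domain_quality(m, "c", 5, 3, 0.2)


class TestSegmentation:
    def test_block_diagonal_recovery(self):
        block = np.full((20, 20), 1.0)
        block[3:8, 3:8] = 30.0
        block[12:17, 12:17] = 30.0
        m = matrix_from_dense(block)
        ds = hk.armatus_segment(m, "c", 0.25)
        assert [(d.start_bin, d.end_bin) for d in ds.domains] == [(3, 7), (12, 16)]

    def test_uniform_matrix_yields_no_domains(self):
        m = matrix_from_dense(np.full((20, 20), 2.0))
        ds = hk.armatus_segment(m, "c", 0.25)
        assert ds.domains == []

    @pytest.mark.parametrize("gamma", [0.0, 0.2, 0.3])
    def test_dp_equals_exhaustive_oracle(self, gamma):
        """DP total score equals brute-force enumeration, random matrices n<=12."""
        rng = np.random.default_rng(42)
        params = DomainParams(min_domain_bins=2, max_domain_mb=100)
        for trial in range(200):
            n = int(rng.integers(4, 13))
            raw = rng.exponential(5.0, size=(n, n))
            block = np.triu(raw) + np.triu(raw, 1).T
            m = matrix_from_dense(block)
            Q = _quality_table(m, "c", gamma, params)
            want = brute_force_score(Q, params.min_domain_bins)
            got = segmentation_score(m, "c", gamma, params)
            assert got == pytest.approx(want), f"trial {trial}, n={n}"

    def test_domains_disjoint_and_sorted(self):
        rng = np.random.default_rng(1)
        raw = rng.exponential(5.0, size=(60, 60))
        m = matrix_from_dense(np.triu(raw) + np.triu(raw, 1).T)
        ds = hk.armatus_segment(m, "c", 0.2)
        ends = -1
        for d in sorted(ds.domains, key=lambda d: d.start_bin):
            assert d.start_bin > ends
            ends = d.end_bin


class TestConsensus:
    @pytest.fixture(scope="class")
    def nested_map(self):
        g = GenomeModel((Chromosome("A", 20_000_000), Chromosome("B", 15_000_000)))
        doms = []
        for s in (0, 6_000_000, 12_000_000):
            doms.append(("A", s, s + 3_000_000, 2.0))  # strong parents
            for cs in range(s, s + 3_000_000, 1_000_000):
                doms.append(("A", cs, cs + 1_000_000, 1.0))
        p = hk.SimulationParams(bin_size=50_000, total_contacts=1.2e7, seed=3,
                                tad_domains=doms)
        return hk.simulate_map(DerivativeKaryotype.identity(g), p)

    def test_single_gamma_equals_armatus(self, nested_map):
        params = DomainParams(gamma_grid=(0.1,))
        cons = hk.consensus_domains(nested_map, "A", params)
        single = hk.armatus_segment(nested_map, "A", 0.1, params)
        assert {(d.start_bin, d.end_bin) for d in cons.domains} == {
            (d.start_bin, d.end_bin) for d in single.domains
        }

    def test_hierarchy_recovered(self, nested_map):
        params = DomainParams(gamma_grid=(0.05, 0.1))
        cons = hk.consensus_domains(nested_map, "A", params)
        parents = [d for d in cons.domains if d.n_bins == 60]
        children = [d for d in cons.domains if d.n_bins == 20]
        assert {(d.start_bin, d.end_bin) for d in parents} == {
            (0, 59), (120, 179), (240, 299)}
        assert len(children) == 9
        for c in children:  # every child sits inside a parent
            assert any(p.start_bin <= c.start_bin and c.end_bin <= p.end_bin
                       for p in parents)

    def test_gamma_order_invariance(self, nested_map):
        a = hk.consensus_domains(nested_map, "A", DomainParams(gamma_grid=(0.05, 0.1)))
        b = hk.consensus_domains(nested_map, "A", DomainParams(gamma_grid=(0.1, 0.05)))
        assert [(d.start_bin, d.end_bin) for d in a.domains] == [
            (d.start_bin, d.end_bin) for d in b.domains]


def make_set(n, doms, gammas=(0.25,)):
    return DomainSet("c", n, 50_000, [Domain(a, b, gammas[0], 1.0) for a, b in doms],
                     tuple(gammas))


class TestBoundaryOverlap:
    def test_identical_sets(self):
        d = make_set(20, [(0, 4), (5, 9)])
        assert hk.boundary_overlap(d, d) == 1.0

    def test_one_bin_offset_tolerance(self):
        d1 = make_set(20, [(0, 4)])
        d2 = make_set(20, [(1, 5)])
        assert hk.boundary_overlap(d1, d2, tol_bins=1) == 1.0
        assert hk.boundary_overlap(d1, d2, tol_bins=0) == 0.0

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(2)
        d1 = make_set(50, [(0, 9), (12, 20), (30, 44)])
        d2 = make_set(50, [(3, 11), (22, 28), (33, 40)])
        vals = [hk.boundary_overlap(d1, d2, t) for t in range(6)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_empty_first_set_rejected(self):
        with pytest.raises(ValueError):
            hk.boundary_overlap(make_set(20, []), make_set(20, [(0, 5)]))

    def test_replicate_maps_share_boundaries(self):
        g = GenomeModel((Chromosome("A", 20_000_000), Chromosome("B", 15_000_000)))
        doms = [("A", s, s + 1_000_000) for s in range(0, 20_000_000, 1_000_000)]
        sets = []
        for seed in (31, 32):
            p = hk.SimulationParams(bin_size=50_000, total_contacts=1.2e7, seed=seed,
                                    tad_boost=1.0, tad_domains=doms)
            m = hk.simulate_map(DerivativeKaryotype.identity(g), p)
            sets.append(hk.armatus_segment(m, "A", 0.1))
        assert hk.boundary_overlap(sets[0], sets[1], tol_bins=1) > 0.8


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        d = make_set(20, [(0, 4), (5, 9)])
        assert hk.variation_of_information(d, d) == 0.0

    def test_two_vs_one_cluster_closed_form(self):
        # 4 bins split {2,2} against one 4-bin cluster: VI = 1 bit
        d1 = make_set(4, [(0, 1), (2, 3)])
        d2 = make_set(4, [(0, 3)])
        assert hk.variation_of_information(d1, d2) == pytest.approx(1.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            def rand_set():
                doms, k = [], 0
                while k < n - 1:
                    span = int(rng.integers(1, 6))
                    if rng.random() < 0.7:
                        doms.append((k, min(k + span - 1, n - 1)))
                    k += span
                return make_set(n, doms)
            a, b = rand_set(), rand_set()
            vab = hk.variation_of_information(a, b)
            vba = hk.variation_of_information(b, a)
            assert vab == pytest.approx(vba)
            assert vab >= 0
            assert hk.variation_of_information(a, a) == 0.0
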