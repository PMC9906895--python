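"""Map-level quality statistics: cis/trans ratio, replicate agreement, coverage."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .genome import BinTable
from .matrix import ContactMatrix


class InfiniteRatioError(ZeroDivisionError):
    """Raised when a map has no trans contacts (cis/trans ratio undefined)."""


@dataclass
class CoverageTrack:
    bin_table: BinTable
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.bin_table.n_bins:
            raise ValueError("coverage length does not match bin table")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bin_table.chrom_slice(chrom)]

    def write_bedgraph(self, path) -> None:
        bt = self.bin_table
        with open(path, "w") as fh:
            for k, v in enumerate(self.values):
                fh.write(
                    f"{bt.bin_chrom(k)}\t{bt.starts[k]}\t{bt.ends[k]}\t{v:g}\n"
                )


def cis_trans_ratio(matrix: ContactMatrix) -> float:
    """Total intra- over inter-chromosomal contacts (diagonal counts as cis)."""
    if len(matrix.bin_table.genome.chromosomes) < 2:
        raise ValueError("cis/trans ratio needs at least two chromosomes")
    cis, trans = matrix.cis_trans_totals()
    if trans == 0:
        raise InfiniteRatioError("map has no trans contacts")
    return cis / trans


def trans_fraction(matrix: ContactMatrix) -> float:
    """Inter-chromosomal contacts as a fraction of all contacts."""
    cis, trans = matrix.cis_trans_totals()
    total = cis + trans
    if total == 0:
        raise ValueError("empty contact matrix")
    return trans / total


def replicate_correlation(m1: ContactMatrix, m2: ContactMatrix,
                          bin_size: int = 50_000) -> float:
    """Pearson correlation of log1p counts over the union of nonzero pixels.

    Both maps are coarsened to ``bin_size`` first; zeros are kept wherever the
    other map has signal, so missing pixels count against the correlation.
    """
    if m1.bin_table.genome.names != m2.bin_table.genome.names:
        raise ValueError("maps are on different genomes")
    a = m1.coarsen(max(bin_size, m1.bin_table.bin_size)).pixels.tocsr()
    b = m2.coarsen(max(bin_size, m2.bin_table.bin_size)).pixels.tocsr()
    union = (a != 0) + (b != 0)
    union = union.tocoo()
    va = np.asarray(a[union.row, union.col]).ravel()
    vb = np.asarray(b[union.row, union.col]).ravel()
    r, _ = pearsonr(np.log1p(va), np.log1p(vb))
    return float(r)


def cis_coverage_track(matrix: ContactMatrix) -> CoverageTrack:
    """Per-bin marginal restricted to intra-chromosomal contacts.

    A segment moved off one homologue loses half its interactions with the
    rest of its own chromosome, while a translocated duplication keeps them --
    this channel separates the two where the raw marginal cannot.
    """
    s = matrix.symmetric()
    bt = matrix.bin_table
    vals = np.zeros(bt.n_bins)
    for chrom in bt.genome.names:
        sl = bt.chrom_slice(chrom)
        vals[sl] = np.asarray(s[sl, sl].sum(axis=1)).ravel()
    return CoverageTrack(bt, vals)


def coverage_track(matrix: ContactMatrix, normalized: bool = False) -> CoverageTrack:
    """Per-bin marginal contact sums; optionally scaled to autosomal median 1."""
    vals = matrix.marginals()
    if normalized:
        bt = matrix.bin_table
        auto = np.concatenate(
            [vals[bt.chrom_slice(c.name)] for c in bt.genome.autosomes()]
        )
        med = np.median(auto[auto > 0]) if (auto > 0).any() else 0
        if med == 0:
            raise ValueError("cannot normalize: autosomal coverage is zero")
        vals = vals / med
    return CoverageTrack(matrix.bin_table, vals)
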