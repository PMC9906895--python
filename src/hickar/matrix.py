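"""Sparse genome-wide contact matrices.

Only the upper triangle (bin_i <= bin_j) is stored; accessors symmetrize on
the fly.  Interchange formats are COO triplet text with a bins side file, and
a minimal cool-style HDF5 container (chroms/bins/pixels groups).
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .genome import BinTable, Chromosome, GenomeModel


class ContactMatrix:
    def __init__(self, bin_table: BinTable, pixels: sp.spmatrix,
                 balanced_weights: np.ndarray | None = None):
        n = bin_table.n_bins
        csr = sp.csr_matrix(pixels, shape=(n, n))
        csr.sum_duplicates()
        if (csr.data < 0).any() or not np.isfinite(csr.data).all():
            raise ValueError("contact counts must be finite and non-negative")
        low = sp.tril(csr, k=-1)
        if low.nnz:
            # fold any lower-triangle input onto the upper triangle
            csr = sp.triu(csr) + low.T
            csr = sp.csr_matrix(csr)
        csr.eliminate_zeros()
        self.bin_table = bin_table
        self.pixels = csr
        self.balanced_weights = balanced_weights
        self._sym: sp.csr_matrix | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_coo_arrays(cls, bin_table, bin1, bin2, count) -> "ContactMatrix":
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        i = np.minimum(bin1, bin2)
        j = np.maximum(bin1, bin2)
        n = bin_table.n_bins
        if len(i) and (i.min() < 0 or j.max() >= n):
            raise ValueError("pixel references a bin outside the bin table")
        m = sp.coo_matrix((np.asarray(count, dtype=np.float64), (i, j)), shape=(n, n))
        return cls(bin_table, m)

    # -- basic properties --------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins

    def total(self) -> float:
        return float(self.pixels.sum())

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric matrix (diagonal counted once); cached."""
        if self._sym is None:
            u = self.pixels
            self._sym = (u + sp.triu(u, k=1).T).tocsr()
        return self._sym

    def dense_block(self, chromA: str, chromB: str) -> np.ndarray:
        """Dense counts for a chromosome pair in (A-bins, B-bins) orientation."""
        sa = self.bin_table.chrom_slice(chromA)
        sb = self.bin_table.chrom_slice(chromB)
        s = self.symmetric()
        return np.asarray(s[sa, sb].todense())

    def marginals(self) -> np.ndarray:
        s = self.symmetric()
        return np.asarray(s.sum(axis=1)).ravel()

    def cis_trans_totals(self) -> tuple[float, float]:
        coo = self.pixels.tocoo()
        same = self.bin_table.chrom_ids[coo.row] == self.bin_table.chrom_ids[coo.col]
        cis = float(coo.data[same].sum())
        return cis, float(coo.data.sum() - cis)

    # -- resolution changes ------------------------------------------------
    def coarsen(self, bin_size: int) -> "ContactMatrix":
        """Aggregate counts onto a coarser bin grid (bin_size a multiple of current)."""
        cur = self.bin_table.bin_size
        if bin_size == cur:
            return self
        if bin_size % cur:
            raise ValueError(f"target bin size {bin_size} not a multiple of {cur}")
        new_bt = BinTable(self.bin_table.genome, bin_size)
        # map old bin -> new bin via genomic start position
        old = self.bin_table
        new_ids = np.empty(old.n_bins, dtype=np.int64)
        for c in old.genome.names:
            sl = old.chrom_slice(c)
            new_ids[sl] = new_bt.chrom_offset(c) + old.starts[sl] // bin_size
        coo = self.pixels.tocoo()
        i = new_ids[coo.row]
        j = new_ids[coo.col]
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        m = sp.coo_matrix((coo.data, (lo, hi)), shape=(new_bt.n_bins, new_bt.n_bins))
        return ContactMatrix(new_bt, m)

    # -- I/O ---------------------------------------------------------------
    def write_coo(self, pixels_path, bins_path) -> None:
        coo = self.pixels.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(pixels_path, "w") as fh:
            fh.write("bin1_id\tbin2_id\tcount\n")
            for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{r}\t{c}\t{v:g}\n")
        self.bin_table.to_frame().to_csv(bins_path, sep="\t", index=False)

    @classmethod
    def read_coo(cls, pixels_path, bins_path) -> "ContactMatrix":
        import pandas as pd

        bins = pd.read_csv(bins_path, sep="\t")
        bt = _bin_table_from_frame(bins)
        px = pd.read_csv(pixels_path, sep="\t")
        return cls.from_coo_arrays(bt, px["bin1_id"], px["bin2_id"], px["count"])

    def write_cool(self, path) -> None:
        """Write a single-resolution cool-style HDF5 container."""
        import h5py

        bt = self.bin_table
        coo = self.pixels.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with h5py.File(path, "w") as h5:
            h5.attrs["format"] = "HDF5::Cooler"
            h5.attrs["bin-size"] = bt.bin_size
            g = h5.create_group("chroms")
            g.create_dataset("name", data=np.array(bt.genome.names, dtype="S32"))
            g.create_dataset(
                "length", data=np.array([c.length for c in bt.genome.chromosomes])
            )
            g = h5.create_group("bins")
            g.create_dataset("chrom", data=bt.chrom_ids.astype(np.int32))
            g.create_dataset("start", data=bt.starts)
            g.create_dataset("end", data=bt.ends)
            g = h5.create_group("pixels")
            g.create_dataset("bin1_id", data=coo.row[order].astype(np.int64))
            g.create_dataset("bin2_id", data=coo.col[order].astype(np.int64))
            g.create_dataset("count", data=coo.data[order])

    @classmethod
    def read_cool(cls, path) -> "ContactMatrix":
        import h5py

        with h5py.File(path, "r") as h5:
            names = [n.decode() for n in h5["chroms/name"][:]]
            lengths = h5["chroms/length"][:]
            bin_size = int(h5.attrs["bin-size"])
            genome = GenomeModel(
                tuple(Chromosome(n, int(L)) for n, L in zip(names, lengths))
            )
            bt = BinTable(genome, bin_size)
            return cls.from_coo_arrays(
                bt, h5["pixels/bin1_id"][:], h5["pixels/bin2_id"][:], h5["pixels/count"][:]
            )


def _bin_table_from_frame(bins) -> BinTable:
    chroms = []
    for name, grp in bins.groupby("chrom", sort=False):
        chroms.append(Chromosome(str(name), int(grp["end"].max())))
    bin_size = int((bins["end"] - bins["start"]).max())
    return BinTable(GenomeModel(tuple(chroms)), bin_size)
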