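"""A/B compartment calling by eigenvector decomposition of the contact
correlation matrix, and cross-map comparison.

Per chromosome: coarsen to the analysis bin size, mask low-coverage bins,
divide by the per-diagonal mean (observed/expected), take the Pearson
correlation matrix of the result and report its leading eigenvector.  The
eigenvector sign is arbitrary and must be oriented against an activity proxy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .genome import BinTable
from .matrix import ContactMatrix


@dataclass
class CompartmentTrack:
    bin_table: BinTable
    chrom: str
    values: np.ndarray  # NaN on masked bins
    variance_explained: float = float("nan")
    reliable: bool = True
    orientation_ambiguous: bool = False

    @property
    def labels(self) -> np.ndarray:
        """Per-bin 'A' / 'B' / 'NA' labels (A = positive value)."""
        lab = np.where(np.isnan(self.values), "NA", np.where(self.values > 0, "A", "B"))
        return lab.astype("U2")

    def write_bedgraph(self, path) -> None:
        bt = self.bin_table
        sl = bt.chrom_slice(self.chrom)
        with open(path, "w") as fh:
            for k, v in zip(range(sl.start, sl.stop), self.values):
                if not np.isnan(v):
                    fh.write(f"{self.chrom}\t{bt.starts[k]}\t{bt.ends[k]}\t{v:g}\n")

    def write_bed(self, path) -> None:
        """A/B/NA segments as BED intervals."""
        bt = self.bin_table
        sl = bt.chrom_slice(self.chrom)
        labs = self.labels
        with open(path, "w") as fh:
            run_start, run_lab = 0, labs[0]
            for k in range(1, len(labs) + 1):
                if k == len(labs) or labs[k] != run_lab:
                    s = bt.starts[sl.start + run_start]
                    e = bt.ends[sl.start + k - 1]
                    fh.write(f"{self.chrom}\t{s}\t{e}\t{run_lab}\n")
                    if k < len(labs):
                        run_start, run_lab = k, labs[k]


def observed_expected(block: np.ndarray) -> np.ndarray:
    """Divide a symmetric dense cis matrix by its per-diagonal mean."""
    n = len(block)
    oe = np.zeros((n, n))
    idx = np.arange(n)
    for d in range(n):
        i, j = idx[: n - d], idx[d:]
        vals = block[i, j]
        mu = vals.mean()
        r = vals / mu if mu > 0 else np.zeros_like(vals)
        oe[i, j] = r
        oe[j, i] = r
    return oe


def compartment_eigenvector(
    matrix: ContactMatrix, chrom: str, bin_size: int = 50_000,
    mask_quantile: float = 0.02,
) -> CompartmentTrack:
    """Leading eigenvector of the cis correlation matrix at ``bin_size``.

    Bins with zero coverage and the bottom ``mask_quantile`` of per-bin
    coverage are masked; masked bins are reported NaN, never imputed.
    """
    m = matrix.coarsen(max(bin_size, matrix.bin_table.bin_size))
    bt = m.bin_table
    block = m.dense_block(chrom, chrom)
    n = len(block)
    if n < 20:
        raise ValueError(f"{chrom}: need >=20 bins for eigenvector analysis")
    cov = block.sum(axis=1)
    usable = cov > 0
    if usable.sum():
        thr = np.quantile(cov[usable], mask_quantile)
        usable &= cov >= thr
    if usable.sum() < 3:
        raise ValueError(f"{chrom}: all bins masked")
    sub = block[np.ix_(usable, usable)]
    oe = observed_expected(sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    var_exp = float(evals[-1] / np.sum(np.abs(evals)))
    # a leading eigenvalue standing clear of the noise bulk (second
    # eigenvalue) marks a genuine two-state structure
    gap = float(evals[-1] / evals[-2]) if evals[-2] > 0 else np.inf
    values = np.full(n, np.nan)
    values[usable] = lead
    return CompartmentTrack(
        bt, chrom, values,
        variance_explained=var_exp,
        reliable=gap >= 1.5,
    )


def orient_sign(track: CompartmentTrack, reference: np.ndarray,
                ambiguity_r: float = 0.05) -> CompartmentTrack:
    """Flip the track so it correlates positively with an activity proxy.

    ``reference`` covers the chromosome on the track's bin grid.  A proxy with
    |r| below ``ambiguity_r`` leaves the sign as-is but flags the orientation
    as ambiguous.
    """
    ref = np.asarray(reference, dtype=float)
    if len(ref) != len(track.values):
        raise ValueError("proxy length does not match track")
    ok = ~np.isnan(track.values) & ~np.isnan(ref)
    if ref[ok].std() == 0:
        raise ValueError("zero-variance orientation proxy")
    r, _ = pearsonr(track.values[ok], ref[ok])
    vals = track.values if r >= 0 else -track.values
    return CompartmentTrack(
        track.bin_table, track.chrom, vals,
        variance_explained=track.variance_explained,
        reliable=track.reliable,
        orientation_ambiguous=abs(r) < ambiguity_r,
    )


def compare_compartments(t1: CompartmentTrack, t2: CompartmentTrack) -> float:
    """Pearson correlation over bins defined in both tracks."""
    if t1.bin_table.bin_size != t2.bin_table.bin_size:
        raise ValueError("tracks use different bin sizes")
    if len(t1.values) != len(t2.values):
        raise ValueError("tracks cover different extents")
    ok = ~np.isnan(t1.values) & ~np.isnan(t2.values)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 shared usable bins")
    r, _ = pearsonr(t1.values[ok], t2.values[ok])
    return float(r)


def compartment_switch_bins(
    t1: CompartmentTrack, t2: CompartmentTrack
) -> list[tuple[str, int, int, str]]:
    """Contiguous intervals whose A/B label differs, with switch direction."""
    l1, l2 = t1.labels, t2.labels
    bt = t1.bin_table
    sl = bt.chrom_slice(t1.chrom)
    diff = (l1 != l2) & (l1 != "NA") & (l2 != "NA")
    out = []
    k = 0
    while k < len(diff):
        if diff[k]:
            j = k
            while j + 1 < len(diff) and diff[j + 1] and l1[j + 1] == l1[k]:
                j += 1
            direction = f"{l1[k]}→{l2[k]}"
            out.append(
                (t1.chrom, int(bt.starts[sl.start + k]), int(bt.ends[sl.start + j]), direction)
            )
            k = j + 1
        else:
            k += 1
    return out
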