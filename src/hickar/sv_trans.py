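"""Interchromosomal structural-variant detection from trans-contact patterns.

The detector formalizes what a trained eye does on a chromosome-pair heatmap:
find blocks of inter-chromosomal contact enrichment against the pair's
background, localize the breakpoints from the contact gradient at fine
resolution (contacts decay away from the fusion junction), read the segment
orientation off the gradient direction, and classify each event from the
block geometry and read coverage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import poisson

from .matrix import ContactMatrix
from .qc import CoverageTrack, coverage_track


def _bh_reject(pvals: np.ndarray, alpha: float, min_tests: int) -> np.ndarray:
    """Benjamini-Hochberg rejections with a floor on the test count."""
    m = len(pvals)
    denom = max(m, min_tests)
    order = np.argsort(pvals)
    thr = alpha * np.arange(1, m + 1) / denom
    passed = pvals[order] <= thr
    if not passed.any():
        return np.zeros(m, dtype=bool)
    k = int(np.max(np.flatnonzero(passed)))
    return pvals <= pvals[order][k]


@dataclass
class DetectionParams:
    scan_bin: int = 250_000
    refine_bin: int = 5_000
    enrichment_z_min: float = 4.0
    min_segment_bp: int = 200_000
    background_model: str = "per-pair-median"  # or "global-trans-mean"
    smoothing_window: int = 3
    fusion_span_fraction: float = 0.9
    fdr_alpha: float = 0.01
    # a block needs at least this many significant pixels: single-pixel
    # components carry no spatial support and are rejected as noise
    min_block_pixels: int = 2
    # the BH correction is per chromosome pair, but small pairs (a handful of
    # pixels) are corrected as if they had at least this many tests so that
    # the many micro-micro pairs do not leak genome-wide false positives
    bh_min_tests: int = 50_000
    # cis-coverage ratio below which the donor segment counts as moved off
    # one homologue (moved ~ 0.5, duplicated ~ 1.0 of the chromosome's level)
    loss_coverage_max: float = 0.75
    # O/E enrichment between the donor flanks (the "bridge" created when the
    # segment leaves one homologue and its flanks become adjacent) above
    # which an interior segment counts as moved
    bridge_oe_min: float = 3.0
    bridge_flank_bins: int = 4
    # matched-filter half-width (refine bins) for acceptor-site localization
    peak_window: int = 20

    def __post_init__(self):
        if self.scan_bin % self.refine_bin:
            raise ValueError("refine_bin must divide scan_bin")
        if self.min_segment_bp < self.refine_bin:
            raise ValueError("min_segment_bp must be >= refine_bin")
        if self.background_model not in ("per-pair-median", "global-trans-mean"):
            raise ValueError(f"unknown background model {self.background_model!r}")


@dataclass
class EnrichmentBlock:
    chromA: str
    intervalA: tuple[int, int]  # bp, half-open
    chromB: str
    intervalB: tuple[int, int]
    mean_z: float
    pixel_count: int


@dataclass
class SVCall:
    kind: str  # translocation | terminal_fusion | inversion | deletion
    donor_chrom: str
    donor_segment: tuple[int, int]  # bp
    donor_breakpoint: int | str | None  # bp, or "ter"
    donor_orientation: str  # + | - | unknown
    acceptor_chrom: str | None = None
    acceptor_insertion: int | str | None = None  # bp or ter:p / ter:q
    classification: str = "unclassified"
    score: float = 0.0
    uncertainty_bp: int = 0
    low_confidence: bool = False
    block: EnrichmentBlock | None = None
    # whether each donor-segment edge is a sharp signal/background step; a
    # non-sharp edge means the enrichment faded below significance and the
    # physical segment probably continues past it
    edges_sharp: tuple[bool, bool] = (True, True)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.donor_chrom, self.acceptor_chrom)


def _global_trans_mean(matrix: ContactMatrix) -> float:
    cis, trans = matrix.cis_trans_totals()
    bt = matrix.bin_table
    sizes = np.array([bt.n_chrom_bins(c) for c in bt.genome.names], dtype=float)
    n = sizes.sum()
    pairs = (n * n - np.sum(sizes * sizes)) / 2
    return trans / pairs if pairs else 0.0


def trans_enrichment(
    matrix: ContactMatrix, chromA: str, chromB: str,
    params: DetectionParams | None = None,
) -> list[EnrichmentBlock]:
    """Significant trans-contact enrichment blocks for one chromosome pair.

    Pixels at ``scan_bin`` are tested against a Poisson background (per-pair
    median by default, which is robust to the block itself), corrected by
    Benjamini-Hochberg across the pair; significant pixels are joined into
    8-connected components (bridging gaps up to the smoothing window) and
    reported as bounding boxes.
    """
    params = params or DetectionParams()
    m = matrix.coarsen(max(params.scan_bin, matrix.bin_table.bin_size))
    bt = m.bin_table
    X = m.dense_block(chromA, chromB)
    if params.background_model == "per-pair-median":
        lam = float(np.median(X))
        if lam == 0:
            lam = max(float(X.mean()), _global_trans_mean(m))
    else:
        lam = _global_trans_mean(m)
    lam = max(lam, 1e-9)
    pv = poisson.sf(X - 1, lam)
    sig = _bh_reject(pv.ravel(), params.fdr_alpha, params.bh_min_tests).reshape(X.shape)
    if not sig.any():
        return []
    # cross-shaped (4-connected) joining: diagonal-only contact is kept apart,
    # which is what separates the two quadrants of a reciprocal translocation;
    # fragments of one blob are re-joined afterwards by _merge_fragments
    cross = ndimage.generate_binary_structure(2, 1)
    labels, nlab = ndimage.label(sig, structure=cross)
    scan = bt.bin_size
    lenA = bt.genome.length(chromA)
    lenB = bt.genome.length(chromB)
    z = (X - lam) / np.sqrt(lam)
    raw = []
    for k in range(1, nlab + 1):
        comp = sig & (labels == k)
        npix = int(comp.sum())
        if npix == 0:
            continue
        rows, cols = np.nonzero(comp)
        raw.append(
            [rows.min(), rows.max() + 1, cols.min(), cols.max() + 1,
             float(z[comp].sum()), npix]
        )
    raw = _merge_fragments(raw)
    blocks = []
    for a0, a1, b0, b1, zsum, npix in raw:
        if npix < params.min_block_pixels:
            continue
        extA = min(a1 * scan, lenA) - a0 * scan
        extB = min(b1 * scan, lenB) - b0 * scan
        if extA < params.min_segment_bp and extB < params.min_segment_bp:
            continue
        mean_z = zsum / npix
        if mean_z < params.enrichment_z_min:
            continue
        blocks.append(
            EnrichmentBlock(
                chromA, (int(a0 * scan), int(min(a1 * scan, lenA))),
                chromB, (int(b0 * scan), int(min(b1 * scan, lenB))),
                mean_z, npix,
            )
        )
    blocks.sort(key=lambda b: (-b.mean_z, b.intervalA, b.intervalB))
    return blocks


def _merge_fragments(raw: list, gap: int = 20) -> list:
    """Join component fragments of one enrichment blob.

    Two components merge when their boxes overlap on one axis and are within
    ``gap`` bins on the other -- the shape of a decaying junction signal that
    broke into pieces.  Blocks that merely touch at a corner point (the
    reciprocal-translocation geometry) never merge.
    """
    def overlap(lo1, hi1, lo2, hi2):
        return min(hi1, hi2) - max(lo1, lo2)

    changed = True
    while changed:
        changed = False
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                a = raw[i]
                b = raw[j]
                oA = overlap(a[0], a[1], b[0], b[1])
                oB = overlap(a[2], a[3], b[2], b[3])
                if (oA >= 1 and oB >= -gap) or (oB >= 1 and oA >= -gap):
                    raw[i] = [
                        min(a[0], b[0]), max(a[1], b[1]),
                        min(a[2], b[2]), max(a[3], b[3]),
                        a[4] + b[4], a[5] + b[5],
                    ]
                    del raw[j]
                    changed = True
                    break
            if changed:
                break
    return raw


# ---------------------------------------------------------------------------
# breakpoint localization
# ---------------------------------------------------------------------------

def _two_changepoint(y: np.ndarray) -> tuple[int, int, float]:
    """Best (c1, c2) under a 3-segment constant-rate Poisson model.

    The middle segment [c1, c2) is the signal; outer segments may be empty.
    Returns the change points and the log-likelihood gain over a flat model.
    Exhaustive over all bin pairs; deterministic.
    """
    n = len(y)
    c = np.concatenate([[0.0], np.cumsum(y)])

    def ll(s, width):
        out = np.zeros_like(np.asarray(s, dtype=float))
        w = np.asarray(width, dtype=float)
        sv = np.asarray(s, dtype=float)
        pos = (sv > 0) & (w > 0)
        out = np.where(pos, sv * np.log(np.maximum(sv, 1e-300) / np.maximum(w, 1)), 0.0)
        return out

    best = (-np.inf, 0, n)
    c2s = np.arange(1, n + 1)
    for c1 in range(n):
        valid = c2s > c1
        c2v = c2s[valid]
        left = ll(c[c1], c1)
        mid = ll(c[c2v] - c[c1], c2v - c1)
        right = ll(c[n] - c[c2v], n - c2v)
        tot = left + mid + right
        k = int(np.argmax(tot))
        if tot[k] > best[0]:
            best = (float(tot[k]), c1, int(c2v[k]))
    flat = float(ll(c[n], n))
    return best[1], best[2], best[0] - flat


def _one_changepoint(y: np.ndarray) -> int:
    """Index splitting y into two maximal-likelihood constant-rate segments."""
    n = len(y)
    if n < 2:
        return 0
    c = np.concatenate([[0.0], np.cumsum(y)])
    ks = np.arange(1, n)

    def ll(s, w):
        s = np.asarray(s, dtype=float)
        w = np.asarray(w, dtype=float)
        return np.where(s > 0, s * np.log(np.maximum(s, 1e-300) / np.maximum(w, 1)), 0.0)

    tot = ll(c[ks], ks) + ll(c[n] - c[ks], n - ks)
    return int(ks[np.argmax(tot)])


def _signal_run(y: np.ndarray, bg: float, smooth: int = 5,
                refine_half: int = 20) -> tuple[int, int]:
    """Extent [c1, c2) of the contiguous above-background signal in a profile.

    The run is located on a lightly smoothed profile (strongest contiguous
    excess over the trans background), then each interior edge is sharpened
    by a local single-change-point Poisson fit -- the crossing itself is
    blurred by smoothing, the likelihood fit is not.
    """
    n = len(y)
    ys = ndimage.uniform_filter1d(y.astype(float), smooth, mode="nearest")
    thr = bg + 3.0 * np.sqrt(max(bg, 0.25) / smooth) + 0.5
    mask = ys > thr
    if not mask.any():
        return 0, n
    # strongest contiguous run
    best = (0.0, 0, n)
    k = 0
    while k < n:
        if mask[k]:
            j = k
            while j + 1 < n and mask[j + 1]:
                j += 1
            excess = float(np.sum(ys[k : j + 1] - bg))
            if excess > best[0]:
                best = (excess, k, j + 1)
            k = j + 1
        else:
            k += 1
    _, c1, c2 = best

    def refine(edge):
        a = max(0, edge - refine_half)
        b = min(n, edge + refine_half)
        if b - a < 3:
            return edge
        return a + _one_changepoint(y[a:b])

    if c1 > 0:
        c1 = refine(c1)
    if c2 < n:
        c2 = refine(c2)
    if c2 <= c1:
        c1, c2 = best[1], best[2]
    return c1, c2


def _peak_boundary(y: np.ndarray, smooth: int) -> int:
    """Boundary index between the two adjacent bins with maximal joint signal.

    At a fusion insertion both flanking bins touch (different ends of) the
    inserted segment, so the profile peaks on the two bins around the
    insertion point; the boundary between them is the insertion site.  The
    coarse argmax is refined by a template fit (:func:`_insertion_fit`).
    """
    if len(y) < 2:
        return len(y)
    ys = y
    if smooth > 1:
        ys = ndimage.uniform_filter1d(y.astype(float), smooth, mode="nearest")
    pair = ys[:-1] + ys[1:]
    init = int(np.argmax(pair)) + 1
    return _insertion_fit(y, init)


def _insertion_fit(y: np.ndarray, init: int, seg_bins: float = 500.0,
                   half: int = 40) -> int:
    """Refine an insertion boundary by fitting the marginal's decay template.

    Around an insertion at boundary b the marginal follows
    bg + A*log(1 + L/(d+1)) with d the bin distance to b on either side
    (both flanks touch an end of the inserted segment).  Fitting amplitude
    and background per candidate boundary and scoring by residual error uses
    the whole window's trend rather than two noisy bins.
    """
    n = len(y)
    lo = max(1, init - half)
    hi = min(n - 1, init + half)
    if hi <= lo:
        return init
    x = np.arange(n, dtype=float)
    yf = y.astype(float)
    best = (np.inf, init)
    for b in range(lo, hi + 1):
        d = np.abs(x - b + 0.5) - 0.5
        s = np.log1p(seg_bins / (d + 1.0))
        A = np.column_stack([np.ones(n), s])
        coef, res, *_ = np.linalg.lstsq(A, yf, rcond=None)
        sse = float(res[0]) if len(res) else float(np.sum((yf - A @ coef) ** 2))
        if sse < best[0]:
            best = (sse, b)
    return best[1]


def _orientation(y: np.ndarray, c1: int, c2: int) -> tuple[str, bool]:
    """Gradient direction across the signal segment.

    Returns (orientation, confident): '+' when the profile decays toward
    higher coordinates (junction at the segment start), '-' for the reverse,
    'unknown' when the total log-fall across the segment is below ln 2.
    """
    seg = y[c1:c2].astype(float)
    if len(seg) < 4:
        return "unknown", False
    x = np.arange(len(seg))
    ly = np.log1p(seg)
    slope = np.polyfit(x, ly, 1)[0]
    fall = slope * len(seg)
    if abs(fall) < np.log(2):
        return "unknown", False
    return ("-" if fall > 0 else "+"), True


def localize_breakpoint(
    block: EnrichmentBlock, matrix: ContactMatrix,
    params: DetectionParams | None = None,
    donor_axis: str | None = None,
    acceptor_edge: str | None = None,
) -> SVCall:
    """Refine a coarse enrichment block into an oriented breakpoint call.

    Within the block (plus one scan-bin margin) at the matrix's native
    resolution, the marginal contact profile along each axis is examined.
    The donor axis -- the one whose enrichment is sharply bounded -- is fitted
    with a two-change-point Poisson model giving the translocated segment; the
    junction is the segment end adjacent to the enrichment maximum.  On the
    acceptor axis the insertion site is the boundary between the two jointly
    maximal flanking bins (both touch the inserted segment).
    """
    params = params or DetectionParams()
    bt = matrix.bin_table
    fine = bt.bin_size
    margin = 4 * params.scan_bin
    sym = matrix.symmetric().tocsr()

    def window(chrom, interval):
        n = bt.n_chrom_bins(chrom)
        off = bt.chrom_offset(chrom)
        lo = max(0, (interval[0] - margin) // fine)
        hi = min(n, -(-(interval[1] + margin) // fine))
        return off + lo, off + hi, lo, hi

    a_lo, a_hi, aw0, aw1 = window(block.chromA, block.intervalA)
    b_lo, b_hi, bw0, bw1 = window(block.chromB, block.intervalB)
    # profiles extend past the block on their own axis only; the summed-over
    # axis stays strictly inside the block so that neighbouring events (e.g.
    # the other quadrant of a reciprocal) cannot bleed into the marginal
    offA = bt.chrom_offset(block.chromA)
    offB = bt.chrom_offset(block.chromB)
    sa0 = offA + block.intervalA[0] // fine
    sa1 = offA + -(-block.intervalA[1] // fine)
    sb0 = offB + block.intervalB[0] // fine
    sb1 = offB + -(-block.intervalB[1] // fine)
    profA = np.asarray(sym[a_lo:a_hi, sb0:sb1].sum(axis=1)).ravel()
    profB = np.asarray(sym[sa0:sa1, b_lo:b_hi].sum(axis=0)).ravel()

    # The donor axis is bounded by true background: just outside the donor
    # segment the marginal falls to the pair's trans-background level.  On
    # the acceptor axis the gradient continues (just below block
    # significance), so its flanks stay measurably elevated.  The background
    # is the pair's scan-level median (same model as the detection stage),
    # which is robust to the enrichment itself.
    f = max(1, params.scan_bin // fine)
    nA_ch = bt.n_chrom_bins(block.chromA)
    nB_ch = bt.n_chrom_bins(block.chromB)
    piece = sym[offA : offA + nA_ch, offB : offB + nB_ch].tocoo()
    coarse = np.zeros((-(-nA_ch // f), -(-nB_ch // f)))
    np.add.at(coarse, (piece.row // f, piece.col // f), piece.data)
    bg_px = float(np.median(coarse)) / (f * f)
    del piece

    def bg_flanks(prof, interval, lo_bin, n_summed):
        """(number of background-level flanks, number of existing flanks)."""
        i0 = interval[0] // fine - lo_bin
        i1 = -(-interval[1] // fine) - lo_bin
        bg = bg_px * n_summed
        nbg = nex = 0
        for s in (prof[:i0], prof[i1:]):
            if not s.size:
                continue
            nex += 1
            noise = 3.0 * np.sqrt(max(bg, 0.25) / len(s))
            if float(s.mean()) - bg <= noise + 0.5:
                nbg += 1
        return nbg, nex

    def sharp_interior_edges(prof, bg):
        """Count signal-run edges that are steps (not smooth decay fades)."""
        e1, e2 = _signal_run(prof, bg)
        thr = 3.0 * np.sqrt(max(bg, 0.25) / 5) + 0.5
        n = len(prof)
        count = 0
        if 0 < e1:
            inner = prof[e1 : min(e1 + 5, e2)]
            if inner.size and float(inner.mean()) - bg > 4.0 * thr:
                count += 1
        if e2 < n:
            inner = prof[max(e1, e2 - 5) : e2]
            if inner.size and float(inner.mean()) - bg > 4.0 * thr:
                count += 1
        return count

    if donor_axis is None:
        # the donor profile steps down to background at a true segment edge;
        # the acceptor profile is a gradient that fades smoothly
        sA = sharp_interior_edges(profA, bg_px * (sb1 - sb0))
        sB = sharp_interior_edges(profB, bg_px * (sa1 - sa0))
        nA, _ = bg_flanks(profA, block.intervalA, aw0, sb1 - sb0)
        nB, _ = bg_flanks(profB, block.intervalB, bw0, sa1 - sa0)
        if sA != sB:
            donor_is_A = sA > sB
        elif (nA > 0) != (nB > 0):
            donor_is_A = nA > 0
        else:
            # neither axis decisive (fusion corner): by convention the donor
            # is the chromosome with the larger involved fraction -- whole
            # microchromosomes read as donors
            fA = (block.intervalA[1] - block.intervalA[0]) / bt.genome.length(block.chromA)
            fB = (block.intervalB[1] - block.intervalB[0]) / bt.genome.length(block.chromB)
            donor_is_A = fA >= fB
    else:
        donor_is_A = donor_axis == "A"

    if donor_is_A:
        dchrom, dprof, dw0 = block.chromA, profA, aw0
        achrom, aprof, aw = block.chromB, profB, bw0
    else:
        dchrom, dprof, dw0 = block.chromB, profB, bw0
        achrom, aprof, aw = block.chromA, profA, aw0

    dbg = bg_px * ((sb1 - sb0) if donor_is_A else (sa1 - sa0))
    c1, c2 = _signal_run(dprof, dbg)
    seg = (int((dw0 + c1) * fine), int(min((dw0 + c2) * fine, bt.genome.length(dchrom))))

    # edge sharpness: a true segment boundary still carries strong signal on
    # its inner side; a decay-faded edge crosses the threshold smoothly
    thr_excess = 3.0 * np.sqrt(max(dbg, 0.25) / 5) + 0.5
    nprof = len(dprof)

    def edge_sharp(edge, inner):
        if edge <= 0:
            return seg[0] == 0
        if edge >= nprof:
            return seg[1] >= bt.genome.length(dchrom)
        ins = dprof[inner]
        if not len(ins):
            return False
        return float(ins.mean()) - dbg > 4.0 * thr_excess

    sharp_left = edge_sharp(c1, slice(c1, min(c1 + 5, c2)))
    sharp_right = edge_sharp(c2, slice(max(c1, c2 - 5), c2))
    orient, confident = _orientation(dprof, c1, c2)
    dlen_bp = bt.genome.length(dchrom)
    if orient == "+":
        bp = seg[0]
    elif orient == "-":
        bp = seg[1]
    elif seg[0] == 0 and seg[1] < dlen_bp:
        # terminal segment with an unreadable gradient: the interior edge is
        # the identified breakpoint
        bp = seg[1]
    else:
        bp = seg[0]

    # donor segment spanning (almost) the whole chromosome with edges at the
    # termini: breakpoint not identifiable -> terminal region.  A non-sharp
    # edge means the enrichment continues past the detected extent, so the
    # span is measured on the extended segment.
    dlen = bt.genome.length(dchrom)
    ext = (0 if not sharp_left else seg[0],
           dlen if not sharp_right else seg[1])
    span = (ext[1] - ext[0]) / dlen
    kind = "translocation"
    donor_bp: int | str | None = int(bp)
    if span >= params.fusion_span_fraction:
        kind = "terminal_fusion"
        donor_bp = "ter"

    # acceptor insertion site; once the donor junction is localized, restrict
    # the marginal to junction-adjacent donor rows -- that is where the
    # acceptor-side gradient is steepest relative to the flat background
    pk = None
    if acceptor_edge is None and orient in "+-" and c2 - c1 > 40:
        K = min(400, c2 - c1)
        r_lo, r_hi = (c1, c1 + K) if orient == "+" else (c2 - K, c2)
        if donor_is_A:
            jprof = np.asarray(
                sym[a_lo + r_lo : a_lo + r_hi, b_lo:b_hi].sum(axis=0)
            ).ravel()
        else:
            jprof = np.asarray(
                sym[a_lo:a_hi, b_lo + r_lo : b_lo + r_hi].sum(axis=1)
            ).ravel()
        # relative to junction-adjacent donor rows the acceptor signal is
        # one-sided: only the acceptor side welded to the junction is
        # elevated, and the insertion is the run edge facing the other side
        jbg = bg_px * (r_hi - r_lo)
        e1, e2 = _signal_run(jprof, jbg)
        if 0 < e1 or e2 < len(jprof):
            center_bp = (aw + 0.5 * (e1 + e2)) * fine
            bulk_left = center_bp > 0.5 * bt.genome.length(achrom)
            pk = e2 if bulk_left else e1
            aprof = jprof
    if pk is None and acceptor_edge is None:
        pk = _peak_boundary(aprof, params.smoothing_window)
    elif pk is None:
        abg = bg_px * ((sa1 - sa0) if donor_is_A else (sb1 - sb0))
        e1, e2 = _signal_run(aprof, abg)
        pk = e1 if acceptor_edge == "left" else e2
    ains = (aw + pk) * fine
    alen = bt.genome.length(achrom)
    n_a = len(aprof)
    insertion: int | str
    if pk >= n_a - 1 and (aw + n_a) * fine >= alen:
        insertion = "ter:q"
    elif pk <= 1 and aw == 0:
        insertion = "ter:p"
    else:
        insertion = int(min(ains, alen))

    return SVCall(
        kind=kind,
        donor_chrom=dchrom,
        donor_segment=seg,
        donor_breakpoint=donor_bp,
        donor_orientation=orient if kind == "translocation" else "unknown",
        acceptor_chrom=achrom,
        acceptor_insertion=insertion,
        score=block.mean_z,
        uncertainty_bp=fine,
        low_confidence=not confident and kind == "translocation",
        block=block,
        edges_sharp=(sharp_left, sharp_right),
    )


def _pair_corners(blocks: list[EnrichmentBlock], params: DetectionParams
                  ) -> tuple[list[tuple[int, int, str]], list[int]]:
    """Identify block pairs that are the two junction corners of one insertion.

    Inserting a donor segment into the body of an acceptor chromosome creates
    *two* junctions (segment start and segment end): two enrichment corners
    that nearly share a point on the acceptor axis but sit far apart on the
    donor axis.  A reciprocal (balanced) pair instead meets at one corner on
    *both* axes and is never paired here.  Returns (pairs, unpaired), each
    pair as (index_low, index_high, donor_axis).
    """
    touch = 2 * params.scan_bin

    def gap(iv1, iv2):
        return max(iv1[0], iv2[0]) - min(iv1[1], iv2[1])

    pairs = []
    used: set[int] = set()
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if i in used or j in used:
                continue
            gA = gap(blocks[i].intervalA, blocks[j].intervalA)
            gB = gap(blocks[i].intervalB, blocks[j].intervalB)
            # one axis overlapping or nearly touching (the shared acceptor
            # junction), the other clearly separated (the two donor-segment
            # ends); a balanced pair touches on *both* axes and never pairs
            if gB <= touch and gA > touch:
                lo, hi = (i, j) if blocks[i].intervalA < blocks[j].intervalA else (j, i)
                pairs.append((lo, hi, "A"))
                used |= {i, j}
            elif gA <= touch and gB > touch:
                lo, hi = (i, j) if blocks[i].intervalB < blocks[j].intervalB else (j, i)
                pairs.append((lo, hi, "B"))
                used |= {i, j}
    unpaired = [k for k in range(len(blocks)) if k not in used]
    return pairs, unpaired


def _corner_pair_call(b_lo: EnrichmentBlock, b_hi: EnrichmentBlock, axis: str,
                      matrix: ContactMatrix, params: DetectionParams) -> SVCall:
    """Assemble one insertion call from its two junction corners.

    The low-coordinate corner contributes the donor segment start, the high
    corner its end; the insertion site is the acceptor-axis edge facing the
    other corner.  The corner geometry fixes the orientation: when the low
    donor corner couples to the acceptor side left of the insertion, the
    segment reads forward into the derivative.
    """
    # acceptor edge facing the other corner: low corner's acceptor interval
    # that lies left of the touch point uses its right edge, and vice versa
    def acc_iv(b):
        return b.intervalB if axis == "A" else b.intervalA

    lo_left = sum(acc_iv(b_lo)) <= sum(acc_iv(b_hi))  # compare interval centers
    c_lo = localize_breakpoint(
        b_lo, matrix, params, donor_axis=axis,
        acceptor_edge="right" if lo_left else "left",
    )
    c_hi = localize_breakpoint(
        b_hi, matrix, params, donor_axis=axis,
        acceptor_edge="left" if lo_left else "right",
    )
    best = max((c_lo, c_hi), key=lambda c: c.score)
    seg = (c_lo.donor_segment[0], c_hi.donor_segment[1])
    orient = "+" if lo_left else "-"
    # insertion from the combined profile of both corners: summing the two
    # one-sided gradients yields a two-sided peak whose flanking-bin boundary
    # is the insertion site
    ins = _combined_insertion(b_lo, b_hi, axis, seg, matrix, params)
    if ins is None:
        ins = best.acceptor_insertion
    return replace(
        best,
        kind="translocation",
        donor_segment=seg,
        donor_breakpoint=seg[0] if orient == "+" else seg[1],
        donor_orientation=orient,
        acceptor_insertion=ins,
        score=max(c_lo.score, c_hi.score),
        low_confidence=False,
        edges_sharp=(True, True),
    )


def _combined_insertion(b_lo: EnrichmentBlock, b_hi: EnrichmentBlock, axis: str,
                        segment: tuple[int, int],
                        matrix: ContactMatrix, params: DetectionParams) -> int | None:
    """Insertion site from both junctions of a corner pair.

    Only donor rows adjacent to each segment end carry a steep acceptor-side
    gradient; summing the two junction-local marginals gives a two-sided peak
    at the insertion point with the best available signal-to-background.
    """
    bt = matrix.bin_table
    fine = bt.bin_size
    sym = matrix.symmetric().tocsr()
    if axis == "A":
        dchrom, achrom = b_lo.chromA, b_lo.chromB
        aiv = (min(b_lo.intervalB[0], b_hi.intervalB[0]),
               max(b_lo.intervalB[1], b_hi.intervalB[1]))
    else:
        dchrom, achrom = b_lo.chromB, b_lo.chromA
        aiv = (min(b_lo.intervalA[0], b_hi.intervalA[0]),
               max(b_lo.intervalA[1], b_hi.intervalA[1]))
    offd = bt.chrom_offset(dchrom)
    offa = bt.chrom_offset(achrom)
    na = bt.n_chrom_bins(achrom)
    nd = bt.n_chrom_bins(dchrom)
    # acceptor window: around the shared touch region of the two corners
    p0 = max(b_lo.intervalB[0] if axis == "A" else b_lo.intervalA[0],
             b_hi.intervalB[0] if axis == "A" else b_hi.intervalA[0])
    a0 = max(0, (aiv[0] - 4 * params.scan_bin) // fine)
    a1 = min(na, -(-(aiv[1] + 4 * params.scan_bin) // fine))
    K = 200
    s0 = segment[0] // fine
    s1 = -(-segment[1] // fine)
    prof = np.zeros(a1 - a0)
    for r0, r1 in ((s0, min(s0 + K, s1)), (max(s0, s1 - K), s1)):
        r0 = max(0, min(r0, nd))
        r1 = max(0, min(r1, nd))
        if r1 <= r0:
            continue
        sub = sym[offd + r0 : offd + r1, offa + a0 : offa + a1]
        prof += np.asarray(sub.sum(axis=0)).ravel()
    if len(prof) < 2:
        return None
    pk = _peak_boundary(prof, params.smoothing_window)
    return int((a0 + pk) * fine)


def _complementary(b1: EnrichmentBlock, b2: EnrichmentBlock) -> bool:
    """Two blocks of one pair occupying opposite quadrants (reciprocal pattern)."""
    disjA = b1.intervalA[1] <= b2.intervalA[0] or b2.intervalA[1] <= b1.intervalA[0]
    disjB = b1.intervalB[1] <= b2.intervalB[0] or b2.intervalB[1] <= b1.intervalB[0]
    if not (disjA and disjB):
        return False
    aboveA = b1.intervalA[0] < b2.intervalA[0]
    aboveB = b1.intervalB[0] < b2.intervalB[0]
    return aboveA != aboveB


def segment_moved_evidence(matrix: ContactMatrix, chrom: str,
                           segment: tuple[int, int],
                           params: DetectionParams) -> bool | None:
    """Did the donor segment leave one homologue?

    Interior segments are tested for the *bridge*: when the segment leaves a
    homologue its flanks become adjacent there, so flank-to-flank contacts
    appear far above the distance expectation.  Terminal segments (no flank
    on one side) are tested for depletion of segment-to-remainder contacts
    instead.  Returns None when the segment spans the whole chromosome.
    """
    from .compartments import observed_expected

    bt = matrix.bin_table
    block = matrix.dense_block(chrom, chrom)
    oe = observed_expected(block)
    bs = bt.bin_size
    i0 = segment[0] // bs
    i1 = max(i0 + 1, -(-segment[1] // bs))
    n = len(block)
    w = params.bridge_flank_bins
    if i0 >= w and i1 + w <= n:
        bridge = oe[max(0, i0 - w) : i0, i1 : i1 + w]
        if bridge.size:
            return float(bridge.mean()) > params.bridge_oe_min
    # depletion near the segment edge, where distance decay still dominates
    # the trans-background floor of the mixture model
    near = 6
    boxes = []
    if i0 > 0:
        boxes.append(oe[i0 : min(i0 + near, i1), max(0, i0 - near) : i0])
    if i1 < n:
        boxes.append(oe[max(i0, i1 - near) : i1, i1 : min(i1 + near, n)])
    vals = np.concatenate([b.ravel() for b in boxes if b.size]) if boxes else None
    if vals is None or not len(vals):
        return None
    return float(vals.mean()) < params.loss_coverage_max


def classify_translocation(
    calls: Sequence[SVCall], coverage: CoverageTrack | None = None,
    params: DetectionParams | None = None,
    matrix: ContactMatrix | None = None,
    fine_matrix: ContactMatrix | None = None,
) -> list[SVCall]:
    """Classify calls sharing one chromosome pair.

    A reciprocal pair of complementary-quadrant blocks is balanced.  A single
    block is read off the donor segment's retention of *cis* contact with the
    rest of its chromosome (see :func:`segment_cis_retention`): below ~0.75
    the segment left one homologue (unbalanced moved); otherwise it was
    copied, not moved (translocated duplication).  When only a coverage track
    is available the same threshold is applied to the segment's normalized
    coverage relative to its chromosome's median.
    """
    params = params or DetectionParams()
    calls = list(calls)
    out = []
    balanced_idx = set()
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            bi, bj = calls[i].block, calls[j].block
            if bi and bj and _complementary(bi, bj):
                balanced_idx |= {i, j}
    for i, call in enumerate(calls):
        cls = "unclassified"
        if i in balanced_idx:
            cls = "balanced"
        elif matrix is not None:
            seg = call.donor_segment
            # a decay-faded edge means the physical segment continues: extend
            # it to the chromosome end for the purposes of classification
            if not call.edges_sharp[0]:
                seg = (0, seg[1])
            if not call.edges_sharp[1]:
                seg = (seg[0], matrix.bin_table.genome.length(call.donor_chrom))
            use = matrix
            # small segments wash out at scan resolution; use the fine map
            # when its cis block is still tractable
            if (fine_matrix is not None
                    and seg[1] - seg[0] < 20 * matrix.bin_table.bin_size
                    and fine_matrix.bin_table.n_chrom_bins(call.donor_chrom) <= 5000):
                use = fine_matrix
            moved = segment_moved_evidence(use, call.donor_chrom, seg, params)
            if moved is not None:
                cls = "unbalanced" if moved else "translocated_duplication"
        elif coverage is not None:
            sl = coverage.bin_table.chrom_slice(call.donor_chrom)
            bs = coverage.bin_table.bin_size
            i0 = call.donor_segment[0] // bs
            i1 = max(i0 + 1, -(-call.donor_segment[1] // bs))
            chrom_cov = coverage.values[sl]
            rest = np.concatenate([chrom_cov[:i0], chrom_cov[i1:]])
            base = float(np.median(rest)) if len(rest) >= 10 else 0.0
            if base > 0 and i1 > i0:
                mc = float(np.mean(chrom_cov[i0:i1])) / base
                cls = ("unbalanced" if mc < params.loss_coverage_max
                       else "translocated_duplication")
        out.append(replace(call, classification=cls))
    return out


def detect_translocations(
    matrix: ContactMatrix,
    reference_matrix: ContactMatrix | None = None,
    params: DetectionParams | None = None,
) -> list[SVCall]:
    """Genome-wide interchromosomal SV scan.

    Runs trans_enrichment over every chromosome pair, localizes and classifies
    each block.  With a reference map, blocks whose region is enriched in the
    reference too are vetoed as shared (putative assembly) artifacts.
    """
    params = params or DetectionParams()
    coarse = matrix.coarsen(max(params.scan_bin, matrix.bin_table.bin_size))
    ref_coarse = None
    if reference_matrix is not None:
        ref_coarse = reference_matrix.coarsen(coarse.bin_table.bin_size)
    names = matrix.bin_table.genome.names
    all_calls: list[SVCall] = []
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            A, B = names[ai], names[bi]
            blocks = trans_enrichment(coarse, A, B, params)
            if not blocks:
                continue
            if ref_coarse is not None:
                blocks = [
                    b for b in blocks
                    if not _enriched_in_reference(ref_coarse, b, params)
                ]
            pairs, unpaired = _pair_corners(blocks, params)
            calls = [
                _corner_pair_call(blocks[lo], blocks[hi], axis, matrix, params)
                for lo, hi, axis in pairs
            ]
            calls += [localize_breakpoint(blocks[k], matrix, params) for k in unpaired]
            calls = _merge_same_junction(calls, matrix.bin_table, params)
            calls = classify_translocation(
                calls, params=params, matrix=coarse, fine_matrix=matrix
            )
            all_calls.extend(calls)
    all_calls.sort(key=lambda c: (-c.score, c.donor_chrom, c.donor_segment))
    return all_calls


def _merge_same_junction(calls: list[SVCall], bin_table,
                         params: DetectionParams) -> list[SVCall]:
    """Fuse calls of one pair that share an acceptor junction.

    Leftover pieces of one insertion event (a junction corner that escaped
    block-level merging) localize to the same acceptor site but to disjoint,
    well-separated donor segments; they are one event.  Reciprocal (balanced)
    pairs share the acceptor site too, but their donor intervals meet at the
    donor breakpoint, so the donor-gap requirement protects them.
    """
    tol = 4 * params.scan_bin
    min_gap = 2 * params.scan_bin

    def site(c):
        ins = c.acceptor_insertion
        if isinstance(ins, (int, np.integer)):
            return int(ins)
        if isinstance(ins, str) and c.acceptor_chrom is not None:
            return 0 if ins.endswith("p") else bin_table.genome.length(c.acceptor_chrom)
        return None

    out: list[SVCall] = []
    used = [False] * len(calls)
    for i in range(len(calls)):
        if used[i]:
            continue
        merged = calls[i]
        for j in range(i + 1, len(calls)):
            if used[j]:
                continue
            a, b = merged, calls[j]
            if (a.donor_chrom, a.acceptor_chrom) != (b.donor_chrom, b.acceptor_chrom):
                continue
            sa, sb = site(a), site(b)
            if sa is None or sb is None or abs(sa - sb) > tol:
                continue
            gap = max(a.donor_segment[0], b.donor_segment[0]) - min(
                a.donor_segment[1], b.donor_segment[1]
            )
            # donor intervals meeting near a point are the balanced geometry
            # and stay separate; clear separation (two junction corners) or
            # substantial overlap (a sub-fragment) are one event
            if abs(gap) <= min_gap:
                continue
            # an oriented call carries the better-localized junction
            best = max(a, b, key=lambda c: (c.donor_orientation in "+-", c.score))
            seg = (min(a.donor_segment[0], b.donor_segment[0]),
                   max(a.donor_segment[1], b.donor_segment[1]))
            bp = best.donor_breakpoint
            if isinstance(bp, (int, np.integer)):
                bp = seg[0] if best.donor_orientation == "+" else (
                    seg[1] if best.donor_orientation == "-" else bp)
            merged = replace(
                best, donor_segment=seg, donor_breakpoint=bp,
                edges_sharp=(True, True),
            )
            used[j] = True
        out.append(merged)
    return out


def _enriched_in_reference(ref: ContactMatrix, block: EnrichmentBlock,
                           params: DetectionParams) -> bool:
    X = ref.dense_block(block.chromA, block.chromB)
    lam = max(float(np.median(X)), 1e-9)
    scan = ref.bin_table.bin_size
    a0, a1 = block.intervalA[0] // scan, -(-block.intervalA[1] // scan)
    b0, b1 = block.intervalB[0] // scan, -(-block.intervalB[1] // scan)
    sub = X[a0:a1, b0:b1]
    if sub.size == 0:
        return False
    z = (sub.mean() - lam) / np.sqrt(lam / sub.size)
    return z >= params.enrichment_z_min
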