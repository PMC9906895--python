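"""Intrachromosomal structural variants: coverage-based CNV segmentation and
reference-comparison detection of inversions and deletions.

CNV calling segments the per-bin log2 coverage ratio with deterministic
binary segmentation under a BIC penalty and labels segments by copy-number
thresholds.  Inversions and deletions are defined *comparatively*: an
inversion swaps the contact pattern around its ends, producing a butterfly of
enriched corners relative to a reference map of the same chromosome; a
deletion makes its flanks adjacent, enriching contacts that bridge the gap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix
from .qc import CoverageTrack
from .sv_trans import SVCall


@dataclass
class CNVParams:
    # log2-ratio state thresholds chosen to separate 1-, 0-, 3- and >=4-copy
    # states under a diploid mixture
    del_het_log2: float = -0.5
    del_hom_log2: float = -3.0
    gain_log2: float = 0.4
    ampl_log2: float = 1.0
    bic_mult: float = 2.0  # penalty multiplier per change point, x ln(n)
    min_seg_bins: int = 2
    eps: float = 1e-3


@dataclass
class CNVCall:
    chrom: str
    interval: tuple[int, int]  # bp
    log2_ratio: float
    state: str  # deletion_het | deletion_hom | gain | amplification
    boundary_uncertainty_bins: int = 1


@dataclass
class InversionParams:
    grid_step_bins: int = 4
    min_inv_bins: int = 8
    box_bins: int = 4
    score_min: float = 0.4
    pseudocount: float = 1.0


def _binary_segmentation(x: np.ndarray, penalty: float, min_seg: int) -> list[int]:
    """Change points (sorted) minimizing SSE with a per-split penalty.

    Greedy recursive splitting with a two-split lookahead: a single split is
    accepted when its SSE reduction beats the penalty; when no single split
    pays for itself, the best *pair* of splits is tried against twice the
    penalty.  The lookahead is what lets a short bump (a deletion or
    amplification flanked by two nearby change points, where neither split
    helps alone) be found.  Deterministic.
    """

    def sse_tables(y):
        c = np.concatenate([[0.0], np.cumsum(y)])
        c2 = np.concatenate([[0.0], np.cumsum(y * y)])

        def sse(a, b):
            a = np.asarray(a)
            b = np.asarray(b)
            w = np.maximum(b - a, 1)
            return (c2[b] - c2[a]) - (c[b] - c[a]) ** 2 / w

        return sse

    def best_split(lo, hi):
        y = x[lo:hi]
        n = len(y)
        if n < 2 * min_seg:
            return None
        sse = sse_tables(y)
        tot = float(sse(0, n))
        ks = np.arange(min_seg, n - min_seg + 1)
        gain = tot - (sse(0, ks) + sse(ks, n))
        k = int(np.argmax(gain))
        return float(gain[k]), lo + int(ks[k])

    def best_pair(lo, hi):
        y = x[lo:hi]
        n = len(y)
        if n < 3 * min_seg:
            return None
        sse = sse_tables(y)
        tot = float(sse(0, n))
        best = (-np.inf, 0, 0)
        for a in range(min_seg, n - 2 * min_seg + 1):
            bs = np.arange(a + min_seg, n - min_seg + 1)
            gain = tot - (float(sse(0, a)) + sse(a, bs) + sse(bs, n))
            k = int(np.argmax(gain))
            if gain[k] > best[0]:
                best = (float(gain[k]), a, int(bs[k]))
        return best

    cps: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        res = best_split(lo, hi)
        if res is None:
            continue
        gain, cp = res
        if gain > penalty:
            cps.append(cp)
            stack.append((lo, cp))
            stack.append((cp, hi))
            continue
        pair = best_pair(lo, hi)
        if pair is not None and pair[0] > 2 * penalty:
            _, a, b = pair
            cps.extend([lo + a, lo + b])
            stack.append((lo, lo + a))
            stack.append((lo + a, lo + b))
            stack.append((lo + b, hi))
    return sorted(cps)


def _classify_state(mean_log2: float, p: CNVParams) -> str | None:
    if mean_log2 <= p.del_hom_log2:
        return "deletion_hom"
    if mean_log2 <= p.del_het_log2:
        return "deletion_het"
    if mean_log2 >= p.ampl_log2:
        return "amplification"
    if mean_log2 >= p.gain_log2:
        return "gain"
    return None


def cnv_segments(
    coverage: CoverageTrack,
    reference_coverage: CoverageTrack | None = None,
    params: CNVParams | None = None,
) -> list[CNVCall]:
    """Copy-number segments from a normalized coverage track.

    The log2 ratio of coverage to the reference (or to the diploid baseline 1)
    is segmented per chromosome; segment means beyond the state thresholds
    become calls.  Scaling the coverage by any positive constant leaves the
    segmentation unchanged up to that constant's log2 offset in the neutral
    level, so tracks should be median-normalized first.
    """
    params = params or CNVParams()
    bt = coverage.bin_table
    calls: list[CNVCall] = []
    for chrom in bt.genome.names:
        vals = coverage.chrom_values(chrom).astype(float)
        if reference_coverage is not None:
            ref = reference_coverage.chrom_values(chrom).astype(float)
        else:
            ref = np.ones_like(vals)
        x = np.log2((vals + params.eps) / (ref + params.eps))
        n = len(x)
        if n < 2 * params.min_seg_bins:
            continue
        # robust noise scale from successive differences
        d = np.diff(x)
        sigma2 = max((np.median(np.abs(d)) / 0.6745) ** 2 / 2, 1e-6)
        penalty = params.bic_mult * sigma2 * np.log(n)
        cps = _binary_segmentation(x, penalty, params.min_seg_bins)
        bounds = [0] + cps + [n]
        bs = bt.bin_size
        chrom_len = bt.genome.length(chrom)
        chrom_calls: list[CNVCall] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mean = float(np.mean(x[lo:hi]))
            state = _classify_state(mean, params)
            if state is None:
                continue
            call = CNVCall(chrom, (lo * bs, min(hi * bs, chrom_len)), mean, state)
            prev = chrom_calls[-1] if chrom_calls else None
            if prev and prev.state == state and prev.interval[1] == call.interval[0]:
                w1 = prev.interval[1] - prev.interval[0]
                w2 = call.interval[1] - call.interval[0]
                chrom_calls[-1] = CNVCall(
                    chrom, (prev.interval[0], call.interval[1]),
                    (prev.log2_ratio * w1 + mean * w2) / (w1 + w2), state,
                )
            else:
                chrom_calls.append(call)
        calls.extend(chrom_calls)
    return calls


def write_cnv_bed(calls, path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.interval[0]}\t{c.interval[1]}\t{c.state}\t{c.log2_ratio:.3f}\n"
            )


# ---------------------------------------------------------------------------
# inversions
# ---------------------------------------------------------------------------

def _log_ratio(obs: np.ndarray, ref: np.ndarray, pc: float) -> np.ndarray:
    # depth-match the reference before comparing
    s = obs.sum() / max(ref.sum(), 1.0)
    return np.log((obs + pc) / (ref * s + pc))


def _box_mean(L: np.ndarray, r0, r1, c0, c1) -> float:
    r0, r1 = max(0, r0), min(L.shape[0], r1)
    c0, c1 = max(0, c0), min(L.shape[1], c1)
    if r1 <= r0 or c1 <= c0:
        return 0.0
    return float(L[r0:r1, c0:c1].mean())


def _butterfly_score(L: np.ndarray, a: int, b: int, w: int) -> float:
    """Inversion corner score at candidate end bins (a, b).

    An inversion of [a, b] maps x to a+b-x, so contacts between just-outside-a
    and just-inside-b (and between just-inside-a's image and just-outside-b)
    are enriched relative to the reference, while the opposite corners are not.
    """
    enr = _box_mean(L, a - w, a, b - w, b) + _box_mean(L, a, a + w, b, b + w)
    ctl = _box_mean(L, a - w, a, b, b + w) + _box_mean(L, a, a + w, b - w, b)
    return (enr - ctl) / 2.0


def detect_inversion(
    matrix: ContactMatrix,
    reference_matrix: ContactMatrix,
    chrom: str,
    params: InversionParams | None = None,
) -> list[SVCall]:
    """Inversions on one chromosome, detected against a reference map."""
    if reference_matrix is None:
        raise ValueError("inversion detection requires a reference map")
    params = params or InversionParams()
    obs = matrix.dense_block(chrom, chrom)
    ref = reference_matrix.coarsen(matrix.bin_table.bin_size).dense_block(chrom, chrom)
    if obs.shape != ref.shape:
        raise ValueError("reference map is on a different grid")
    L = _log_ratio(obs, ref, params.pseudocount)
    n = len(L)
    step, w = params.grid_step_bins, params.box_bins
    best: dict[tuple[int, int], float] = {}
    cands = []
    for a in range(w, n - params.min_inv_bins, step):
        for b in range(a + params.min_inv_bins, n - 1, step):
            s = _butterfly_score(L, a, b, w)
            if s > params.score_min:
                cands.append((s, a, b))
    # greedy non-overlapping selection with local refinement
    cands.sort(reverse=True)
    taken: list[tuple[int, int, float]] = []
    for s, a, b in cands:
        if any(not (b <= ta or tb <= a) for ta, tb, _ in taken):
            continue
        # local search on both ends
        improved = True
        while improved:
            improved = False
            for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                na, nb = a + da, b + db
                if w <= na < nb < n:
                    ns = _butterfly_score(L, na, nb, w)
                    if ns > s:
                        s, a, b = ns, na, nb
                        improved = True
        taken.append((a, b, s))
    bs = matrix.bin_table.bin_size
    chrom_len = matrix.bin_table.genome.length(chrom)
    calls = [
        SVCall(
            kind="inversion",
            donor_chrom=chrom,
            donor_segment=(a * bs, min(b * bs, chrom_len)),
            donor_breakpoint=a * bs,
            donor_orientation="-",
            score=s,
            uncertainty_bp=params.grid_step_bins * bs,
        )
        for a, b, s in sorted(taken)
    ]
    return calls


def inversion_score(matrix, reference_matrix, chrom, a_bp, b_bp,
                    params: InversionParams | None = None) -> float:
    """Butterfly score for one candidate inversion interval (for diagnostics)."""
    params = params or InversionParams()
    obs = matrix.dense_block(chrom, chrom)
    ref = reference_matrix.coarsen(matrix.bin_table.bin_size).dense_block(chrom, chrom)
    L = _log_ratio(obs, ref, params.pseudocount)
    bs = matrix.bin_table.bin_size
    return _butterfly_score(L, a_bp // bs, b_bp // bs, params.box_bins)


# ---------------------------------------------------------------------------
# deletions seen in the contact pattern
# ---------------------------------------------------------------------------

def detect_cis_deletion(
    matrix: ContactMatrix,
    reference_matrix: ContactMatrix,
    chrom: str,
    coverage: CoverageTrack | None = None,
    reference_coverage: CoverageTrack | None = None,
    cnv_params: CNVParams | None = None,
    bridge_box_bins: int = 4,
    pseudocount: float = 1.0,
) -> list[SVCall]:
    """Deletions on one chromosome, from coverage loss plus bridge enrichment.

    Candidate intervals come from CNV segmentation of the coverage track; each
    is scored by the contact enrichment between its flanks (which become
    adjacent on the deleted homologue) relative to the reference map.
    """
    if reference_matrix is None:
        raise ValueError("deletion detection requires a reference map")
    from .qc import coverage_track

    cov = coverage or coverage_track(matrix, normalized=True)
    ref_cov = reference_coverage
    cands = [
        c for c in cnv_segments(cov, ref_cov, cnv_params)
        if c.chrom == chrom and c.state in ("deletion_het", "deletion_hom")
    ]
    if not cands:
        return []
    obs = matrix.dense_block(chrom, chrom)
    ref = reference_matrix.coarsen(matrix.bin_table.bin_size).dense_block(chrom, chrom)
    L = _log_ratio(obs, ref, pseudocount)
    bs = matrix.bin_table.bin_size
    w = bridge_box_bins
    out = []
    for c in cands:
        a = c.interval[0] // bs
        b = -(-c.interval[1] // bs)
        bridge = _box_mean(L, a - w, a, b, b + w)
        out.append(
            SVCall(
                kind="deletion",
                donor_chrom=chrom,
                donor_segment=c.interval,
                donor_breakpoint=c.interval[0],
                donor_orientation="+",
                classification=("homozygous" if c.state == "deletion_hom"
                                else "heterozygous"),
                score=float(bridge),
                uncertainty_bp=bs,
            )
        )
    return out
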