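"""Karyotype edits and derivative chromosomes.

A karyotype is represented as haplotypes, each an ordered list of derivative
chromosomes; a derivative chromosome is an ordered list of oriented reference
segments.  Edits are expressed in reference coordinates and resolved through
the current haplotype mapping, so a list of edits applies sequentially the way
rearrangements are tabulated from a Hi-C map.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome import BinTable, GenomeModel

EDIT_KINDS = (
    "translocation",
    "deletion",
    "inversion",
    "duplication",
    "whole_chrom_gain",
)


@dataclass(frozen=True)
class Segment:
    """Oriented reference interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    orientation: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment interval {self.chrom}:{self.start}-{self.end}")
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def flipped(self) -> "Segment":
        return replace(self, orientation="-" if self.orientation == "+" else "+")


@dataclass
class DerivativeChromosome:
    name: str
    segments: list[Segment]

    def __post_init__(self):
        if not self.segments:
            raise ValueError(f"derivative {self.name!r} has no segments")

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class KaryotypeEdit:
    edit_kind: str
    donor_chrom: str
    donor_start: int
    donor_end: int
    orientation: str = "+"
    acceptor_chrom: str | None = None
    insertion: int | str | None = None  # bp position or "ter:p"/"ter:q"/"ter"
    mode: str = "moved"  # moved | duplicated
    balanced: bool = False
    affected_haplotype: int = 1
    name: str | None = None

    def __post_init__(self):
        if self.edit_kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.edit_kind!r}")
        if self.edit_kind != "whole_chrom_gain" and not (0 <= self.donor_start < self.donor_end):
            raise ValueError(f"bad donor interval {self.donor_start}-{self.donor_end}")
        if self.mode not in ("moved", "duplicated"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.edit_kind == "translocation" and self.acceptor_chrom is None:
            raise ValueError("translocation needs an acceptor chromosome")

    def validate(self, genome: GenomeModel) -> None:
        L = genome.length(self.donor_chrom)
        if self.edit_kind == "whole_chrom_gain":
            return
        if self.donor_end > L:
            raise ValueError(
                f"donor interval {self.donor_chrom}:{self.donor_start}-{self.donor_end} "
                f"exceeds chromosome length {L}"
            )
        if self.edit_kind == "translocation":
            ins = self.insertion
            if isinstance(ins, str):
                if ins not in ("ter", "ter:p", "ter:q"):
                    raise ValueError(f"bad insertion sentinel {ins!r}")
            elif ins is None or not (0 <= int(ins) <= genome.length(self.acceptor_chrom)):
                raise ValueError(f"insertion site {ins!r} outside {self.acceptor_chrom}")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return (
            f"{self.edit_kind}:{self.donor_chrom}:{self.donor_start}-{self.donor_end}"
            + (f"->{self.acceptor_chrom}:{self.insertion}" if self.acceptor_chrom else "")
        )


class EditConflictError(ValueError):
    pass


def identity_haplotypes(genome: GenomeModel) -> list[list[DerivativeChromosome]]:
    """Wild-type haplotypes: haplotype 0 carries every chromosome, haplotype 1
    carries chromosomes with ploidy >= 2; extra ploidy goes to haplotype 0 copies."""
    haps: list[list[DerivativeChromosome]] = [[], []]
    for c in genome.chromosomes:
        seg = Segment(c.name, 0, c.length)
        if c.ploidy >= 1:
            haps[0].append(DerivativeChromosome(c.name, [seg]))
        if c.ploidy >= 2:
            haps[1].append(DerivativeChromosome(c.name, [seg]))
        for k in range(2, c.ploidy):
            haps[0].append(DerivativeChromosome(f"{c.name}__copy{k}", [seg]))
    return haps


@dataclass
class DerivativeKaryotype:
    """Per-haplotype derivative chromosome lists plus the genome they edit.

    ``weights`` (optional, same length as ``haplotypes``) are cell-population
    fractions; when absent the simulator uses (1-w, w) from its parameters.
    """

    genome: GenomeModel
    haplotypes: list[list[DerivativeChromosome]]
    weights: list[float] | None = None
    edits: list[KaryotypeEdit] = field(default_factory=list)

    @classmethod
    def identity(cls, genome: GenomeModel) -> "DerivativeKaryotype":
        return cls(genome, identity_haplotypes(genome))

    def copy_number(self, bin_table: BinTable) -> np.ndarray:
        """Integer per-reference-bin count of covering haplotype segments."""
        track = np.zeros(bin_table.n_bins, dtype=int)
        for hap in self.haplotypes:
            for der in hap:
                for seg in der.segments:
                    i0 = bin_table.bin_id(seg.chrom, seg.start)
                    i1 = bin_table.bin_id(seg.chrom, max(seg.start, seg.end - 1))
                    track[i0 : i1 + 1] += 1
        return track

    def haplotype_weights(self, het_weight: float = 0.5) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.haplotypes):
                raise ValueError("weights/haplotypes length mismatch")
            return w
        if len(self.haplotypes) != 2:
            raise ValueError("explicit weights required for >2 haplotypes")
        return np.array([1.0 - het_weight, het_weight])


def _split_segment(seg: Segment, pos: int) -> list[Segment]:
    """Split ``seg`` at reference position ``pos`` (if interior), preserving order."""
    if not (seg.start < pos < seg.end):
        return [seg]
    left = Segment(seg.chrom, seg.start, pos, seg.orientation)
    right = Segment(seg.chrom, pos, seg.end, seg.orientation)
    return [left, right] if seg.orientation == "+" else [right, left]


def _split_hap_at(hap: list[DerivativeChromosome], chrom: str, pos: int) -> None:
    for der in hap:
        new: list[Segment] = []
        for seg in der.segments:
            if seg.chrom == chrom:
                new.extend(_split_segment(seg, pos))
            else:
                new.append(seg)
        der.segments = new


def _extract_run(
    hap: list[DerivativeChromosome], chrom: str, start: int, end: int, *, remove: bool
) -> list[Segment]:
    """Collect the segments covering reference ``chrom:start-end`` after splitting.

    The interval must form one contiguous run inside a single derivative
    chromosome (it does unless earlier edits already dismembered it).
    Returns the run in derivative order; removes it when ``remove``.
    """
    _split_hap_at(hap, chrom, start)
    _split_hap_at(hap, chrom, end)

    def inside(seg: Segment) -> bool:
        return seg.chrom == chrom and seg.start >= start and seg.end <= end

    target = end - start
    found = None
    any_hit = False
    for der in hap:
        k = 0
        while k < len(der.segments) and found is None:
            if not inside(der.segments[k]):
                k += 1
                continue
            any_hit = True
            covered = 0
            j = k
            while j < len(der.segments) and inside(der.segments[j]) and covered < target:
                covered += der.segments[j].length
                j += 1
            if covered == target:
                span = {(s.start, s.end) for s in der.segments[k:j]}
                lo = min(s for s, _ in span)
                hi = max(e2 for _, e2 in span)
                if lo == start and hi == end:
                    found = (der, list(range(k, j)))
                    break
            k = j if j > k else k + 1
        if found:
            break
    if found is None:
        if not any_hit:
            raise EditConflictError(
                f"donor interval {chrom}:{start}-{end} absent from haplotype"
            )
        raise EditConflictError(
            f"donor interval {chrom}:{start}-{end} is no longer intact "
            "(disrupted by an earlier edit)"
        )
    der, idx = found
    run = [der.segments[k] for k in idx]
    if remove:
        der.segments = [s for k, s in enumerate(der.segments) if k not in set(idx)]
        if not der.segments:
            hap.remove(der)
    else:
        run = list(run)
    return run


def _oriented(run: list[Segment], orientation: str) -> list[Segment]:
    if orientation == "+":
        return list(run)
    return [s.flipped() for s in reversed(run)]


def _insert_at_ter(hap, chrom: str, arm: str, payload: list[Segment], genome: GenomeModel):
    """Append ``payload`` beyond the terminal reference bp of the named arm."""
    L = genome.length(chrom)
    target = None
    for der in hap:
        for k, seg in enumerate(der.segments):
            if seg.chrom != chrom:
                continue
            if arm == "q" and seg.end == L:
                target = (der, k, seg)
            elif arm == "p" and seg.start == 0:
                target = (der, k, seg)
    if target is None:
        raise EditConflictError(f"cannot find {chrom}{arm} terminus in haplotype")
    der, k, seg = target
    at_right = (arm == "q") == (seg.orientation == "+")
    if at_right:
        der.segments = der.segments[: k + 1] + payload + der.segments[k + 1 :]
    else:
        der.segments = der.segments[:k] + _oriented(payload, "-") + der.segments[k:]


def apply_edits(genome, edits: Sequence[KaryotypeEdit]) -> DerivativeKaryotype:
    """Apply edits sequentially and return the resulting karyotype.

    Each edit names the haplotype it affects; donor/acceptor coordinates are
    reference coordinates resolved through the current haplotype state.  An
    unbalanced moved translocation removes the donor interval from the edited
    haplotype and inserts it, with orientation, at the acceptor site;
    ``mode="duplicated"`` leaves the donor intact (translocated duplication).
    """
    from .genome import make_genome

    genome = make_genome(genome)
    kt = DerivativeKaryotype.identity(genome)
    consumed: list[tuple[int, str, int, int, KaryotypeEdit]] = []
    for edit in edits:
        edit.validate(genome)
        h = edit.affected_haplotype
        while h >= len(kt.haplotypes):
            kt.haplotypes.append([])
        hap = kt.haplotypes[h]
        if edit.edit_kind != "whole_chrom_gain" and edit.mode == "moved":
            for (ph, pc, ps, pe, prev) in consumed:
                if (
                    ph == h
                    and pc == edit.donor_chrom
                    and edit.donor_start < pe
                    and ps < edit.donor_end
                ):
                    raise EditConflictError(
                        f"edits overlap on haplotype {h}: {prev.label!r} and {edit.label!r}"
                    )
        try:
            _apply_one(kt, genome, hap, edit)
        except EditConflictError as exc:
            raise EditConflictError(f"{edit.label}: {exc}") from exc
        if edit.edit_kind in ("translocation", "deletion") and edit.mode == "moved":
            consumed.append((h, edit.donor_chrom, edit.donor_start, edit.donor_end, edit))
        kt.edits.append(edit)
    return kt


def _apply_one(kt, genome, hap, edit: KaryotypeEdit) -> None:
    kind = edit.edit_kind
    if kind == "whole_chrom_gain":
        c = genome[edit.donor_chrom]
        hap.append(
            DerivativeChromosome(f"{c.name}__gain", [Segment(c.name, 0, c.length)])
        )
        return
    if kind == "deletion":
        _extract_run(hap, edit.donor_chrom, edit.donor_start, edit.donor_end, remove=True)
        return
    if kind == "inversion":
        run = _extract_run(hap, edit.donor_chrom, edit.donor_start, edit.donor_end, remove=False)
        # locate and reverse the run in place
        for der in hap:
            for k in range(len(der.segments)):
                if der.segments[k : k + len(run)] == run:
                    der.segments[k : k + len(run)] = _oriented(run, "-")
                    return
        raise EditConflictError("inversion target run not found")
    if kind == "duplication":
        run = _extract_run(hap, edit.donor_chrom, edit.donor_start, edit.donor_end, remove=False)
        for der in hap:
            for k in range(len(der.segments)):
                if der.segments[k : k + len(run)] == run:
                    der.segments[k + len(run) : k + len(run)] = [
                        Segment(s.chrom, s.start, s.end, s.orientation) for s in run
                    ]
                    return
        raise EditConflictError("duplication target run not found")
    # translocation
    payload = _oriented(
        _extract_run(
            hap, edit.donor_chrom, edit.donor_start, edit.donor_end,
            remove=(edit.mode == "moved"),
        ),
        edit.orientation,
    )
    ins = edit.insertion
    if isinstance(ins, str):
        arm = ins.split(":")[1] if ":" in ins else "q"
        _insert_at_ter(hap, edit.acceptor_chrom, arm, payload, genome)
    else:
        pos = int(ins)
        _split_hap_at(hap, edit.acceptor_chrom, pos)
        target = None
        for der in hap:
            for k, seg in enumerate(der.segments):
                if seg.chrom != edit.acceptor_chrom:
                    continue
                if seg.orientation == "+" and seg.start == pos and pos > 0:
                    target = (der, k)
                elif seg.orientation == "+" and pos == 0 and seg.start == 0:
                    target = (der, k)
                elif seg.orientation == "-" and seg.end == pos:
                    target = (der, k)
        if target is None:
            # position at acceptor chromosome end: append after the last bp
            if pos == genome.length(edit.acceptor_chrom):
                _insert_at_ter(hap, edit.acceptor_chrom, "q", payload, genome)
                return
            raise EditConflictError(
                f"insertion site {edit.acceptor_chrom}:{pos} absent from haplotype"
            )
        der, k = target
        der.segments = der.segments[:k] + payload + der.segments[k:]
    if edit.balanced:
        # reciprocal exchange: the acceptor tail distal to the insertion point
        # moves onto the donor gap (terminal donor segments only)
        if edit.donor_end != genome.length(edit.donor_chrom) or not isinstance(ins, int):
            raise EditConflictError(
                "balanced translocations are modeled as terminal tail swaps"
            )
        tail = _extract_run(
            hap, edit.acceptor_chrom, int(ins), genome.length(edit.acceptor_chrom), remove=True
        )
        # weld the tail where the donor segment was cut off
        for der in hap:
            if der.segments and der.segments[-1].chrom == edit.donor_chrom and \
                    der.segments[-1].end == edit.donor_start:
                der.segments.extend(tail)
                return
        raise EditConflictError("donor cut end not found for reciprocal tail")
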