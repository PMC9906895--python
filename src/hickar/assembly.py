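"""Breakpoint graph and derivative-chromosome reconstruction.

Chromosomes are cut at every called breakpoint; the resulting oriented
segments are graph nodes.  Reference adjacencies (consecutive segments) and
novel adjacencies (one per translocation call, at the junction ends implied
by the call's orientation) are edges.  Derivatives are maximal simple paths
through the graph; because a rearranged cell retains wild-type homologues and
the evidence rarely pins a single history, reconstructions are emitted as
ranked alternatives, never a single truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .edits import DerivativeChromosome, Segment
from .genome import GenomeModel
from .qc import CoverageTrack
from .sv_trans import SVCall


@dataclass(frozen=True)
class SegNode:
    chrom: str
    start: int
    end: int

    def __str__(self):
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class Adjacency:
    end_a: tuple[SegNode, str]  # (segment, 'L'|'R')
    end_b: tuple[SegNode, str]
    kind: str  # reference | novel
    calls: list[SVCall] = field(default_factory=list)
    conflict: bool = False

    @property
    def score(self) -> float:
        return sum(c.score for c in self.calls)


@dataclass
class BreakpointGraph:
    genome: GenomeModel
    nodes: list[SegNode]
    adjacencies: list[Adjacency]

    def edges_at(self, end: tuple[SegNode, str]) -> list[Adjacency]:
        return [a for a in self.adjacencies if end in (a.end_a, a.end_b)]


def _cut_positions(calls: Sequence[SVCall], genome: GenomeModel) -> dict[str, list[int]]:
    cuts: dict[str, set[int]] = {c.name: set() for c in genome.chromosomes}
    for call in calls:
        s, e = call.donor_segment
        L = genome.length(call.donor_chrom)
        cuts[call.donor_chrom] |= {x for x in (s, e) if 0 < x < L}
        if call.acceptor_chrom is not None and isinstance(call.acceptor_insertion, (int, np.integer)):
            p = int(call.acceptor_insertion)
            if 0 < p < genome.length(call.acceptor_chrom):
                cuts[call.acceptor_chrom].add(p)
    return {c: sorted(v) for c, v in cuts.items()}


def build_breakpoint_graph(calls: Sequence[SVCall], genome) -> BreakpointGraph:
    """Cut chromosomes at all call breakpoints and wire evidence edges."""
    from .genome import make_genome

    genome = make_genome(genome)
    cuts = _cut_positions(calls, genome)
    segs: dict[str, list[SegNode]] = {}
    nodes: list[SegNode] = []
    for c in genome.chromosomes:
        bounds = [0] + cuts[c.name] + [c.length]
        segs[c.name] = [
            SegNode(c.name, a, b) for a, b in zip(bounds[:-1], bounds[1:])
        ]
        nodes.extend(segs[c.name])
    # reference adjacencies, except those severed where a moved (non-
    # duplicated) donor segment was cut out of its chromosome
    severed: dict[str, set[int]] = {c.name: set() for c in genome.chromosomes}
    for call in calls:
        if call.kind not in ("translocation", "terminal_fusion"):
            continue
        if call.classification == "translocated_duplication":
            continue
        s, e = call.donor_segment
        L = genome.length(call.donor_chrom)
        severed[call.donor_chrom] |= {x for x in (s, e) if 0 < x < L}
    adjacencies: list[Adjacency] = []
    for c in genome.chromosomes:
        run = segs[c.name]
        for a, b in zip(run[:-1], run[1:]):
            if a.end in severed[c.name]:
                continue
            adjacencies.append(Adjacency((a, "R"), (b, "L"), "reference"))

    def seg_run(chrom, start, end):
        return [s for s in segs[chrom] if s.start >= start and s.end <= end]

    def add_novel(end_a, end_b, call):
        for adj in adjacencies:
            if adj.kind == "novel" and {adj.end_a, adj.end_b} == {end_a, end_b}:
                adj.calls.append(call)
                return
        # contradictory orientation evidence for the same junction pair is
        # retained on both edges, flagged
        new = Adjacency(end_a, end_b, "novel", [call])
        for adj in adjacencies:
            if adj.kind == "novel" and {adj.end_a[0], adj.end_b[0]} == {end_a[0], end_b[0]}:
                adj.conflict = True
                new.conflict = True
        adjacencies.append(new)

    for call in calls:
        if call.kind not in ("translocation", "terminal_fusion"):
            continue
        run = seg_run(call.donor_chrom, *call.donor_segment)
        if not run:
            continue
        if call.donor_orientation == "-":
            junction = (run[-1], "R")
            far = (run[0], "L")
        else:
            junction = (run[0], "L")
            far = (run[-1], "R")
        if call.acceptor_chrom is None:
            continue
        acc = segs[call.acceptor_chrom]
        ins = call.acceptor_insertion
        if isinstance(ins, (int, np.integer)):
            p = int(ins)
            left = [s for s in acc if s.end == p]
            right = [s for s in acc if s.start == p]
            if left:
                add_novel((left[0], "R"), junction, call)
            if right:
                add_novel((right[0], "L"), far, call)
            if not left and not right and p == 0:
                add_novel((acc[0], "L"), junction, call)
        else:  # ter sentinel
            arm = str(ins).split(":")[1] if ":" in str(ins) else "q"
            if arm == "p":
                add_novel((acc[0], "L"), junction, call)
            else:
                add_novel((acc[-1], "R"), junction, call)
    return BreakpointGraph(genome, nodes, adjacencies)


@dataclass
class Reconstruction:
    derivative: DerivativeChromosome
    score: float
    novel_edges: int
    cyclic: bool = False


def reconstruct_derivatives(graph: BreakpointGraph, max_alternatives: int = 20
                            ) -> list[Reconstruction]:
    """Ranked candidate derivative chromosomes (maximal simple paths).

    Paths must use at least one novel adjacency; branch points yield multiple
    alternatives ranked by total evidence score.  Components where every end
    is saturated (cycles) are reported as cyclic and not emitted as linear
    chromosomes.
    """
    end_adj: dict[tuple[SegNode, str], list[Adjacency]] = {}
    for adj in graph.adjacencies:
        end_adj.setdefault(adj.end_a, []).append(adj)
        end_adj.setdefault(adj.end_b, []).append(adj)

    results: list[Reconstruction] = []
    seen_paths: set[tuple] = set()

    def other_end(adj: Adjacency, end):
        return adj.end_b if adj.end_a == end else adj.end_a

    def walk(entry: tuple[SegNode, str], used: set[SegNode],
             path: list[tuple[SegNode, str]], novel: list[Adjacency]):
        """entry = (segment, side entered at); traverse and extend."""
        seg, side = entry
        path = path + [(seg, side)]
        used = used | {seg}
        exit_end = (seg, "R" if side == "L" else "L")
        nxt = [
            a for a in end_adj.get(exit_end, [])
            if other_end(a, exit_end)[0] not in used
        ]
        extended = False
        for a in nxt:
            ne = other_end(a, exit_end)
            walk(ne, used, path, novel + ([a] if a.kind == "novel" else []))
            extended = True
        if not extended and novel:
            key = tuple((str(s), d) for s, d in path)
            rkey = tuple((str(s), "L" if d == "R" else "R") for s, d in reversed(path))
            if rkey in seen_paths or key in seen_paths:
                return
            seen_paths.add(key)
            segments = [
                Segment(s.chrom, s.start, s.end, "+" if d == "L" else "-")
                for s, d in path
            ]
            name = "der(" + ",".join(dict.fromkeys(s.chrom for s, _ in path)) + ")"
            results.append(
                Reconstruction(
                    DerivativeChromosome(name, segments),
                    score=sum(a.score for a in novel),
                    novel_edges=len(novel),
                )
            )

    # start walks from free ends (telomeres of the adjacency graph)
    free_ends = [
        (s, side)
        for s in graph.nodes
        for side in ("L", "R")
        if not end_adj.get((s, side))
    ]
    for end in free_ends:
        walk(end, set(), [], [])

    # saturated components containing novel edges are cycles
    if not results and any(a.kind == "novel" for a in graph.adjacencies):
        involved = {
            s for a in graph.adjacencies if a.kind == "novel"
            for s in (a.end_a[0], a.end_b[0])
        }
        if involved and not any(
            (s, side) in [e for e in free_ends] for s in involved for side in ("L", "R")
        ):
            name = "cycle(" + ",".join(sorted({s.chrom for s in involved})) + ")"
            results.append(
                Reconstruction(
                    DerivativeChromosome(
                        name, [Segment(s.chrom, s.start, s.end) for s in sorted(
                            involved, key=lambda s: (s.chrom, s.start))]
                    ),
                    score=0.0, novel_edges=0, cyclic=True,
                )
            )

    results.sort(
        key=lambda r: (-r.score, -len(r.derivative.segments),
                       r.derivative.segments[0].chrom,
                       r.derivative.segments[0].start)
    )
    return results[:max_alternatives]


def estimate_chromosome_count(
    derivatives: Sequence[DerivativeChromosome | Reconstruction],
    coverage: CoverageTrack | dict[str, float] | None,
    genome,
) -> int:
    """Estimated chromosome count: intact reference copies plus derivatives.

    Per-chromosome copy numbers come from normalized read coverage (diploid
    baseline 1.0, so copies = round(2 x median coverage)); each derivative
    that absorbs at least half of a chromosome consumes one of its copies.
    """
    from .genome import make_genome

    genome = make_genome(genome)
    ders = [
        d.derivative if isinstance(d, Reconstruction) else d for d in derivatives
    ]
    copies: dict[str, int] = {}
    for c in genome.chromosomes:
        if coverage is None:
            copies[c.name] = c.ploidy
        elif isinstance(coverage, dict):
            copies[c.name] = int(round(coverage[c.name]))
        else:
            med = float(np.median(coverage.chrom_values(c.name)))
            copies[c.name] = int(round(2 * med))
    consumed: dict[str, int] = {c.name: 0 for c in genome.chromosomes}
    for der in ders:
        per_chrom: dict[str, int] = {}
        for seg in der.segments:
            per_chrom[seg.chrom] = per_chrom.get(seg.chrom, 0) + seg.length
        for chrom, covered in per_chrom.items():
            if covered >= 0.5 * genome.length(chrom):
                consumed[chrom] += 1
    total = sum(max(0, copies[c] - consumed[c]) for c in copies)
    return total + len(ders)
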