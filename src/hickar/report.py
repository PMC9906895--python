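"""Standard-format writers (BEDPE, BED, bedGraph, AGP v2.1, TSV, JSON manifest)."""
from __future__ import annotations

import json
import os
from dataclasses import asdict, is_dataclass
from typing import Sequence

from .assembly import Reconstruction
from .edits import DerivativeChromosome, Segment
from .sv_trans import SVCall

BEDPE_HEADER = (
    "#chromA\tstartA\tendA\tchromB\tstartB\tendB\tname\tscore\tstrand1\tstrand2"
    "\tclassification\tuncertainty_bp\n"
)


def _acceptor_interval(call: SVCall):
    ins = call.acceptor_insertion
    if ins is None:
        return ".", -1, -1
    if isinstance(ins, str):
        return call.acceptor_chrom, -1, -1
    return call.acceptor_chrom, int(ins), int(ins) + 1


def write_bedpe(calls: Sequence[SVCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(BEDPE_HEADER)
        for k, c in enumerate(calls):
            bc, b0, b1 = _acceptor_interval(c)
            ins = c.acceptor_insertion
            name = f"{c.kind}:{k}" + (f"|{ins}" if isinstance(ins, str) else "")
            strand1 = c.donor_orientation if c.donor_orientation in "+-" else "."
            fh.write(
                f"{c.donor_chrom}\t{c.donor_segment[0]}\t{c.donor_segment[1]}\t"
                f"{bc}\t{b0}\t{b1}\t{name}\t{c.score:.3f}\t{strand1}\t.\t"
                f"{c.classification}\t{c.uncertainty_bp}\n"
            )


def read_bedpe(path) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            name = f[6]
            kind = name.split(":")[0]
            ins: int | str | None
            if "|" in name:
                ins = name.split("|", 1)[1]
            elif int(f[4]) >= 0:
                ins = int(f[4])
            else:
                ins = None
            calls.append(
                SVCall(
                    kind=kind,
                    donor_chrom=f[0],
                    donor_segment=(int(f[1]), int(f[2])),
                    donor_breakpoint=int(f[1]),
                    donor_orientation=f[8] if f[8] in "+-" else "unknown",
                    acceptor_chrom=None if f[3] == "." else f[3],
                    acceptor_insertion=ins,
                    classification=f[10],
                    score=float(f[7]),
                    uncertainty_bp=int(f[11]),
                )
            )
    return calls


def write_table1_style(calls: Sequence[SVCall], path) -> None:
    """TSV mirroring the layout of a printed translocation table.

    Coordinates are 1-based in this human-facing report.
    """
    with open(path, "w") as fh:
        fh.write(
            "donor_chrom\tstart\tend\tacceptor_chrom\tinsertion_site\t"
            "orientation\tclassification\tscore\n"
        )
        for c in calls:
            ins = c.acceptor_insertion
            if isinstance(ins, str):
                site = ins
            elif ins is None:
                site = "."
            else:
                site = str(int(ins) + 1)
            fh.write(
                f"{c.donor_chrom}\t{c.donor_segment[0] + 1}\t{c.donor_segment[1]}\t"
                f"{c.acceptor_chrom or '.'}\t{site}\t{c.donor_orientation}\t"
                f"{c.classification}\t{c.score:.2f}\n"
            )


def write_agp(derivatives: Sequence[DerivativeChromosome | Reconstruction], path) -> None:
    """AGP v2.1: ordered, oriented components of each derivative chromosome."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for d in derivatives:
            der = d.derivative if isinstance(d, Reconstruction) else d
            pos = 0
            for k, seg in enumerate(der.segments, start=1):
                beg, end = pos + 1, pos + seg.length
                fh.write(
                    f"{der.name}\t{beg}\t{end}\t{k}\tW\t{seg.chrom}\t"
                    f"{seg.start + 1}\t{seg.end}\t{seg.orientation}\n"
                )
                pos = end


def read_agp(path) -> list[DerivativeChromosome]:
    ders: dict[str, list[Segment]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] != "W":
                continue
            name = f[0]
            if name not in ders:
                ders[name] = []
                order.append(name)
            ders[name].append(
                Segment(f[5], int(f[6]) - 1, int(f[7]), f[8])
            )
    return [DerivativeChromosome(n, ders[n]) for n in order]


def write_outputs(results: dict, out_dir) -> list[str]:
    """Write every available result to ``out_dir``; returns written paths.

    Recognized keys: sv_calls, inversions, cnv_calls, domains (DomainSet
    list), compartments (CompartmentTrack list), coverage (CoverageTrack),
    derivatives, params (mapping), seed.  Missing keys produce valid
    empty-but-headered files for the tabular formats.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def p(name):
        written.append(os.path.join(out_dir, name))
        return written[-1]

    write_bedpe(results.get("sv_calls", []), p("translocations.bedpe"))
    write_bedpe(results.get("inversions", []), p("inversions.bedpe"))
    write_table1_style(results.get("sv_calls", []), p("translocations.tsv"))

    from .sv_cis import write_cnv_bed

    write_cnv_bed(results.get("cnv_calls", []), p("cnv.bed"))

    with open(p("tads.bed"), "w") as fh:
        for ds in results.get("domains", []):
            for d in sorted(ds.domains, key=lambda d: (d.start_bin, -d.n_bins)):
                s = d.start_bin * ds.bin_size
                e = (d.end_bin + 1) * ds.bin_size
                fh.write(f"{ds.chrom}\t{s}\t{e}\tgamma={d.gamma:g}\t{d.score:.4f}\n")

    for tr in results.get("compartments", []):
        tr.write_bedgraph(p(f"compartments_{tr.chrom}.bedgraph"))
        tr.write_bed(p(f"compartments_{tr.chrom}.bed"))

    cov = results.get("coverage")
    if cov is not None:
        cov.write_bedgraph(p("coverage.bedgraph"))

    write_agp(results.get("derivatives", []), p("derivatives.agp"))

    manifest = {
        "seed": results.get("seed"),
        "params": _jsonable(results.get("params", {})),
        "n_sv_calls": len(results.get("sv_calls", [])),
        "n_cnv_calls": len(results.get("cnv_calls", [])),
        "n_derivatives": len(results.get("derivatives", [])),
    }
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return written


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj
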