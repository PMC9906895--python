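"""The published HD3 interchromosomal rearrangement table and planting helpers.

The 26 large (>=200 kb) translocations reported for the chicken HD3 cell line
are encoded below in reference (GalGal5-magnitude) coordinates, exactly as
printed: donor chromosome and segment, acceptor chromosome and insertion site
("ter" where the breakpoint could not be placed and the insertion is at the
terminal region of an arm).  They serve as planting input for simulations
that reproduce the cell line's contact-map phenotype.

Because several events reuse the same donor region or acceptor terminus (the
cell culture is heterogeneous with respect to translocation variants), the
full set cannot coexist on two haplotypes.  ``plant_hd3_karyotype`` therefore
partitions events into clone haplotypes such that no clone carries two events
sharing a chromosome, and mixes the clones with the wild type.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edits import DerivativeKaryotype, KaryotypeEdit, apply_edits, identity_haplotypes
from .genome import GenomeModel, hd3_genome


@dataclass(frozen=True)
class TranslocationRow:
    donor: str
    start: int
    end: int
    acceptor: str
    site: str  # "q"|"p"|"qter"|"pter"|"ter"
    position: int | None  # insertion bp when identified

    @property
    def is_ter(self) -> bool:
        return self.position is None


HD3_TRANSLOCATIONS: tuple[TranslocationRow, ...] = (
    TranslocationRow("1", 180_580_000, 194_260_000, "2", "q", 149_470_000),
    TranslocationRow("4", 0, 16_835_000, "5", "qter", 59_820_000),
    TranslocationRow("4", 18_835_000, 51_490_000, "6", "pter", 500_000),
    TranslocationRow("4", 0, 16_835_000, "7", "pter", 0),
    TranslocationRow("4", 51_505_000, 91_280_000, "17", "qter", 10_950_000),
    TranslocationRow("4", 18_835_000, 51_490_000, "19", "qter", 9_965_000),
    TranslocationRow("5", 0, 59_820_000, "9", "ter", None),
    TranslocationRow("6", 500_000, 35_460_000, "19", "ter", None),
    TranslocationRow("7", 0, 6_310_000, "5", "qter", 59_820_000),
    TranslocationRow("7", 6_145_000, 36_905_000, "27", "ter", None),
    TranslocationRow("7", 4_110_000, 36_905_000, "33", "ter", None),
    TranslocationRow("12", 0, 19_945_000, "21", "ter", None),
    TranslocationRow("12", 0, 19_945_000, "23", "qter", 5_785_000),
    TranslocationRow("13", 500_000, 18_400_000, "28", "ter", None),
    TranslocationRow("17", 505_000, 10_950_000, "28", "ter", None),
    TranslocationRow("17", 505_000, 10_950_000, "33", "ter", None),
    TranslocationRow("18", 0, 11_040_000, "3", "pter", 0),
    TranslocationRow("21", 0, 325_000, "5", "pter", 5_000),
    TranslocationRow("21", 0, 325_000, "9", "pter", 515_000),
    TranslocationRow("21", 0, 6_860_000, "23", "ter", None),
    TranslocationRow("24", 0, 6_270_000, "3", "p", 2_200_000),
    TranslocationRow("27", 0, 5_035_000, "23", "ter", None),
    TranslocationRow("28", 0, 1_140_000, "12", "ter", None),
    TranslocationRow("28", 0, 1_140_000, "21", "ter", None),
    TranslocationRow("28", 0, 1_140_000, "23", "ter", None),
    TranslocationRow("28", 0, 4_970_000, "33", "ter", None),
)


def row_to_edit(row: TranslocationRow, haplotype: int = 1,
                mode: str = "moved") -> KaryotypeEdit:
    ins: int | str
    if row.position is None:
        ins = "ter:q"
    elif row.site in ("pter", "p") and row.position == 0:
        ins = "ter:p"
    else:
        ins = int(row.position)
    return KaryotypeEdit(
        edit_kind="translocation",
        donor_chrom=row.donor,
        donor_start=row.start,
        donor_end=row.end,
        acceptor_chrom=row.acceptor,
        insertion=ins,
        mode=mode,
        affected_haplotype=haplotype,
        name=f"t({row.donor};{row.acceptor})@{row.start}",
    )


def assign_clones(rows=HD3_TRANSLOCATIONS) -> list[list[TranslocationRow]]:
    """Greedy partition of events into clones with disjoint chromosome sets.

    Within a clone no two events touch the same chromosome (as donor or
    acceptor), so every event produces exactly one junction in that clone's
    derivative chromosomes and no chained secondary adjacencies arise.
    """
    clones: list[tuple[set[str], list[TranslocationRow]]] = []
    for row in rows:
        chroms = {row.donor, row.acceptor}
        for used, members in clones:
            if not (used & chroms):
                used |= chroms
                members.append(row)
                break
        else:
            clones.append((set(chroms), [row]))
    return [members for _, members in clones]


def plant_hd3_karyotype(
    genome: GenomeModel | None = None,
    rows=HD3_TRANSLOCATIONS,
    wild_type_fraction: float = 0.5,
) -> DerivativeKaryotype:
    """Multi-clone karyotype carrying every tabulated translocation.

    Haplotype 0 is the shared wild-type genome with weight
    ``wild_type_fraction``; each clone haplotype carries a conflict-free
    subset of the events (mode=moved) and an equal share of the remaining
    weight.  The mixture reproduces both the trans-enrichment blocks of every
    event and the residual wild-type cis signal.
    """
    genome = genome or hd3_genome()
    clones = assign_clones(rows)
    kt = DerivativeKaryotype.identity(genome)
    base = identity_haplotypes(genome)
    # haplotype 0 = pooled wild type; clone haplotypes replace haplotype 1
    kt.haplotypes = [base[0]]
    for members in clones:
        edits = [row_to_edit(r, haplotype=1) for r in members]
        clone_kt = apply_edits(genome, edits)
        kt.haplotypes.append(clone_kt.haplotypes[1])
    k = len(clones)
    kt.weights = [wild_type_fraction] + [(1.0 - wild_type_fraction) / k] * k
    kt.edits = [row_to_edit(r) for r in rows]
    return kt
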