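"""Model genomes, chromosome bins and their plain-text interchange formats.

The package works throughout in 0-based half-open coordinates; report writers
convert to 1-based text only at the output boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

CHROM_CLASSES = ("macro", "micro", "sexZ", "sexW")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    chrom_class: str = "macro"
    centromere: int | None = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: non-positive length {self.length}")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"chromosome {self.name!r}: unknown class {self.chrom_class!r}")
        if self.centromere is not None and not (0 <= self.centromere < self.length):
            raise ValueError(f"chromosome {self.name!r}: centromere outside chromosome")
        if self.ploidy < 0:
            raise ValueError(f"chromosome {self.name!r}: negative ploidy")


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of named chromosomes with per-chromosome copy number."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def length(self, name: str) -> int:
        return self[name].length

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.chrom_class in ("macro", "micro")]

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length}\n")


def make_genome(config) -> GenomeModel:
    """Build a validated :class:`GenomeModel`.

    ``config`` may be a preset name (``"toy-chicken"``, ``"hd3"``), a path to a
    YAML file, a mapping with a ``chromosomes`` list, or an iterable of
    (name, length) pairs / chromosome mappings.
    """
    if isinstance(config, GenomeModel):
        return config
    if isinstance(config, str):
        if config in _PRESETS:
            return _PRESETS[config]()
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if isinstance(config, dict):
        config = config.get("chromosomes", config)
    chroms = []
    for entry in config:
        if isinstance(entry, Chromosome):
            chroms.append(entry)
        elif isinstance(entry, dict):
            chroms.append(Chromosome(**entry))
        else:
            name, length = entry[0], int(entry[1])
            chroms.append(Chromosome(name, length, *entry[2:]))
    return GenomeModel(tuple(chroms))


def toy_chicken() -> GenomeModel:
    """A reduced chicken-like genome: 5 macro- and 10 microchromosomes, Z and W.

    Macrochromosome lengths span 30-200 Mb and microchromosomes 1-12 Mb, the
    magnitudes typical of the avian karyotype; W is monosomic (ZW female).
    """
    macro = [200, 150, 110, 90, 60]
    micro = [12, 10, 9, 8, 6, 5, 4, 3, 2, 1]
    chroms = [Chromosome(f"chr{i + 1}", m * 1_000_000, "macro", centromere=m * 300_000)
              for i, m in enumerate(macro)]
    chroms += [Chromosome(f"chr{i + 6}", m * 1_000_000, "micro")
               for i, m in enumerate(micro)]
    chroms.append(Chromosome("chrZ", 80_000_000, "sexZ"))
    chroms.append(Chromosome("chrW", 7_000_000, "sexW", ploidy=1))
    return GenomeModel(tuple(chroms))


# GalGal5-magnitude lengths for the chromosomes that appear in the HD3
# rearrangement table, plus Z and W.  Microchromosomes are acrocentric.
_HD3_LENGTHS = {
    "1": (196_202_544, "macro"),
    "2": (149_560_735, "macro"),
    "3": (110_854_647, "macro"),
    "4": (91_282_656, "macro"),
    "5": (59_825_302, "macro"),
    "6": (35_467_016, "macro"),
    "7": (36_946_936, "macro"),
    "9": (24_091_566, "macro"),
    "11": (20_200_042, "micro"),
    "12": (20_315_558, "micro"),
    "13": (18_810_724, "micro"),
    "17": (11_219_875, "micro"),
    "18": (11_373_140, "micro"),
    "19": (10_323_212, "micro"),
    "21": (6_862_722, "micro"),
    "23": (6_149_580, "micro"),
    "24": (6_491_222, "micro"),
    "27": (5_313_770, "micro"),
    "28": (5_116_882, "micro"),
    "33": (1_648_031, "micro"),
    "Z": (82_310_166, "sexZ"),
    "W": (6_739_244, "sexW"),
}


def hd3_genome(include_sex: bool = True) -> GenomeModel:
    chroms = []
    for name, (length, klass) in _HD3_LENGTHS.items():
        if not include_sex and klass.startswith("sex"):
            continue
        ploidy = 1 if klass == "sexW" else 2
        chroms.append(Chromosome(name, length, klass, ploidy=ploidy))
    return GenomeModel(tuple(chroms))


_PRESETS = {"toy-chicken": toy_chicken, "hd3": hd3_genome}


class BinTable:
    """Fixed-size genomic bins tiling every chromosome without gaps.

    Bins are 0-based half-open; the last bin of each chromosome may be short.
    The global bin index runs over chromosomes in genome order.
    """

    def __init__(self, genome: GenomeModel, bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        nbins = [-(-c.length // bin_size) for c in genome.chromosomes]
        self._nbins = dict(zip(genome.names, nbins))
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        self._offsets = dict(zip(genome.names, offsets[:-1].astype(int)))
        self.n_bins = int(offsets[-1])
        self.chrom_ids = np.repeat(np.arange(len(nbins)), nbins)
        starts = np.concatenate([np.arange(n, dtype=np.int64) * bin_size for n in nbins])
        self.starts = starts
        lengths = np.repeat([c.length for c in genome.chromosomes], nbins)
        self.ends = np.minimum(starts + bin_size, lengths)

    def __len__(self) -> int:
        return self.n_bins

    def n_chrom_bins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offsets[chrom]
        return slice(o, o + self._nbins[chrom])

    def bin_id(self, chrom: str, pos: int) -> int:
        n = self._nbins[chrom]
        b = min(int(pos) // self.bin_size, n - 1)
        if pos < 0:
            raise ValueError(f"negative position {pos} on {chrom}")
        return self._offsets[chrom] + b

    def bin_chrom(self, bin_id: int) -> str:
        return self.genome.chromosomes[int(self.chrom_ids[bin_id])].name

    def bin_start(self, bin_id: int) -> int:
        return int(self.starts[bin_id])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [self.genome.chromosomes[i].name for i in self.chrom_ids],
                "start": self.starts,
                "end": self.ends,
            }
        )

    def same_grid(self, other: "BinTable") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.names == other.genome.names
            and [c.length for c in self.genome.chromosomes]
            == [c.length for c in other.genome.chromosomes]
        )
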