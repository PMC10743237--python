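"""Circular mitochondrial genome model, region tables, and pathogenicity lookups.

The human mitochondrial genome is a circular molecule of 16,569 bp whose
coordinate system (the rCRS convention, NC_012920.1) is 1-based and wraps
around the origin: the non-coding control region (D-loop) spans positions
16,024-16,569 and 1-576. All coordinates in this package are 1-based
inclusive; conversion to 0-based half-open happens only at file boundaries.

Wrap-around features are stored as two linear :class:`Region` objects that
share a name, so interval queries never have to reason about the origin.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .errors import AlphabetError, CoordinateError

RCRS_LENGTH = 16569
DLOOP_INTERVALS = ((1, 576), (16024, 16569))

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class RegionType(str, Enum):
    DLOOP = "D-loop"
    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    INTERGENIC = "intergenic"


#: priority used when a variant overlaps several features and a single
#: region must be chosen for effect classification
REGION_PRIORITY = (
    RegionType.CDS,
    RegionType.TRNA,
    RegionType.RRNA,
    RegionType.DLOOP,
    RegionType.INTERGENIC,
)


class PathogenicityCategory(str, Enum):
    CONFIRMED_PATHOGENIC_MISSENSE = "confirmed_pathogenic_missense"
    TRNA_CONFIRMED = "tRNA_confirmed"
    TRNA_LIKELY = "tRNA_likely"
    TRNA_POSSIBLY = "tRNA_possibly"
    BENIGN_UNKNOWN = "benign/unknown"


#: tRNA categories that count as deleterious
DELETERIOUS_TRNA_CATEGORIES = frozenset(
    {
        PathogenicityCategory.TRNA_CONFIRMED,
        PathogenicityCategory.TRNA_LIKELY,
        PathogenicityCategory.TRNA_POSSIBLY,
    }
)


@dataclass(frozen=True)
class CircularGenome:
    """A circular genome with 1-based coordinates wrapping modulo length."""

    sequence: str
    name: str = "rCRS"

    def __post_init__(self):
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise AlphabetError(f"genome contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, pos: int) -> int:
        """Map any integer onto a valid 1-based position on the circle."""
        return (pos - 1) % self.length + 1

    def base(self, pos: int) -> str:
        return self.sequence[self.wrap(pos) - 1]

    def fetch(self, start: int, length: int) -> str:
        """`length` bases starting at 1-based `start`, wrapping at the origin."""
        return "".join(self.base(start + k) for k in range(length))

    def check_position(self, pos: int) -> int:
        if not 1 <= pos <= self.length:
            raise CoordinateError(f"position {pos} outside [1, {self.length}]")
        return pos


@dataclass(frozen=True)
class Region:
    """One linear feature interval; wrap-around features use two Regions."""

    start: int
    end: int
    region_type: RegionType
    name: str
    strand: str = "H"
    frame_offset: int | None = None  # CDS only: codon phase of `start`

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval {self.start}-{self.end} for {self.name}"
            )
        if self.region_type is RegionType.CDS:
            if self.frame_offset is None or not 0 <= self.frame_offset <= 2:
                raise AnnotationFrameError(self.name)
        if self.strand not in ("H", "L"):
            raise CoordinateError(f"strand must be H or L, got {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class AnnotationFrameError(CoordinateError):
    def __init__(self, name):
        super().__init__(f"CDS region {name!r} requires frame_offset in 0..2")


@dataclass
class RegionTable:
    """Ordered list of regions covering every position of a circular genome."""

    regions: list[Region]
    genome_length: int

    def __post_init__(self):
        self.regions = sorted(self.regions, key=lambda r: (r.start, r.name))

    def regions_at(self, pos: int) -> list[Region]:
        if not 1 <= pos <= self.genome_length:
            raise CoordinateError(f"position {pos} outside [1, {self.genome_length}]")
        return [r for r in self.regions if r.contains(pos)]

    def is_complete(self) -> bool:
        covered = [False] * self.genome_length
        for r in self.regions:
            for p in range(r.start, r.end + 1):
                covered[p - 1] = True
        return all(covered)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "name": r.name,
                "start": r.start,
                "end": r.end,
                "type": r.region_type.value,
                "strand": r.strand,
                "frame_offset": "" if r.frame_offset is None else r.frame_offset,
            }
            for r in self.regions
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome_length: int) -> "RegionTable":
        df = pd.read_csv(path, sep="\t", dtype={"frame_offset": "object"})
        regions = []
        for row in df.itertuples(index=False):
            fo = row.frame_offset
            fo = None if pd.isna(fo) or fo == "" else int(fo)
            regions.append(
                Region(
                    start=int(row.start),
                    end=int(row.end),
                    region_type=RegionType(row.type),
                    name=str(row.name),
                    strand=str(row.strand),
                    frame_offset=fo,
                )
            )
        return cls(regions=regions, genome_length=genome_length)


def build_region_table(
    features: Iterable[tuple[int, int, RegionType | str, str]],
    genome_length: int,
    add_dloop: bool | None = None,
    strands: dict[str, str] | None = None,
    frames: dict[str, int] | None = None,
) -> RegionTable:
    """Build a complete region table from raw feature intervals.

    Positions not covered by any feature are filled with ``intergenic``
    regions. The two D-loop intervals (1-576 and 16,024-16,569) are inserted
    when absent; by default this happens only for a genome of the canonical
    mitochondrial length, since the printed coordinates are meaningless on
    toy genomes. ``strands`` / ``frames`` optionally supply per-name strand
    and CDS codon phase (defaults: H strand, frame 0).
    """
    strands = strands or {}
    frames = frames or {}
    if add_dloop is None:
        add_dloop = genome_length == RCRS_LENGTH

    regions: list[Region] = []
    for start, end, rtype, name in features:
        rtype = RegionType(rtype)
        if not (1 <= start <= genome_length and 1 <= end <= genome_length):
            raise CoordinateError(
                f"feature {name!r} {start}-{end} outside [1, {genome_length}]"
            )
        regions.append(
            Region(
                start=start,
                end=end,
                region_type=rtype,
                name=name,
                strand=strands.get(name, "H"),
                frame_offset=frames.get(name, 0) if rtype is RegionType.CDS else None,
            )
        )

    if add_dloop:
        have = {(r.start, r.end) for r in regions if r.region_type is RegionType.DLOOP}
        for start, end in DLOOP_INTERVALS:
            if (start, end) not in have:
                regions.append(
                    Region(start=start, end=end, region_type=RegionType.DLOOP, name="D-loop")
                )

    # fill every uncovered run with an intergenic region
    covered = [False] * genome_length
    for r in regions:
        for p in range(r.start, r.end + 1):
            covered[p - 1] = True
    p = 1
    while p <= genome_length:
        if not covered[p - 1]:
            q = p
            while q < genome_length and not covered[q]:
                q += 1
            regions.append(
                Region(
                    start=p,
                    end=q,
                    region_type=RegionType.INTERGENIC,
                    name=f"intergenic_{p}_{q}",
                )
            )
            p = q + 1
        else:
            p += 1

    return RegionTable(regions=regions, genome_length=genome_length)


def annotate_position(pos: int, table: RegionTable) -> list[RegionType]:
    """Region types covering `pos`, ordered by (start, name)."""
    return [r.region_type for r in table.regions_at(pos)]


def primary_region(regions: Sequence[Region]) -> Region:
    """Pick the single region used for effect classification when a position
    is covered by several features (CDS > tRNA > rRNA > D-loop > intergenic)."""
    rank = {t: i for i, t in enumerate(REGION_PRIORITY)}
    return min(regions, key=lambda r: (rank[r.region_type], r.start, r.name))


def translate_codon(codon: str) -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    Differences from the universal code matter here: TGA encodes tryptophan
    and AGA/AGG are stop codons.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise AlphabetError(f"codon must be 3 bases over ACGT, got {codon!r}")
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PathogenicityTable:
    """Lookup of curated pathogenicity labels keyed by (pos, ref, alt).

    Stands in for the web annotators used in practice (clinical missense
    catalogs and tRNA pathogenicity scores); only their interpretation
    categories are consumed, never raw scores.
    """

    records: dict[tuple[int, str, str], tuple[PathogenicityCategory, str]] = field(
        default_factory=dict
    )

    def lookup(self, pos: int, ref: str, alt: str) -> PathogenicityCategory | None:
        rec = self.records.get((pos, ref, alt))
        return rec[0] if rec else None

    @classmethod
    def from_tsv(cls, path) -> "PathogenicityTable":
        df = pd.read_csv(path, sep="\t")
        records = {}
        for row in df.itertuples(index=False):
            key = (int(row.pos), str(row.ref), str(row.alt))
            if key in records:
                raise ValueError(f"duplicate pathogenicity key {key}")
            records[key] = (PathogenicityCategory(row.category), str(row.source))
        return cls(records=records)

    def to_tsv(self, path) -> None:
        rows = [
            {"pos": k[0], "ref": k[1], "alt": k[2], "category": v[0].value, "source": v[1]}
            for k, v in sorted(self.records.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _data_path(fname: str) -> Path:
    return Path(importlib.resources.files("mthet") / "data" / fname)


def load_rcrs_regions() -> RegionTable:
    """Packaged region table with the NC_012920.1 feature layout (37 genes
    plus the two D-loop intervals, intergenic gaps filled)."""
    return RegionTable.from_tsv(_data_path("regions_rcrs.tsv"), RCRS_LENGTH)


def load_toy_regions() -> RegionTable:
    """A 2 kb toy genome layout for fast tests."""
    return RegionTable.from_tsv(_data_path("regions_toy.tsv"), 2000)


def load_pathogenicity() -> PathogenicityTable:
    return PathogenicityTable.from_tsv(_data_path("pathogenicity.tsv"))
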