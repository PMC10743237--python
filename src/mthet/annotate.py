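"""Region annotation, coding-effect classification, and deleterious calls.

Coding effects are computed from first principles — substitute the variant
base into its codon (respecting strand and the circular coordinate system)
and translate under the vertebrate mitochondrial code — rather than parsed
from an external annotator. Curated pathogenicity labels enter only through
a lookup table: a missense variant is deleterious when the table confirms
it pathogenic, a tRNA variant when its category is confirmed/likely/
possibly pathogenic, while every nonsense and frameshift variant is
deleterious unconditionally.

A frameshift is any CDS indel whose inserted/deleted base count is not
divisible by three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .calling import HetClass, VarClass, VariantCall
from .errors import AnnotationError
from .reference import (
    CircularGenome,
    DELETERIOUS_TRNA_CATEGORIES,
    PathogenicityCategory,
    PathogenicityTable,
    Region,
    RegionTable,
    RegionType,
    primary_region,
    reverse_complement,
    translate_codon,
)


class Effect(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    IN_FRAME_INDEL = "in_frame_indel"
    NONCODING = "noncoding"


class DeleteriousReason(str, Enum):
    PATHOGENIC_MISSENSE = "pathogenic_missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    PATHOGENIC_TRNA = "pathogenic_tRNA"
    NONE = "none"


@dataclass(frozen=True)
class AnnotatedVariant:
    call: VariantCall
    region_types: tuple[RegionType, ...]
    gene: str | None
    effect: Effect
    deleterious: bool
    deleterious_reason: DeleteriousReason

    # convenience passthroughs
    @property
    def pos(self) -> int:
        return self.call.pos

    @property
    def vaf(self) -> float:
        return self.call.vaf

    @property
    def sample_id(self) -> str:
        return self.call.sample_id


def _codon_at(genome: CircularGenome, region: Region, pos: int) -> tuple[str, int]:
    """The coding-strand codon containing `pos` and the variant's 0-based
    offset within it. Handles H- and L-strand CDS on the circle."""
    frame = region.frame_offset or 0
    if region.strand == "H":
        cds_index = pos - region.start - frame
        if cds_index < 0:
            raise AnnotationError(f"position {pos} upstream of codon frame in {region.name}")
        within = cds_index % 3
        codon = genome.fetch(pos - within, 3)
        return codon, within
    # L strand: coding sequence is the reverse complement read from end down
    cds_index = region.end - frame - pos
    if cds_index < 0:
        raise AnnotationError(f"position {pos} upstream of codon frame in {region.name}")
    within = cds_index % 3
    top = genome.fetch(pos + within - 2, 3)  # genomic triplet covering the codon
    return reverse_complement(top), within


def classify_coding_effect(
    call: VariantCall, region: Region, genome: CircularGenome
) -> Effect:
    """Effect of a call within one region."""
    if region.region_type is not RegionType.CDS:
        return Effect.NONCODING
    if call.var_class is not VarClass.SNV:
        return (
            Effect.FRAMESHIFT
            if abs(call.indel_length) % 3 != 0
            else Effect.IN_FRAME_INDEL
        )
    if region.frame_offset is None:
        raise AnnotationError(f"CDS region {region.name!r} lacks frame_offset")
    codon, within = _codon_at(genome, region, call.pos)
    ref_base, alt_base = call.ref, call.alt
    if region.strand == "L":
        ref_base = reverse_complement(ref_base)
        alt_base = reverse_complement(alt_base)
    if codon[within] != ref_base:
        raise AnnotationError(
            f"reference mismatch at {call.pos}: codon has {codon[within]}, call says {ref_base}"
        )
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(mutated)
    if aa_alt == aa_ref:
        return Effect.SYNONYMOUS
    if aa_alt == "*":
        return Effect.NONSENSE
    return Effect.MISSENSE


def classify_deleterious(
    effect: Effect,
    region_types: tuple[RegionType, ...],
    pos: int,
    ref: str,
    alt: str,
    ptable: PathogenicityTable,
) -> tuple[bool, DeleteriousReason]:
    if effect is Effect.NONSENSE:
        return True, DeleteriousReason.NONSENSE
    if effect is Effect.FRAMESHIFT:
        return True, DeleteriousReason.FRAMESHIFT
    category = ptable.lookup(pos, ref, alt)
    if effect is Effect.MISSENSE and category is (
        PathogenicityCategory.CONFIRMED_PATHOGENIC_MISSENSE
    ):
        return True, DeleteriousReason.PATHOGENIC_MISSENSE
    if RegionType.TRNA in region_types and category in DELETERIOUS_TRNA_CATEGORIES:
        return True, DeleteriousReason.PATHOGENIC_TRNA
    return False, DeleteriousReason.NONE


def annotate_variant(
    call: VariantCall,
    table: RegionTable,
    genome: CircularGenome,
    ptable: PathogenicityTable,
) -> AnnotatedVariant:
    regions = table.regions_at(call.pos)
    region_types = tuple(r.region_type for r in regions)
    region = primary_region(regions)
    effect = classify_coding_effect(call, region, genome)
    gene = region.name if region.region_type is not RegionType.INTERGENIC else None
    deleterious, reason = classify_deleterious(
        effect, region_types, call.pos, call.ref, call.alt, ptable
    )
    return AnnotatedVariant(
        call=call,
        region_types=region_types,
        gene=gene,
        effect=effect,
        deleterious=deleterious,
        deleterious_reason=reason,
    )


def annotate_variants(
    calls: list[VariantCall],
    table: RegionTable,
    genome: CircularGenome,
    ptable: PathogenicityTable | None = None,
) -> list[AnnotatedVariant]:
    ptable = ptable or PathogenicityTable()
    return [annotate_variant(c, table, genome, ptable) for c in calls]


def deleterious_burden(
    samples: list[tuple[str, list[AnnotatedVariant]]],
    vaf_window: tuple[float, float] = (0.005, 0.95),
    include_upper: bool = False,
) -> dict[str, int]:
    """Deleterious heteroplasmic PASS variants per sample within a VAF window.

    The window is [low, high) by default, matching the operational
    heteroplasmy definition; ``include_upper`` closes the upper bound for
    reports on narrow low-VAF slices. Duplicate (pos, alt) pairs within a
    sample count once.
    """
    low, high = vaf_window
    out: dict[str, int] = {}
    for sample_id, variants in samples:
        seen: set[tuple[int, str]] = set()
        for v in variants:
            if not (v.call.is_pass and v.deleterious):
                continue
            if v.call.het_class is not HetClass.HETEROPLASMIC:
                continue
            in_window = (low <= v.vaf <= high) if include_upper else (low <= v.vaf < high)
            if in_window:
                seen.add((v.pos, v.call.alt))
        out[sample_id] = len(seen)
    return out
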