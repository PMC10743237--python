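"""Pileup-count SNV/indel calling with mtDNA-specific site filters.

The caller is deliberately simple: at each position, every non-reference
base (or distinct indel allele) whose read support clears a minimum count
and whose frequency clears the configured minimum VAF becomes a call.
Heteroplasmy classification follows the operational definition used
throughout the package: heteroplasmic when min_vaf <= VAF < 0.95,
homoplasmic when VAF >= 0.95.

The site filters encode known mitochondrial artifact positions on rCRS
coordinates: the poly-C stretch at 302-315 and the spacer N at 3107
(context ACNTT, 3105-3109) attract misaligned reads and produce spurious
SNVs in every sample; positions 248 and 16,256 produce shadow SNVs only in
samples carrying a homoplasmic deletion there; and the A7/A8 homopolymers
at 11,031 and 12,417 generate recurrent slippage indels. Flagged calls are
retained (for audit) but carry a non-PASS filter and are excluded from all
downstream counting.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum

from .simulate import BASES, PileupMatrix

POLY_C_RANGE = (302, 315)
N3107_RANGE = (3105, 3109)
DEL_SHADOW_POSITIONS = (248, 16256)
HOMOPOLYMER_INDEL_POSITIONS = (11031, 12417)


class VarClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class HetClass(str, Enum):
    BELOW_CUTOFF = "below_cutoff"
    HETEROPLASMIC = "heteroplasmic"
    HOMOPLASMIC = "homoplasmic"


class Filter(str, Enum):
    PASS = "PASS"
    POLY_C_302_315 = "poly_C_302_315"
    N3107 = "N3107"
    DEL_SHADOW_248 = "del_shadow_248"
    DEL_SHADOW_16256 = "del_shadow_16256"
    HOMOPOLYMER_11031 = "homopolymer_11031"
    HOMOPOLYMER_12417 = "homopolymer_12417"
    COMMON_INDEL = "common_indel"


@dataclass(frozen=True)
class CallerConfig:
    min_vaf: float = 0.005
    homoplasmy_threshold: float = 0.95
    min_alt_reads: int = 2

    def __post_init__(self):
        if not 0 < self.min_vaf < self.homoplasmy_threshold <= 1:
            raise ValueError(
                f"require 0 < min_vaf < homoplasmy_threshold <= 1, "
                f"got {self.min_vaf}, {self.homoplasmy_threshold}"
            )

    def het_class(self, vaf: float) -> HetClass:
        if vaf >= self.homoplasmy_threshold:
            return HetClass.HOMOPLASMIC
        if vaf >= self.min_vaf:
            return HetClass.HETEROPLASMIC
        return HetClass.BELOW_CUTOFF


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    pos: int
    ref: str
    alt: str  # base for SNV, "+SEQ" for insertion, "-N" for deletion
    vaf: float
    depth: int  # quality-passing reads at the position
    var_class: VarClass
    het_class: HetClass
    filters: frozenset[Filter] = frozenset({Filter.PASS})

    @property
    def is_pass(self) -> bool:
        return self.filters == frozenset({Filter.PASS})

    @property
    def indel_length(self) -> int:
        """Signed inserted/deleted base count; 0 for SNVs."""
        if self.var_class is VarClass.INSERTION:
            return len(self.alt) - 1
        if self.var_class is VarClass.DELETION:
            return -int(self.alt[1:])
        return 0


def call_snvs(
    pileup: PileupMatrix, config: CallerConfig = CallerConfig(), sample_id: str = "sample"
) -> list[VariantCall]:
    """Call every non-reference base meeting the support and VAF thresholds."""
    import numpy as np

    depths = pileup.passing_depths
    calls: list[VariantCall] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_matrix = pileup.counts / depths[:, None]
    candidate = (
        (pileup.counts >= config.min_alt_reads)
        & (vaf_matrix >= config.min_vaf)
        & (depths[:, None] > 0)
    )
    for i, j in zip(*candidate.nonzero()):
        ref = pileup.ref_bases[i]
        alt = BASES[j]
        if alt == ref:
            continue
        vaf = float(vaf_matrix[i, j])
        calls.append(
            VariantCall(
                sample_id=sample_id,
                pos=int(i) + 1,
                ref=str(ref),
                alt=alt,
                vaf=vaf,
                depth=int(depths[i]),
                var_class=VarClass.SNV,
                het_class=config.het_class(vaf),
            )
        )
    return calls


def call_indels(
    pileup: PileupMatrix, config: CallerConfig = CallerConfig(), sample_id: str = "sample"
) -> list[VariantCall]:
    """Call each distinct insertion/deletion allele independently."""
    calls: list[VariantCall] = []
    depths = pileup.passing_depths
    for i in range(pileup.n_positions):
        depth = int(depths[i])
        if depth == 0:
            continue
        ref = str(pileup.ref_bases[i])
        for seq, count in sorted(pileup.insertions[i].items()):
            if not seq or set(seq) - set(BASES):
                raise ValueError(f"malformed insertion record {seq!r} at {i + 1}")
            vaf = count / depth
            if count >= config.min_alt_reads and vaf >= config.min_vaf:
                calls.append(
                    VariantCall(
                        sample_id=sample_id, pos=i + 1, ref=ref, alt=f"+{seq}",
                        vaf=float(vaf), depth=depth, var_class=VarClass.INSERTION,
                        het_class=config.het_class(vaf),
                    )
                )
        for length, count in sorted(pileup.deletions[i].items()):
            if int(length) <= 0:
                raise ValueError(f"malformed deletion length {length!r} at {i + 1}")
            vaf = count / depth
            if count >= config.min_alt_reads and vaf >= config.min_vaf:
                calls.append(
                    VariantCall(
                        sample_id=sample_id, pos=i + 1, ref=ref, alt=f"-{int(length)}",
                        vaf=float(vaf), depth=depth, var_class=VarClass.DELETION,
                        het_class=config.het_class(vaf),
                    )
                )
    return calls


def _with_flags(call: VariantCall, flags: set[Filter]) -> VariantCall:
    if not flags:
        return call
    current = set(call.filters) - {Filter.PASS}
    return replace(call, filters=frozenset(current | flags))


def detect_homoplasmic_deletions(
    calls: list[VariantCall], homoplasmy_threshold: float = 0.95
) -> dict[str, set[int]]:
    """Per-sample positions carrying a homoplasmic (VAF >= threshold) deletion."""
    found: dict[str, set[int]] = defaultdict(set)
    for c in calls:
        if c.var_class is VarClass.DELETION and c.vaf >= homoplasmy_threshold:
            found[c.sample_id].add(c.pos)
    return dict(found)


def apply_site_filters(
    calls: list[VariantCall],
    per_sample_homoplasmic_deletions: dict[str, set[int]] | None = None,
) -> list[VariantCall]:
    """Flag SNVs at known artifact sites.

    Poly-C (302-315) and the 3107 spacer context (3105-3109) are flagged in
    all samples; positions 248 and 16,256 are flagged only in samples whose
    call set contains a homoplasmic deletion at that position. The poly-C
    and spacer filters target misaligned SNVs; indels there are handled by
    the common-indel rule if artifactual.
    """
    if per_sample_homoplasmic_deletions is None:
        per_sample_homoplasmic_deletions = detect_homoplasmic_deletions(calls)
    out = []
    for c in calls:
        flags: set[Filter] = set()
        if c.var_class is VarClass.SNV:
            if POLY_C_RANGE[0] <= c.pos <= POLY_C_RANGE[1]:
                flags.add(Filter.POLY_C_302_315)
            if N3107_RANGE[0] <= c.pos <= N3107_RANGE[1]:
                flags.add(Filter.N3107)
            sample_dels = per_sample_homoplasmic_deletions.get(c.sample_id, set())
            if c.pos == 248 and 248 in sample_dels:
                flags.add(Filter.DEL_SHADOW_248)
            if c.pos == 16256 and 16256 in sample_dels:
                flags.add(Filter.DEL_SHADOW_16256)
        out.append(_with_flags(c, flags))
    return out


def apply_indel_blacklist(
    calls: list[VariantCall],
    cohort_presence: dict[tuple[int, str], float] | None = None,
    commonality_threshold: float = 1.0,
    n_samples: int | None = None,
) -> list[VariantCall]:
    """Flag homopolymer-artifact indels.

    Indels at 11,031 and 12,417 (A7/A8 homopolymers) are always flagged.
    Additionally, any indel allele present in >= commonality_threshold of
    the cohort's samples is flagged common_indel; the default threshold of
    1.0 removes only alleles seen in every sample, the most conservative
    reading of "detected commonly".
    """
    if cohort_presence is None:
        sample_ids = {c.sample_id for c in calls}
        n = n_samples if n_samples is not None else len(sample_ids)
        carriers: dict[tuple[int, str], set[str]] = defaultdict(set)
        for c in calls:
            if c.var_class is not VarClass.SNV and c.is_pass:
                carriers[(c.pos, c.alt)].add(c.sample_id)
        cohort_presence = {k: len(v) / n for k, v in carriers.items()} if n else {}
    out = []
    for c in calls:
        flags: set[Filter] = set()
        if c.var_class is not VarClass.SNV:
            if c.pos == 11031:
                flags.add(Filter.HOMOPOLYMER_11031)
            if c.pos == 12417:
                flags.add(Filter.HOMOPOLYMER_12417)
            if cohort_presence.get((c.pos, c.alt), 0.0) >= commonality_threshold:
                flags.add(Filter.COMMON_INDEL)
        out.append(_with_flags(c, flags))
    return out


def pass_calls(calls: list[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.is_pass]
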