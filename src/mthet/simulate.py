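"""Seeded generators for pileups, admixture pairs, and stage cohorts.

These emulate the statistical structure of ultra-deep (~30,000x) amplicon
sequencing of the mitochondrial genome, so every downstream stage — cutoff
determination, variant calling, annotation, copy-number and trend statistics
— is testable without access to controlled sequencing data.

The error model is intentionally simple: per-position background error is
binomial, optionally with a log-normal per-position rate multiplier to give
the empirical error distribution the right-skewed tail that real platforms
show (without it, a nonparametric upper fence on the error distribution is
unrealistically tight). Base quality is a per-read pass/fail mask rather
than Phred scores; callers see only passing reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoordinateError, ParameterError
from .reference import CircularGenome

#: cohort stage sizes of the emulated study (no G3 samples)
DEFAULT_STAGE_SIZES = {"G1": 16, "G2": 15, "G4": 4, "G5": 42}
DEFAULT_STAGE_ORDER = ("G1", "G2", "G4", "G5")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PileupMatrix:
    """Per-position read counts over a circular genome.

    ``counts`` is an (L, 4) array of quality-passing base counts in A,C,G,T
    order; ``insertions``/``deletions`` are sparse per-position records
    (sequence -> count, deletion length -> count); ``low_quality`` counts
    reads failing the base-quality screen. Total depth at a position is the
    base-count row sum plus the low-quality count; VAFs are computed over
    passing reads only.
    """

    genome_name: str
    ref_bases: np.ndarray  # (L,) '<U1'
    counts: np.ndarray  # (L, 4) int64
    insertions: list[dict[str, int]]
    deletions: list[dict[int, int]]
    low_quality: np.ndarray  # (L,) int64

    @property
    def n_positions(self) -> int:
        return len(self.ref_bases)

    def passing_depth(self, pos: int) -> int:
        return int(self.counts[pos - 1].sum())

    @property
    def passing_depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def total_depth(self, pos: int) -> int:
        return self.passing_depth(pos) + int(self.low_quality[pos - 1])

    def ref_count(self, pos: int) -> int:
        return int(self.counts[pos - 1, _BASE_INDEX[self.ref_bases[pos - 1]]])

    def ref_counts_all(self) -> np.ndarray:
        idx = np.array([_BASE_INDEX[b] for b in self.ref_bases])
        return self.counts[np.arange(self.n_positions), idx]

    def validate(self) -> None:
        if self.counts.shape != (self.n_positions, 4):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any() or (self.low_quality < 0).any():
            raise ValueError("negative counts")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "pos": np.arange(1, self.n_positions + 1),
                "ref": self.ref_bases,
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
                "ins_json": [json.dumps(d) if d else "{}" for d in self.insertions],
                "del_json": [
                    json.dumps({str(k): v for k, v in d.items()}) if d else "{}"
                    for d in self.deletions
                ],
                "lowq": self.low_quality,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# genome={self.genome_name}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupMatrix":
        genome_name = "unknown"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# genome="):
                genome_name = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        df = df.sort_values("pos")
        return cls(
            genome_name=genome_name,
            ref_bases=df["ref"].to_numpy(dtype="<U1"),
            counts=df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64),
            insertions=[
                {k: int(v) for k, v in json.loads(s).items()} for s in df["ins_json"]
            ],
            deletions=[
                {int(k): int(v) for k, v in json.loads(s).items()} for s in df["del_json"]
            ],
            low_quality=df["lowq"].to_numpy(dtype=np.int64),
        )

    @classmethod
    def empty(cls, genome: CircularGenome) -> "PileupMatrix":
        L = genome.length
        return cls(
            genome_name=genome.name,
            ref_bases=np.array(list(genome.sequence), dtype="<U1"),
            counts=np.zeros((L, 4), dtype=np.int64),
            insertions=[{} for _ in range(L)],
            deletions=[{} for _ in range(L)],
            low_quality=np.zeros(L, dtype=np.int64),
        )


@dataclass(frozen=True)
class PlantedVariant:
    """Ground-truth variant planted into a simulated pileup.

    ``alt`` is a base for SNVs, ``+SEQ`` for insertions, ``-N`` for
    deletions of N bases.
    """

    pos: int
    ref: str
    alt: str
    true_vaf: float

    def __post_init__(self):
        if not 0.0 <= self.true_vaf <= 1.0:
            raise ParameterError(f"true_vaf {self.true_vaf} outside [0, 1]")


@dataclass
class CohortSample:
    """One synthetic study subject with its ground truth attached."""

    sample_id: str
    ckd_stage: str
    age: float
    ct_nd1: float
    ct_ppia: float
    true_cn: float
    true_deleterious: int
    planted: list[PlantedVariant] = field(default_factory=list)
    pileup: PileupMatrix | None = None


def random_genome(length: int = 16569, seed: int = 0, name: str = "synthetic-mt") -> CircularGenome:
    """A uniformly random circular genome. Synthetic stand-in for a real
    mitochondrial reference sequence, which is not bundled."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), size=length))
    return CircularGenome(sequence=seq, name=name)


def simulate_pileup(
    genome: CircularGenome,
    mean_depth: int = 30_000,
    error_rate: float = 5e-4,
    variants: list[PlantedVariant] = (),
    homopolymer_hotspots: list[tuple[int, float]] = (),
    seed: int = 0,
    quality_pass_prob: float = 1.0,
    error_dispersion: float = 0.0,
    error_multipliers: np.ndarray | None = None,
) -> PileupMatrix:
    """Simulate one sample's pileup.

    Depth is Poisson(mean_depth) per position; reads fail the quality screen
    independently with probability 1 - quality_pass_prob. Background errors
    among passing reads are Binomial(depth, e_i) split uniformly over the
    three non-reference bases, where e_i = error_rate at every position when
    ``error_dispersion`` is 0, and otherwise error_rate times a per-position
    log-normal multiplier LogNormal(0, error_dispersion). The multiplier is
    median-1: error_rate is the error at a typical position, and dispersion
    fattens the right tail (raising the mean), as position/context-dependent
    platform error does. Pass ``error_multipliers`` to fix the multiplier
    array explicitly — e.g. to share one error landscape between two samples
    sequenced on the same platform.

    Planted SNVs draw alt reads Binomial(depth, true_vaf) first, with errors
    superimposed on the remainder; planted indels and hotspot 1-bp
    insertions are recorded as sparse indel reads.
    """
    if not 0 <= error_rate < 0.01:
        raise ParameterError(f"error_rate {error_rate} outside [0, 0.01)")
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    L = genome.length
    pile = PileupMatrix.empty(genome)

    depth = rng.poisson(mean_depth, size=L)
    if quality_pass_prob < 1.0:
        lowq = rng.binomial(depth, 1.0 - quality_pass_prob)
    else:
        lowq = np.zeros(L, dtype=np.int64)
    passing = depth - lowq
    pile.low_quality = lowq.astype(np.int64)

    if error_multipliers is not None:
        if len(error_multipliers) != L:
            raise ParameterError("error_multipliers length mismatch")
        err = np.clip(error_rate * np.asarray(error_multipliers, dtype=float), 0.0, 0.999)
    elif error_dispersion > 0:
        mult = rng.lognormal(mean=0.0, sigma=error_dispersion, size=L)
        err = np.clip(error_rate * mult, 0.0, 0.999)
    else:
        err = np.full(L, error_rate)

    snvs = {v.pos: v for v in variants if len(v.alt) == 1 and v.alt in BASES}
    for v in variants:
        if not 1 <= v.pos <= L:
            raise CoordinateError(f"planted variant position {v.pos} outside genome")

    ref_idx = np.array([_BASE_INDEX[b] for b in pile.ref_bases])
    alt_counts = np.zeros(L, dtype=np.int64)
    alt_idx = np.full(L, -1)
    if snvs:
        pos_arr = np.array(sorted(snvs))
        vafs = np.array([snvs[p].true_vaf for p in pos_arr])
        alt_counts[pos_arr - 1] = rng.binomial(passing[pos_arr - 1], vafs)
        alt_idx[pos_arr - 1] = [_BASE_INDEX[snvs[p].alt] for p in pos_arr]

    remaining = passing - alt_counts
    err_counts = rng.binomial(remaining, err) if error_rate > 0 else np.zeros(L, dtype=np.int64)

    # split errors uniformly over the three non-reference bases
    counts = np.zeros((L, 4), dtype=np.int64)
    counts[np.arange(L), ref_idx] = remaining - err_counts
    nz = np.nonzero(err_counts)[0]
    if len(nz):
        splits = rng.multinomial(err_counts[nz], [1 / 3] * 3)
        for row, i in enumerate(nz):
            others = [j for j in range(4) if j != ref_idx[i]]
            counts[i, others] += splits[row]
    has_alt = alt_idx >= 0
    counts[np.nonzero(has_alt)[0], alt_idx[has_alt]] += alt_counts[has_alt]
    pile.counts = counts

    for v in variants:
        if len(v.alt) == 1 and v.alt in BASES:
            continue  # SNVs handled vectorized above (one per position)
        n = int(rng.binomial(passing[v.pos - 1], v.true_vaf))
        if n == 0:
            continue
        if v.alt.startswith("+"):
            seq = v.alt[1:]
            pile.insertions[v.pos - 1][seq] = pile.insertions[v.pos - 1].get(seq, 0) + n
        elif v.alt.startswith("-"):
            k = int(v.alt[1:])
            pile.deletions[v.pos - 1][k] = pile.deletions[v.pos - 1].get(k, 0) + n
        else:
            raise ParameterError(f"unrecognized alt spec {v.alt!r}")

    for pos, rate in homopolymer_hotspots:
        if not 1 <= pos <= L:
            raise CoordinateError(f"hotspot position {pos} outside genome")
        if rate < 0:
            raise ParameterError("hotspot rate must be nonnegative")
        n = int(rng.binomial(passing[pos - 1], rate))
        if n:
            # slippage modeled as a 1-bp insertion of the reference base
            seq = pile.ref_bases[pos - 1]
            pile.insertions[pos - 1][seq] = pile.insertions[pos - 1].get(seq, 0) + n

    pile.validate()
    return pile


def _nonref_base(rng: np.random.Generator, ref: str) -> str:
    return rng.choice([b for b in BASES if b != ref])


def simulate_admixture_pair(
    genome: CircularGenome,
    n_shared_homoplasmies: int = 13,
    n_private_homoplasmies: int = 23,
    mean_depth: int = 30_000,
    error_rate: float = 5e-4,
    seed: int = 0,
    error_dispersion: float = 1.2,
) -> tuple[PileupMatrix, PileupMatrix, list[int]]:
    """A background/spike sample pair for in silico admixture.

    Both samples carry ``n_shared_homoplasmies`` homoplasmic variants at
    shared positions; only the spike carries ``n_private_homoplasmies``
    additional ones. The defaults (13 shared / 23 private) mirror the
    cell-line-vs-kidney pair used to calibrate the detection cutoff.

    Both samples share one per-position error landscape (a log-normal
    multiplier with shape ``error_dispersion`` on top of ``error_rate``),
    since position- and context-dependent error is a property of the
    platform, not the sample. Homoplasmy positions are drawn from clean
    positions (multiplier <= 1): sites called confidently homoplasmic in
    real data are by construction sites with well-behaved error.

    Returns (background, spike, private positions).
    """
    total = n_shared_homoplasmies + n_private_homoplasmies
    if total > genome.length:
        raise ParameterError("more homoplasmies requested than genome positions")
    rng = np.random.default_rng(seed)
    if error_dispersion > 0:
        multipliers = rng.lognormal(mean=0.0, sigma=error_dispersion, size=genome.length)
    else:
        multipliers = np.ones(genome.length)
    clean = np.nonzero(multipliers <= 1.0)[0] + 1
    if len(clean) < total:
        raise ParameterError("not enough clean positions for requested homoplasmies")
    positions = rng.choice(clean, size=total, replace=False)
    shared = sorted(int(p) for p in positions[:n_shared_homoplasmies])
    private = sorted(int(p) for p in positions[n_shared_homoplasmies:])

    def homoplasmy(pos):
        ref = genome.base(pos)
        return PlantedVariant(pos=pos, ref=ref, alt=_nonref_base(rng, ref), true_vaf=1.0)

    shared_vars = [homoplasmy(p) for p in shared]
    private_vars = [homoplasmy(p) for p in private]

    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    background = simulate_pileup(
        genome, mean_depth, error_rate, shared_vars,
        seed=s1.generate_state(1)[0] % 2**31, error_multipliers=multipliers,
    )
    spike = simulate_pileup(
        genome, mean_depth, error_rate, shared_vars + private_vars,
        seed=s2.generate_state(1)[0] % 2**31, error_multipliers=multipliers,
    )
    return background, spike, private


@dataclass(frozen=True)
class BurdenModel:
    """Poisson model for per-sample deleterious-variant counts: the mean at
    ordered stage index k (0-based) is baseline + k * increment."""

    baseline: float = 0.3
    increment: float = 0.5

    def mean(self, stage_index: int) -> float:
        m = self.baseline + stage_index * self.increment
        if m < 0:
            raise ParameterError("negative Poisson mean")
        return m


@dataclass(frozen=True)
class CopyNumberModel:
    """Stage-dependent mtDNA copy number: mean at stage index k is
    baseline - k * decrement, with multiplicative log-normal noise of shape
    ``noise_sd`` (CV on the natural scale); Ct pairs get additive Gaussian
    noise of ``ct_noise`` cycles."""

    baseline: float = 1500.0
    decrement: float = 250.0
    noise_sd: float = 0.3
    ct_noise: float = 0.0

    def mean(self, stage_index: int) -> float:
        m = self.baseline - stage_index * self.decrement
        if m <= 0:
            raise ParameterError(f"copy-number model gives CN <= 0 at stage index {stage_index}")
        return m


def simulate_cohort(
    n_per_stage: dict[str, int] | None = None,
    burden_model: BurdenModel = BurdenModel(),
    cn_model: CopyNumberModel = CopyNumberModel(),
    age_range: tuple[float, float] = (40.0, 80.0),
    seed: int = 0,
    stage_order: tuple[str, ...] | None = None,
    mean_ct_ppia: float = 25.0,
) -> list[CohortSample]:
    """Simulate a stage-ordered cohort with ground truth.

    Deleterious counts are Poisson with a stage-increasing mean and copy
    numbers are log-normal around a stage-decreasing mean. Ct pairs are
    back-computed from the sampled copy number by inverting the qPCR
    doubling relation CN = 2^(Ct_nuclear - Ct_mito), so with ct_noise = 0
    the copy-number estimator recovers the sampled CN exactly.
    """
    if n_per_stage is None:
        n_per_stage = dict(DEFAULT_STAGE_SIZES)
    if stage_order is None:
        stage_order = tuple(s for s in DEFAULT_STAGE_ORDER if s in n_per_stage)
        stage_order = stage_order + tuple(s for s in n_per_stage if s not in stage_order)
    rng = np.random.default_rng(seed)

    samples: list[CohortSample] = []
    i = 0
    for k, stage in enumerate(stage_order):
        n = n_per_stage.get(stage, 0)
        if n < 0:
            raise ParameterError("negative group size")
        lam = burden_model.mean(k)
        cn_mean = cn_model.mean(k)
        for _ in range(n):
            i += 1
            burden = int(rng.poisson(lam))
            cn = cn_mean * rng.lognormal(
                mean=-0.5 * cn_model.noise_sd**2, sigma=cn_model.noise_sd
            ) if cn_model.noise_sd > 0 else cn_mean
            ct_ppia = mean_ct_ppia + (rng.normal(0, 0.5) if cn_model.ct_noise > 0 else 0.0)
            ct_nd1 = ct_ppia - np.log2(cn)
            if cn_model.ct_noise > 0:
                ct_nd1 += rng.normal(0, cn_model.ct_noise)
            age = float(rng.uniform(*age_range))
            samples.append(
                CohortSample(
                    sample_id=f"S{i:03d}",
                    ckd_stage=stage,
                    age=age,
                    ct_nd1=float(ct_nd1),
                    ct_ppia=float(ct_ppia),
                    true_cn=float(cn),
                    true_deleterious=burden,
                )
            )
    return samples


def attach_cohort_pileups(
    samples: list[CohortSample],
    genome: CircularGenome,
    region_table,
    mean_depth: int = 5_000,
    error_rate: float = 0.0,
    vaf_range: tuple[float, float] = (0.008, 0.05),
    seed: int = 0,
) -> None:
    """Plant each sample's deleterious burden as frameshift indels in CDS
    and simulate a pileup per sample (in place).

    Each planted variant is a 1-bp insertion at a distinct CDS position with
    a low-heteroplasmy VAF, so the calling -> annotation -> burden path
    recovers ``true_deleterious`` exactly when error_rate is 0.
    """
    from .reference import RegionType

    cds_positions = sorted(
        {
            p
            for r in region_table.regions
            if r.region_type is RegionType.CDS
            for p in range(r.start, r.end + 1)
        }
    )
    rng = np.random.default_rng(seed)
    for s in samples:
        if s.true_deleterious > len(cds_positions):
            raise ParameterError("burden exceeds available CDS positions")
        chosen = rng.choice(cds_positions, size=s.true_deleterious, replace=False)
        s.planted = [
            PlantedVariant(
                pos=int(p),
                ref=genome.base(int(p)),
                alt="+" + genome.base(int(p)),
                true_vaf=float(rng.uniform(*vaf_range)),
            )
            for p in chosen
        ]
        s.pileup = simulate_pileup(
            genome,
            mean_depth=mean_depth,
            error_rate=error_rate,
            variants=s.planted,
            seed=int(rng.integers(2**31)),
        )


def cohort_to_frame(samples: list[CohortSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "ckd_stage": [s.ckd_stage for s in samples],
            "age": [s.age for s in samples],
            "ct_nd1": [s.ct_nd1 for s in samples],
            "ct_ppia": [s.ct_ppia for s in samples],
            "true_cn": [s.true_cn for s in samples],
            "true_deleterious": [s.true_deleterious for s in samples],
        }
    )
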