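"""In silico admixture and minimum VAF cutoff determination.

Detecting heteroplasmy below ~1% VAF requires knowing where background
sequencing error ends and signal begins. The procedure implemented here
mixes reads from a background sample (a monoclonal cell line) with a spike
sample carrying private homoplasmic variants, at a series of small mixture
ratios, thereby creating artificial heteroplasmies of known frequency.

Two boundaries are then compared:

* an **upper fence** on background error — the Tukey nonparametric outlier
  bound Q3 + 1.5 * IQR applied to the background sample's non-reference VAF
  at every position, and
* a per-ratio **lower confidence limit** — mean - 3 * SD of the observed
  VAF at the artificial heteroplasmic positions.

The minimum usable VAF cutoff is the smallest mixture ratio whose lower
confidence limit stays strictly above the fence: at that ratio, true
heteroplasmies remain separable from error.

Mixing happens at read-count level by binomial thinning (keep each
background read with probability 1 - ratio, each spike read with
probability ratio), which matches file-level read splitting in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import IncompatibleGenomesError, InsufficientDataError, ZeroDepthError
from .simulate import PileupMatrix

UNDETERMINED = "undetermined"


@dataclass
class AdmixtureResult:
    """Outcome of one cutoff-determination experiment."""

    upper_fence: float
    lower_limits: dict[float, float]
    selected_cutoff: float | None
    ratios_tested: list[float]
    n_background_positions: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "upper_fence": self.upper_fence,
            "lower_limits": {str(r): v for r, v in self.lower_limits.items()},
            "selected_cutoff": (
                self.selected_cutoff if self.selected_cutoff is not None else UNDETERMINED
            ),
            "ratios_tested": self.ratios_tested,
            "n_background_positions": self.n_background_positions,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _thin_counts(rng, counts: np.ndarray, p: float) -> np.ndarray:
    if p <= 0:
        return np.zeros_like(counts)
    if p >= 1:
        return counts.copy()
    return rng.binomial(counts, p)


def mix_pileups(
    background: PileupMatrix, spike: PileupMatrix, ratio: float, seed: int = 0
) -> PileupMatrix:
    """Binomially thin and sum two pileups at the given spike ratio."""
    if background.genome_name != spike.genome_name or (
        background.n_positions != spike.n_positions
    ):
        raise IncompatibleGenomesError(
            f"cannot mix pileups over {background.genome_name!r}/{spike.genome_name!r}"
        )
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    rng = np.random.default_rng(seed)
    L = background.n_positions

    out = PileupMatrix(
        genome_name=background.genome_name,
        ref_bases=background.ref_bases.copy(),
        counts=_thin_counts(rng, background.counts, 1.0 - ratio)
        + _thin_counts(rng, spike.counts, ratio),
        insertions=[{} for _ in range(L)],
        deletions=[{} for _ in range(L)],
        low_quality=_thin_counts(rng, background.low_quality, 1.0 - ratio)
        + _thin_counts(rng, spike.low_quality, ratio),
    )
    for i in range(L):
        for src, p in ((background, 1.0 - ratio), (spike, ratio)):
            for seq, c in src.insertions[i].items():
                kept = int(rng.binomial(c, p)) if 0 < p < 1 else int(c * p)
                if kept:
                    out.insertions[i][seq] = out.insertions[i].get(seq, 0) + kept
            for k, c in src.deletions[i].items():
                kept = int(rng.binomial(c, p)) if 0 < p < 1 else int(c * p)
                if kept:
                    out.deletions[i][k] = out.deletions[i].get(k, 0) + kept
    return out


def nonref_vaf(pileup: PileupMatrix, pos: int) -> float:
    """(total passing reads - reference reads) / total passing reads."""
    total = pileup.passing_depth(pos)
    if total == 0:
        raise ZeroDepthError(f"no passing reads at position {pos}")
    return (total - pileup.ref_count(pos)) / total


def nonref_vaf_all(pileup: PileupMatrix) -> np.ndarray:
    """Vector of non-reference VAFs; NaN where passing depth is zero."""
    total = pileup.passing_depths.astype(float)
    ref = pileup.ref_counts_all().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = (total - ref) / total
    vaf[total == 0] = np.nan
    return vaf


def upper_fence(vafs) -> float:
    """Tukey upper fence Q3 + 1.5 * IQR with linear-interpolation quantiles.

    The quantile convention matters for a fence: this uses linear
    interpolation between order statistics (numpy's default, R's type 7),
    fixed here so results are reproducible across environments.
    """
    vafs = np.asarray(list(vafs), dtype=float)
    vafs = vafs[~np.isnan(vafs)]
    if len(vafs) < 4:
        raise InsufficientDataError(f"upper fence needs >= 4 values, got {len(vafs)}")
    q1, q3 = np.quantile(vafs, [0.25, 0.75], method="linear")
    return float(q3 + 1.5 * (q3 - q1))


def lower_confidence_limit(vafs) -> float:
    """mean - 3 * SD (sample SD, n-1 denominator); may be negative, meaning
    the mixture ratio is statistically indistinguishable from zero."""
    vafs = np.asarray(list(vafs), dtype=float)
    vafs = vafs[~np.isnan(vafs)]
    if len(vafs) < 2:
        raise InsufficientDataError(
            f"lower confidence limit needs >= 2 values, got {len(vafs)}"
        )
    return float(vafs.mean() - 3.0 * vafs.std(ddof=1))


def select_cutoff(fence: float, lower_limits: dict[float, float]) -> float | None:
    """Smallest tested ratio whose lower confidence limit strictly exceeds
    the fence; None ("undetermined") if no ratio qualifies."""
    qualifying = [r for r, lim in lower_limits.items() if lim > fence]
    return min(qualifying) if qualifying else None


def run_admixture_experiment(
    background: PileupMatrix,
    spike: PileupMatrix,
    private_positions: list[int],
    ratios: list[float],
    seed: int = 0,
    exclude_background_homoplasmies: bool = False,
) -> AdmixtureResult:
    """Full cutoff determination: fence from the background's genome-wide
    non-reference VAFs, per-ratio lower limits at the private (artificial
    heteroplasmic) positions of each mixture, then cutoff selection.

    By default the fence includes the background sample's own homoplasmic
    positions — a handful of near-1 VAFs barely move the quartiles of a
    genome-wide distribution; ``exclude_background_homoplasmies`` drops
    positions with background VAF >= 0.95 first.
    """
    if not ratios:
        raise InsufficientDataError("at least one mixture ratio required")
    if not private_positions:
        raise InsufficientDataError("at least one private position required")

    bg_vafs = nonref_vaf_all(background)
    if exclude_background_homoplasmies:
        bg_vafs = bg_vafs[~(bg_vafs >= 0.95)]
    fence = upper_fence(bg_vafs[~np.isnan(bg_vafs)])

    priv = np.asarray(private_positions, dtype=int) - 1
    limits: dict[float, float] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(ratios))
    for ratio, ss in zip(sorted(ratios, reverse=True), child_seeds):
        mixed = mix_pileups(background, spike, ratio, seed=ss.generate_state(1)[0] % 2**31)
        vafs = nonref_vaf_all(mixed)[priv]
        limits[ratio] = lower_confidence_limit(vafs)

    return AdmixtureResult(
        upper_fence=fence,
        lower_limits=limits,
        selected_cutoff=select_cutoff(fence, limits),
        ratios_tested=sorted(ratios),
        n_background_positions=int(np.sum(~np.isnan(bg_vafs))),
        seed=seed,
    )
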