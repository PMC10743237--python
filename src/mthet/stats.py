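"""Ordered-group trend tests and mutational-spectrum analysis.

The cohort comparisons revolve around ordered disease stages: the
Jonckheere-Terpstra test for a monotone trend (built from pairwise
Mann-Whitney counts, with exact/Monte-Carlo permutation or a tie-corrected
normal approximation), Dunnett many-to-one comparisons against the first
stage, Kruskal-Wallis, 2x2 chi-squared, and rank-based age correlation.

Spectrum construction collapses every SNV onto the six pyrimidine-centred
substitution classes (optionally with trinucleotide context, 96 classes),
reading context from the circular genome so position 1 uses the last base
as its 5' neighbor. A simplified indel taxonomy (type x length x
homopolymer context) replaces full nuclear-genome indel signature classes,
which are ill-suited to a 16.6 kb genome.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sps

from .calling import VarClass
from .errors import InsufficientDataError, ParameterError
from .reference import CircularGenome, reverse_complement

PYRIMIDINES = ("C", "T")
SBS6_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SBS96_CLASSES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS6_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)
ID_SIMPLE_CLASSES = (
    "ins_1_homopolymer",
    "ins_1_other",
    "ins_long_homopolymer",
    "ins_long_other",
    "del_1_homopolymer",
    "del_1_other",
    "del_long_homopolymer",
    "del_long_other",
)


@dataclass
class OrderedGroups:
    """Values grouped by ordered labels (e.g. disease stages G1 < G2 < ...)."""

    labels: list[str]
    values: dict[str, list[float]]

    def __post_init__(self):
        nonempty = [l for l in self.labels if len(self.values.get(l, [])) > 0]
        if len(nonempty) < 2:
            raise InsufficientDataError("need >= 2 nonempty ordered groups")

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(self.values[l], dtype=float) for l in self.labels if len(self.values.get(l, []))]

    @classmethod
    def from_pairs(cls, labels, pairs) -> "OrderedGroups":
        values = {l: [] for l in labels}
        for label, v in pairs:
            values[label].append(float(v))
        return cls(labels=list(labels), values=values)


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """J = sum over ordered group pairs (i<j) of Mann-Whitney counts,
    ties contributing 1/2."""
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        j += float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    return j


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected null mean and variance of J (Hollander & Wolfe)."""
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    pooled = np.concatenate(groups)
    ties = np.array(list(Counter(pooled).values()), dtype=float)

    mean = (n**2 - (ns**2).sum()) / 4.0
    t1 = (
        n * (n - 1) * (2 * n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (ties * (ties - 1) * (2 * ties + 5)).sum()
    ) / 72.0
    t2 = (
        (ns * (ns - 1) * (ns - 2)).sum()
        * (ties * (ties - 1) * (ties - 2)).sum()
        / (36.0 * n * (n - 1) * (n - 2))
    )
    t3 = (
        (ns * (ns - 1)).sum() * (ties * (ties - 1)).sum() / (8.0 * n * (n - 1))
    )
    return mean, t1 + t2 + t3


def _exact_permutation_p(groups: list[np.ndarray], j_obs: float) -> float:
    """Exhaustive permutation p-value P(J >= j_obs) by enumerating all
    assignments of pooled values to the group sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    count = total = 0
    indices = list(range(n))

    def recurse(remaining: list[int], k: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if k == len(sizes):
            total += 1
            if _jt_statistic(chosen) >= j_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = [i for i in remaining if i not in set(combo)]
            recurse(rest, k + 1, chosen + [pooled[list(combo)]])

    recurse(indices, 0, [])
    return count / total


def jonckheere_terpstra(
    groups: OrderedGroups,
    alternative: str = "increasing",
    method: str = "auto",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Jonckheere-Terpstra trend test over ordered groups.

    Returns (J, p) where J is the directed statistic for the requested
    alternative. ``method`` is one of:

    * ``exact_permutation`` — exhaustive enumeration (feasible for n <= 12);
    * ``normal_approx`` — tie-corrected normal approximation;
    * ``auto`` — exact when total n <= 12, otherwise normal approximation.

    Monte-Carlo permutation is used instead of the normal approximation
    when ``method='permutation'`` (seeded, ``n_perm`` shuffles).
    """
    if alternative not in ("increasing", "decreasing"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    arrays = groups.arrays()
    if alternative == "decreasing":
        arrays = [-a for a in arrays]
    n = sum(len(a) for a in arrays)
    j_obs = _jt_statistic(arrays)

    if method == "auto":
        method = "exact_permutation" if n <= 12 else "normal_approx"

    if method == "exact_permutation":
        if n > 14:
            raise ParameterError("exact permutation infeasible beyond n = 14")
        return j_obs, _exact_permutation_p(arrays, j_obs)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(arrays)
        sizes = np.cumsum([len(a) for a in arrays])[:-1]
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if _jt_statistic(np.split(pooled, sizes)) >= j_obs - 1e-12:
                hits += 1
        return j_obs, (hits + 1) / (n_perm + 1)

    if method == "normal_approx":
        mean, var = _jt_null_moments(arrays)
        if var <= 0:
            return j_obs, 1.0
        z = (j_obs - mean) / math.sqrt(var)
        return j_obs, float(sps.norm.sf(z))

    raise ParameterError(f"unknown method {method!r}")


def dunnett_many_to_one(
    groups: OrderedGroups,
    control: str,
    seed: int | None = None,
    n_mc: int = 100_000,
    alternative: str = "two-sided",
) -> dict[str, float]:
    """Dunnett's many-to-one comparisons of each group mean against the
    control, with family-wise adjustment over the joint max-|t| null
    distribution of the equicorrelated multivariate t.

    The joint distribution is evaluated by seeded randomized quasi-Monte
    Carlo (scipy's implementation); ``n_mc`` caps the precision request.
    """
    if control not in groups.labels:
        raise ParameterError(f"control group {control!r} not among labels")
    others = [l for l in groups.labels if l != control and len(groups.values.get(l, []))]
    ctrl = np.asarray(groups.values[control], dtype=float)
    if not others:
        raise InsufficientDataError("no comparison groups")
    samples = [np.asarray(groups.values[l], dtype=float) for l in others]
    pooled_var = np.concatenate([ctrl] + samples)
    if np.var(pooled_var) == 0:
        raise ParameterError("degenerate: zero variance across all groups")
    res = sps.dunnett(
        *samples,
        control=ctrl,
        alternative=alternative,
        random_state=np.random.default_rng(seed),
    )
    return dict(zip(others, (float(p) for p in res.pvalue)))


def kruskal_wallis(groups: OrderedGroups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (k-1 df).
    All-identical values return (0, 1) by contract."""
    arrays = groups.arrays()
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def chi_squared_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, Yates-corrected by default
    (matching the R convention for 2x2 tables)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ParameterError("need a 2x2 table of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("zero marginal in contingency table")
    res = sps.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def age_correlation(
    ages, burdens, method: str = "spearman"
) -> tuple[float, float]:
    """Rank-based (Spearman) correlation between age and variant burden;
    Pearson available via ``method``."""
    ages = np.asarray(ages, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    if len(ages) != len(burdens) or len(ages) < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.all(ages == ages[0]) or np.all(burdens == burdens[0]):
        raise InsufficientDataError("correlation undefined for constant input")
    if method == "spearman":
        rho, p = sps.spearmanr(ages, burdens)
    elif method == "pearson":
        rho, p = sps.pearsonr(ages, burdens)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return float(rho), float(p)


@dataclass
class Spectrum:
    kind: str  # SBS6 | SBS96 | ID_simple
    labels: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def zeros(cls, kind: str) -> "Spectrum":
        labels = {
            "SBS6": SBS6_CLASSES,
            "SBS96": SBS96_CLASSES,
            "ID_simple": ID_SIMPLE_CLASSES,
        }[kind]
        return cls(kind=kind, labels=labels, counts=np.zeros(len(labels)))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.counts.tolist()))


def _collapse_snv(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Pyrimidine-centred substitution class and context; purine references
    are collapsed by reverse complement."""
    if ref == alt:
        raise ParameterError(f"alt equals ref ({ref})")
    if ref in PYRIMIDINES:
        return f"{ref}>{alt}", context
    return f"{reverse_complement(ref)}>{reverse_complement(alt)}", reverse_complement(context)


def substitution_spectrum(
    variants, genome: CircularGenome, kind: str = "SBS96"
) -> Spectrum:
    """Substitution spectrum of SNVs with trinucleotide context read from
    the circular genome (position 1's 5' neighbor is the last base)."""
    if kind not in ("SBS6", "SBS96"):
        raise ParameterError(f"kind must be SBS6 or SBS96, got {kind!r}")
    spec = Spectrum.zeros(kind)
    index = {l: i for i, l in enumerate(spec.labels)}
    for v in variants:
        call = getattr(v, "call", v)
        if call.var_class is not VarClass.SNV:
            continue
        context = genome.fetch(call.pos - 1, 3)
        sub, ctx = _collapse_snv(call.ref, call.alt, context)
        label = sub if kind == "SBS6" else f"{ctx[0]}[{sub}]{ctx[2]}"
        spec.counts[index[label]] += 1
    return spec


def _homopolymer_run(genome: CircularGenome, pos: int, base: str) -> int:
    """Length of the run of `base` containing/adjacent to `pos`."""
    run = 0
    p = pos
    while genome.base(p) == base and run < genome.length:
        run += 1
        p = genome.wrap(p + 1)
    p = genome.wrap(pos - 1)
    while genome.base(p) == base and run < genome.length:
        run += 1
        p = genome.wrap(p - 1)
    return run


def indel_spectrum(variants, genome: CircularGenome) -> Spectrum:
    """Simplified indel spectrum: type x (1 bp vs longer) x homopolymer
    context (unit base sits in a run of >= 3 identical bases) vs not."""
    spec = Spectrum.zeros("ID_simple")
    index = {l: i for i, l in enumerate(spec.labels)}
    for v in variants:
        call = getattr(v, "call", v)
        if call.var_class is VarClass.SNV:
            continue
        if call.var_class is VarClass.INSERTION:
            kind, unit, anchor = "ins", call.alt[1], call.pos + 1
        else:
            kind, unit, anchor = "del", genome.base(call.pos), call.pos
        length = abs(call.indel_length)
        size = "1" if length == 1 else "long"
        homop = _homopolymer_run(genome, anchor, unit) >= 3
        label = f"{kind}_{size}_{'homopolymer' if homop else 'other'}"
        spec.counts[index[label]] += 1
    return spec


def cosine_similarity(spectrum: Spectrum, reference: Spectrum) -> float:
    """Cosine of the angle between two spectra over the same class set."""
    if spectrum.kind != reference.kind or spectrum.labels != reference.labels:
        raise ParameterError("spectra have different class sets")
    a, b = spectrum.counts.astype(float), reference.counts.astype(float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InsufficientDataError("cosine similarity undefined for all-zero spectrum")
    return float(np.dot(a, b) / (na * nb))


def load_reference_spectra() -> dict[str, Spectrum]:
    """Packaged reference spectra for similarity comparisons.

    These are synthetic stand-ins shaped like published catalog signatures
    (a flat clock-like substitution profile; a homopolymer-deletion-heavy
    indel profile), not the catalog entries themselves, which cannot be
    bundled. Swap in a fuller table for real analyses.
    """
    import pandas as pd

    from .reference import _data_path

    df = pd.read_csv(_data_path("reference_spectra_synthetic.tsv"), sep="\t")
    out: dict[str, Spectrum] = {}
    for sig, sub in df.groupby("signature"):
        kind = sub["kind"].iloc[0]
        spec = Spectrum.zeros(kind)
        weights = dict(zip(sub["class"], sub["weight"]))
        spec.counts = np.array([weights.get(l, 0.0) for l in spec.labels])
        out[sig] = spec
    return out
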