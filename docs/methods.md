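# Methods

## Coordinate model

All coordinates are 1-based inclusive on a circular genome (the rCRS
convention for human mtDNA, 16,569 bp); position arithmetic wraps modulo
the length, so the trinucleotide context of position 1 uses position 16,569
as its 5′ neighbor. Wrap-around features are stored as two linear regions
sharing a name — the D-loop is the pair (1–576, 16,024–16,569). Conversion
to 0-based half-open coordinates happens only inside file writers (VCF).

The packaged region table carries the NC_012920.1 feature layout (13 CDS,
22 tRNA, 2 rRNA, D-loop, intergenic gap-fill). The genome *sequence* is not
bundled: synthetic seeded sequences stand in wherever a sequence is needed,
so coding-effect results on the packaged layout are exercised with real
feature geometry but synthetic codons. Users supply a real FASTA for real
analyses.

Overlapping features (e.g. ATP8/ATP6) are all retained; when a single
region must be chosen for effect classification the priority is
CDS > tRNA > rRNA > D-loop > intergenic.

## Synthetic sequencing model

`simulate_pileup` draws per-position depth Poisson(mean depth; default
30,000, the platform target the pipeline assumes), applies an optional
per-read quality pass/fail mask (stand-in for a Phred ≥ 30 screen — callers
see only passing reads), and draws non-reference reads
Binomial(depth, e_i), split uniformly over the three non-reference bases.

The per-position error rate is e_i = e · m_i with e = 5 × 10⁻⁴ by default
(a free parameter of the synthetic platform, not a measured value) and m_i
a log-normal multiplier, LogNormal(0, σ). The multiplier is
**median-normalized**: m_i = 1 at a typical position, and dispersion raises
the mean and right tail, the way context-dependent platform error does.
This choice matters: with a *mean*-normalized multiplier, the Tukey fence
of the error distribution is capped near 2.5× the mean rate for any σ,
which is too tight a ceiling to reproduce the qualitative behavior of the
admixture experiment (below). Planted SNVs draw alt reads
Binomial(depth, VAF) with errors superimposed on the remainder; indels and
homopolymer-hotspot slippage reads are sparse per-position records.

What the generator does **not** model: read-level artifacts (strand bias,
position-in-read effects), alignment error, NUMT contamination, PCR
jackpot duplicates. A green test on synthetic data therefore establishes
that the *procedure* behaves as specified under its stated error model,
not that the thresholds transfer to any particular real platform.

## Admixture experiment

`simulate_admixture_pair` emulates the background/spike design used to
calibrate detection: 13 shared and 23 spike-private homoplasmies (the
configuration of the cell-line-vs-tissue pair the analysis is modeled on).
Two modeling choices, each with independent grounding:

- the per-position error multiplier array is **shared** between the two
  samples of a pair — positional error is a property of the platform and
  sequence context, not of the sample;
- homoplasmy positions are drawn from **clean positions** (m_i ≤ 1),
  mirroring the ascertainment that sites called confidently homoplasmic
  are, by construction, sites with well-behaved error.

Mixing is binomial thinning at read-count level (keep background reads
with probability 1−r, spike reads with probability r), which matches
file-level read splitting in expectation and conserves expected depth.

The dispersion default σ = 1.2 was fixed once, by scanning σ for the
qualitative separation the experiment is designed to exhibit (the 0.5%
mixture's lower confidence limit above the background fence, the 0.25%
mixture's below it). With it, the synthetic fence and limits
(≈ 0.0025 / 0.0018 / 0.0039) sit close to the published worked-example
values (0.00204 / 0.00178 / 0.00376), and the separation held in 100/100
seeds over two disjoint 50-seed batches.

Numerical conventions, fixed because Tukey fences vary by quantile method:
quartiles use linear interpolation between order statistics (R type 7 /
numpy default); the lower confidence limit uses the n−1 sample SD and may
be negative (meaning the ratio is indistinguishable from zero); cutoff
selection requires the limit to *strictly* exceed the fence; positions
with zero passing depth are skipped, not treated as VAF 0. The fence is
computed over all background positions including the background's own
homoplasmies (a handful of near-1 values barely move genome-wide
quartiles); an option excludes them.

## Caller and filters

Every non-reference base or distinct indel allele with ≥ 2 supporting
reads (guarding against single-read artifacts at extreme depth;
configurable) and VAF ≥ cutoff becomes a call; VAF denominators are
quality-passing reads only. Heteroplasmic means cutoff ≤ VAF < 0.95 (lower
bound inclusive, upper exclusive); homoplasmic means VAF ≥ 0.95.

Site filters flag rather than drop calls, and flagged calls are excluded
from all downstream counting: SNVs in 302–315 and 3105–3109 in every
sample; SNVs at 248/16,256 only in samples whose call set contains a
homoplasmic (VAF ≥ 0.95) deletion at that position; indels at
11,031/12,417 always; and any indel allele present in ≥ 100% of cohort
samples (the most conservative reading of "detected commonly" — the
threshold is configurable, and the known 59/77-type recurrence at 11,031
is handled by its explicit positional flag). The poly-C and spacer filters
target misaligned SNVs only; artifactual indels there are caught by the
common-indel rule.

## Effects and deleteriousness

SNV effects are computed from first principles: substitute the base into
its codon (respecting strand — one CDS and several tRNAs lie on the L
strand, where the coding codon is the reverse complement read downward —
and the circle) and translate under the vertebrate mitochondrial code
(TGA = Trp, AGA/AGG = stop). A CDS indel is a frameshift iff its length is
not divisible by 3. Deleterious = nonsense ∪ frameshift ∪
(missense confirmed pathogenic in the lookup table) ∪ (tRNA variant with
confirmed/likely/possibly-pathogenic category). The packaged pathogenicity
table is a small curated stand-in for web annotators that cannot be
bundled; it is a lookup mechanism, not a catalog. Burdens count distinct
deleterious PASS heteroplasmic (pos, allele) pairs per sample within a VAF
window, default [cutoff, 0.95); narrow report windows can close the upper
bound.

## Copy number

CN = 2^(Ct_PPIA − Ct_ND1): ideal per-cycle doubling, no efficiency
correction, replicate Ct values pre-averaged by the user. "Normalization"
of burdens by CN is division (variants per copy-number equivalent), with a
per-1000-copies display scale. The cohort generator back-computes Ct pairs
from sampled CN by inverting this relation, so with zero Ct noise the
estimator recovers the generated CN exactly — a deliberate round-trip.

## Cohort model

Default stage sizes 16/15/4/42 (G1/G2/G4/G5; no G3, matching the cohort
structure the pipeline emulates; the stage enum accepts arbitrary ordered
labels). Per-sample deleterious counts are Poisson with mean
0.3 + 0.5·k at stage index k — chosen so per-patient counts stay in the
observed 0–3 range while the trend is detectable at the cohort's sizes —
and copy number is log-normal (CV 0.3, typical for bulk qPCR) around
1500 − 250·k, halving from G1 to G5, consistent with a strongly
significant decline at these group sizes. Ages are uniform on 40–80 years.

## Statistics

- **Jonckheere–Terpstra** (implemented in-package): J = Σ_{i<j} U_ij with
  ties counting ½. Exact p by exhaustive enumeration for n ≤ 12, seeded
  Monte-Carlo permutation, or the tie-corrected normal approximation
  (Hollander & Wolfe moments) for cohort-sized data. The directed
  statistic for a decreasing alternative is computed on negated values.
- **Dunnett** many-to-one: classical pooled-variance form on raw values,
  family-wise adjusted over the joint max-|t| distribution (scipy's
  seeded quasi-Monte-Carlo evaluation of the multivariate t). Counts are
  non-normal; the choice matches common practice, and family-wise error
  control under the null is verified by simulation in the test suite.
- **Kruskal–Wallis / chi-squared / Spearman** via scipy; 2×2 tables use
  the Yates continuity correction by default (the R convention),
  toggleable. All-identical Kruskal–Wallis input returns (0, 1) by
  contract; constant correlation input raises rather than returning NaN.
- **Spectra**: SBS6/SBS96 with pyrimidine-centred collapse and circular
  trinucleotide context. The indel taxonomy is deliberately simplified
  (type × 1-bp-vs-longer × homopolymer context, 8 classes) rather than the
  83-class nuclear-genome scheme: a 16.6 kb genome yields far too few
  indels to populate 83 classes, and the package's own position is that
  nuclear signature frameworks transfer poorly to mtDNA. Cosine similarity
  requires identical class sets and raises on all-zero vectors. Packaged
  reference spectra are synthetic stand-ins (labelled `_synthetic`), not
  catalog entries.

## Degenerate inputs and tie-breaks

Zero-depth positions are skipped by VAF computations and raise when asked
directly. The fence needs ≥ 4 values, the lower limit ≥ 2, correlations
≥ 3 pairs. Region queries on out-of-range positions raise coordinate
errors. Duplicate (pos, allele) pairs count once per sample in burdens.
Deletions at position 1 cannot be left-anchored in VCF and are rejected by
the writer. VAF survives VCF round trips at float32 precision; all other
fields are exact.

## Known limitations

- The admixture world is calibrated to reproduce the *qualitative*
  fence-vs-limit geometry; its absolute fence value tracks the synthetic
  error model, not any particular instrument.
- The caller has no strand-bias or read-position evidence, so it cannot
  discriminate certain real-data artifact classes the filters do not
  cover.
- Coding-effect tests run on synthetic sequences; with a real reference
  FASTA the same code paths apply unchanged, but packaged fixtures cannot
  verify real-sequence annotations.
- Cohort statistics on real data would require the controlled-access
  sequencing inputs; the package verifies procedure correctness and
  calibration, not published effect sizes.
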