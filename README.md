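# mthet

Low-level mitochondrial DNA heteroplasmy analysis for ordered-stage cohort
studies (e.g. kidney tissue across chronic kidney disease stages G1–G5).

Bulk tissue carries thousands of mitochondrial genomes per cell, so a
pathogenic mtDNA allele can be present in only a fraction of them
(*heteroplasmy*). Ultra-deep amplicon sequencing (~30,000×) makes variant
allele frequencies (VAF) below 1% measurable in principle — but at that
depth, platform error produces non-reference reads at every position, and
the central analytical problem is deciding where background error ends and
real heteroplasmy begins. `mthet` implements a complete, testable pipeline
for that problem, with seeded synthetic-data generators standing in for
controlled-access sequencing data:

1. **Cutoff determination by in silico admixture.** Reads from a background
   sample (a monoclonal cell line) and a spike sample carrying private
   homoplasmic variants are mixed at small ratios r ∈ {2%, 1%, 0.5%,
   0.25%}, creating artificial heteroplasmies of known frequency. Per
   position, the non-reference VAF is
   `(total reads − reference reads) / total reads`. Background error is
   bounded by the Tukey fence `Q3 + 1.5·IQR` over the background sample's
   genome-wide VAFs; each ratio gets a lower confidence limit
   `mean − 3·SD` over the artificial sites. The minimum usable VAF cutoff
   is the smallest ratio whose lower limit stays strictly above the fence.
2. **Pileup variant calling** of SNVs and indels at the selected cutoff
   (heteroplasmic: cutoff ≤ VAF < 95%; homoplasmic: VAF ≥ 95%), with
   mitochondria-specific site filters: the poly-C stretch (302–315), the
   3107 spacer context (3105–3109), deletion-shadow SNVs at 248/16,256 in
   homoplasmic-deletion carriers, and recurrent homopolymer indels at
   11,031/12,417 plus cohort-wide common indels.
3. **Annotation on the circular genome** (rCRS 1-based coordinates, D-loop
   spanning the origin): region join, codon-level effect classification
   under the vertebrate mitochondrial code, the frameshift rule (CDS indel
   length not divisible by 3), and deleterious classification (nonsense,
   frameshift, confirmed-pathogenic missense, pathogenic tRNA).
4. **mtDNA copy number** from paired qPCR Ct values,
   `CN = 2^(Ct_PPIA − Ct_ND1)`, and copy-number-normalized burdens.
5. **Ordered-stage statistics**: Jonckheere–Terpstra trend test (exact /
   Monte-Carlo permutation or tie-corrected normal approximation), Dunnett
   many-to-one comparisons, Kruskal–Wallis, 2×2 chi-squared, Spearman age
   correlation, and pyrimidine-collapsed SBS6/SBS96 mutational spectra with
   cosine similarity.

## Worked example

```python
from mthet import random_genome, simulate_admixture_pair, run_admixture_experiment

genome = random_genome(16569, seed=1)
background, spike, private = simulate_admixture_pair(genome, seed=0)
result = run_admixture_experiment(background, spike, private,
                                  ratios=[0.02, 0.01, 0.005, 0.0025], seed=0)
print(f"upper fence      : {result.upper_fence:.5f}")
for r in sorted(result.lower_limits, reverse=True):
    print(f"lower limit {r:>6.2%}: {result.lower_limits[r]:.5f}")
print(f"selected cutoff  : {result.selected_cutoff:.2%}")
```

prints

```
upper fence      : 0.00262
lower limit  2.00%: 0.01800
lower limit  1.00%: 0.00783
lower limit  0.50%: 0.00396
lower limit  0.25%: 0.00149
selected cutoff  : 0.50%
```

Reading: background error alone can push a position's non-reference VAF up
to ~0.26%. The 0.25% mixture's lower confidence limit (0.00149) falls below
that fence — at that level, true heteroplasmies are not separable from
error — while the 0.5% mixture's limit (0.00396) stays above it, so 0.5% is
the smallest trustworthy VAF cutoff for this (synthetic) platform.

The same stages are scriptable from a shell:

```sh
mthet simulate --length 16569 --seed 0 --out-prefix demo
mthet threshold --background demo.background.tsv --spike demo.spike.tsv \
      --private-sites demo.private.txt --ratios 0.02,0.01,0.005,0.0025 \
      --seed 0 --out threshold.json
mthet run --seed 7 --outdir demo_run   # full synthetic pipeline
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package, the cutoff selected from the published
upper fence and per-ratio lower confidence limits of the admixture
experiment, reported as a percent.

## Layout

- `mthet.reference` — circular genome model, region tables (packaged
  rCRS-layout fixture), mitochondrial genetic code, pathogenicity lookups
- `mthet.simulate` — seeded pileup / admixture-pair / cohort generators
- `mthet.admixture` — mixing, fence, lower limits, cutoff selection
- `mthet.calling` — threshold caller and site filters
- `mthet.annotate` — effects, deleterious classification, burdens
- `mthet.copynumber` — qPCR copy number and burden normalization
- `mthet.stats` — trend tests, many-to-one comparisons, spectra
- `mthet.io` / `mthet.cli` / `mthet.pipeline` — formats, CLI, orchestration

See `docs/methods.md` for the models, parameter choices, and limitations.
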