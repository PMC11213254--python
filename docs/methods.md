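# Methods

## The two DMR-calling procedures

Both modes tile the genome into non-overlapping 100-bp windows; a trailing
partial window at a chromosome end is kept (truncated). All internal
coordinates are 0-based half-open; cytosine reports are read 1-based
(Bismark CX convention) and BED is written 0-based.

**Population mode** (two haplotype groups of inbred lines, ≥2 lines each):

1. Per line, only cytosines of the requested context covered by ≥2 reads
   count. This single coverage rule feeds both the retention filter and the
   level computation, so retention and levels are always consistent.
2. A window is retained when strictly more than 50% of lines in *both*
   groups have ≥3 such sites (CG/CHG) or ≥6 (CHH). The CHH "6 methylation
   sites" rule is read as six cytosine *positions*, parallel to the CG/CHG
   site-count rule, not as six methylated reads.
3. Adjacent retained windows (zero gap, same chromosome) merge into
   regions; merged regions are maximal.
4. Per-line region levels are recomputed as the weighted level
   Σ n_meth / Σ n_total over the region's qualifying sites (a
   mean-of-fractions switch exists but is not the default: the weighted
   level is the standard for read-count data). Lines with no qualifying
   site in a region are missing, and missing lines are dropped, not
   imputed.
5. A t-test compares the two groups per region. The flavor is Welch
   (unequal variances, Welch–Satterthwaite df) by default with a pooled
   Student option; this comparison is conventionally described only as a
   "t-test", and Welch is the safer default for unequal group variances. Regions with
   fewer than two informative lines in either group are skipped and
   logged. When both groups have zero variance the region is treated as a
   tie (t = 0, p = 1) rather than propagating NaN or an infinite statistic.
6. DMRs are regions with p < 0.05 and |difference| > 10% (CG/CHG) or > 5%
   (CHH). No multiple-testing correction is applied by default — the procedure
   thresholds raw p-values — but a Benjamini–Hochberg flag is available.

**Pairwise mode** (one wild type vs one mutant): windows are retained when
both samples have ≥3 (CG/CHG) or ≥6 (CHH) context cytosines and mean
coverage ≥2×; per-window weighted levels are compared (|Δ| ≥ 60% for
CG/CHG; for CHH, |Δ| > 20% with min(level) < 5% and max(level) > 25%);
*surviving* windows are merged and region levels recomputed. The two modes
intentionally order merge-vs-test differently (population: merge → test;
pairwise: filter → merge), matching the two workflows they implement.

Direction is always relative to the declared reference (the Indel-7080Ref
haplotype or the wild type): "hypo" means the focal group (Indel-7080In or
the mutant) is lower. Swapping the groups flips every label and negates
every difference while leaving |difference| and p unchanged — a property
the test suite checks.

Symmetric CG sites on opposite strands are kept as separate sites — no
strand-collapsing — so window statistics count sites exactly as the
cytosine report lists them.

## Annotation and enrichment

Promoters are the 2-kb interval upstream of the transcript start on the
gene's strand, truncated at chromosome bounds. Overlap is ≥1 shared base on
0-based half-open intervals; a DMR may hit several feature classes and is
intergenic only when it hits none. Gene association (body or promoter
overlap) exposes an optional symmetric widening distance (default 0;
2000 reproduces a "within 2 kb" association — both definitions appear in
the literature for this analysis, so the parameter is explicit rather than
silently reconciled).

DEG status is re-derived from FDR < 0.05 and |log2FC| > 1 on read, never
trusted from the input file. The enrichment comparison is the
two-proportion chi-square with Yates continuity correction (the default
behaviour of R's `prop.test`), two-sided, on
[[k1, n1−k1], [k2, n2−k2]]; a flag disables the correction. The background
is the caller-supplied expressed-gene universe, not all annotated genes.
The Mann–Whitney test uses the exact distribution when n1·n2 ≤ 400 and the
data are tie-free, otherwise the normal approximation with tie and
continuity corrections.

## Diversity and the coalescent selection test

π is the mean over sequence pairs of per-site differences with pairwise
deletion (a site counts for a pair only if neither sequence has N or a
gap). Sliding profiles use a 100-bp window and 25-bp step and drop any
trailing partial window, mirroring the behaviour of standard diversity
software — deliberately different from the DMR tiling convention, and
documented separately for that reason. Watterson's θ_W = S/(a_{n−1}·L)
uses columns with ≥2 distinct valid bases as segregating sites.

The coalescent simulator is ms-style: the internal clock runs in units of
2N₀ generations, k lineages in an epoch of relative size s coalesce at
rate C(k,2)/s, and mutations are an infinite-sites Poisson process of rate
θ/2 per unit time per unit ancestral material, so E[S] = θ·a_{n−1} and
E[π] = θ at constant size (verified against closed forms and, under the
bottleneck, against an independent branch-length computation with
msprime/tskit in the test suite). Recombination (ρ > 0) uses the ancestral
recombination graph with crossover on the span of ancestral material;
segments that reach their local MRCA drop out. ρ defaults to 0 because
crossover within a 360-bp fragment is negligible.

`DemographyModel` accepts epoch times in units of 4N₀ generations (the ms
convention) and encodes present size 1, a bottleneck of size
k·N_ancestral, then the ancestral size. Published maize domestication
models vary in their exact bottleneck parameterization, so all three
parameters are explicit configuration.
The defaults assume ancestral N = 150,000, domestication 9,000 generations
ago (t_start = 9000/(4·150000) = 0.015), a 1,000-generation bottleneck
(duration ≈ 0.00167) and severity k = 0.05 — magnitudes consistent with
published maize domestication models. Nothing is hidden: a different
parameterization is three keyword arguments away.

The selection test simulates, per replicate, an independent derived sample
under the bottleneck and an ancestral sample at constant size, both at the
θ estimated from the ancestral data, and compares the observed π_M/π_T
against the simulated ratio distribution with the add-one convention
p = (1 + #{ratio ≤ obs})/(n_reps + 1), one-sided lower tail (selection
reduces diversity; the p-value can never be exactly 0). Replicates whose
ancestral sample is monomorphic are redrawn and counted. Modeling maize
and teosinte as diverged demes with migration is out of scope; the two
samples share θ but not a genealogy. A maize-π-only statistic
(`statistic='derived_pi'`) is exposed as an alternative — the literature
uses both the ratio and the derived diversity conditioned on an
ancestrally estimated θ — and the ratio is the default.

## What the synthetic data emulates — and what it does not

The generators are pure functions of config + seed (byte-identical reruns)
and produce truth tables sufficient to score every planted feature.

- **Cytosine catalog**: per-context densities default to maize-gene-space
  magnitudes (~6 CG, ~6 CHG, ~12 CHH sites per 100-bp window); positions
  are uniform. Real context spacing (CG clustering, TE-dense CHH islands)
  is not modeled.
- **Coverage**: per-site Poisson with mean 10×, multiplied by a per-window
  mappability factor shared by all samples — 35% of windows are
  repeat-like (factor 0.05, effectively unsequenceable), the rest
  fluctuate mildly (Gamma, CV ≈ 0.22). Shared mappability is what makes
  window retention patchy in real WGBS; modeling it (rather than thinning
  cytosine density) keeps retained windows site-rich, so region levels
  have realistic precision. Zero-coverage sites arise naturally and
  exercise the coverage filters.
- **Methylation counts**: beta-binomial around the group×context mean with
  precision 20, because real WGBS is overdispersed relative to binomial —
  binomial counts would make the calibration tests anti-conservative.
  Baselines CG 0.85, CHG 0.70, CHH 0.05 follow the maize-typical ordering.
- **Population fixture**: 6 + 6 lines (the study design), a global CHG
  shift of −0.01 on the Indel-7080In group, and 30 planted two-window CHG
  DMRs of effect −0.3. The global shift is kept small because genome-wide
  methylation differences between natural haplotype groups are subtle —
  typically resolvable only in panels of hundreds of lines, not in a
  6-vs-6 comparison — and a shift large relative to the 10% difference
  threshold would be unrealistic. Planted DMRs are
  placed only at loci the caller could in principle retain (both windows
  mappable with ≥3 CHG sites) and are flanked by non-retainable windows so
  the planted loci stay discrete after merging: a "DMR" planted in an
  unsequenceable or site-free region is not an observable region under the
  procedure's own definition.
- **Mutant pair**: genome-wide CHG ×0.65 and CHH ×0.5 depletion in the
  mutant (large, but below the 60% pairwise threshold: in chromomethylase
  mutants genome-wide loss and discrete deep-loss loci coexist), plus 20
  planted CHG regions depleted to ×0.05 of baseline and 10 CHH islands
  (WT 0.35 → mutant 0.03) constructed to satisfy the compound CHH rule.
  CG is untouched.
- **Expression**: genes overlapping planted hypomethylated DMRs (body or
  2-kb promoter) are DEGs with probability 0.101, background 0.078 — the
  two proportions the enrichment analysis contrasts; 67% of
  hypo-associated DEGs are up-regulated. Effect sizes are 1 + Exp(0.8) in
  |log2FC|; FDR fields are drawn consistent with status.
- **Alignments**: a 360-bp locus, 21 teosinte haplotypes at constant size
  and 20 maize haplotypes under the bottleneck, rendered as biallelic
  substitutions on a shared random reference; θ defaults to 5 per locus
  (teosinte-like diversity of ~1.4% per bp). No indels, no sequencing
  error, no population structure within classes.

Passing the planted-truth tests therefore shows the pipeline implements
its own rules correctly at realistic signal-to-noise, not that it would
reproduce genome-scale DMR counts from real data, which depend on the real
genome, its coverage structure, and the population's history.

## Problem sizes and numerical choices

The default synthetic genome is one 100-kb chromosome (~1,000 windows,
~24,000 cytosines per sample) — large enough for a few hundred tested
regions while keeping a full population simulation around two seconds.
Closed-form coalescent checks use 10,000 replicates (3 Monte-Carlo SE
bounds); the null-uniformity check uses 200 selection tests of 100
replicates each; the acceptance script's selection tests use 1,000
replicates. Degenerate inputs are values, not errors, wherever the
original procedure would simply not call a region (missing levels,
untestable regions, tied variances); malformed files and impossible
parameters raise typed errors (`ParseError`, `ValidationError`).

Known limitations: no smoothing/HMM/beta-binomial regression in the DMR
caller (not a general-purpose caller by design); no strand-collapsing of
symmetric CpGs; no Tajima's D or multi-deme models; the enrichment test
assumes the DMR-associated gene set is a subset of the expressed universe;
the ARG implementation is quadratic in lineage segments and meant for
short loci, not chromosomes.
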