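# huskmeth

Analysis toolkit for a maize epigenetics question: how natural and induced
variation in the CHG methyltransferase gene *ZMET2* reshapes the methylome,
gene expression, and — at the causal 3′UTR indel (Indel-7080) — the
population-genetic signature of domestication selection.

The package re-implements, as tested and reusable components, the three
computations such a study chains together:

1. **Windowed DMR calling** from Bismark-style per-cytosine reports, in two
   modes. *Population mode* compares two haplotype groups of inbred lines:
   100-bp windows are retained when more than half the lines in both groups
   have ≥3 (CG/CHG) or ≥6 (CHH) cytosines covered by ≥2 reads, adjacent
   retained windows are merged, per-line weighted region levels
   (Σ methylated / Σ total reads) are recomputed, and a Welch *t*-test plus
   a difference threshold (>10% CG/CHG, >5% CHH at *P* < 0.05) defines the
   DMRs. *Pairwise mode* compares one mutant against one wild type with
   pure threshold rules (|Δ| ≥ 60% for CG/CHG; for CHH, |Δ| > 20% with one
   sample < 5% and the other > 25% methylated), filtering windows before
   merging.
2. **DMR annotation and DEG enrichment**: promoters as the 2-kb upstream
   interval, ≥1-bp overlap assignment to gene body / promoter / TE /
   intergenic, and a two-proportion chi-square test with Yates continuity
   correction (R's `prop.test`) comparing the DEG fraction among
   DMR-associated expressed genes with the genome-wide fraction.
   Mann–Whitney *U* tests for haplotype-vs-trait and global-methylation
   group comparisons.
3. **Diversity and a selection test**: nucleotide diversity π (pairwise
   deletion), sliding 100-bp/25-bp profiles, Watterson's
   θ_W = S / (a_{n−1}·L), and the retained-diversity ratio π_M/π_T of a
   maize allele class relative to teosinte. The ratio is tested against its
   neutral distribution under a domestication bottleneck using an ms-style
   coalescent simulator (piecewise-constant sizes, infinite-sites
   mutations, optional ARG recombination) written in this package:
   *p* = (1 + #{ratio_sim ≤ ratio_obs}) / (n_reps + 1), lower tail, since
   selection removes diversity beyond the bottleneck's expectation.

A seeded synthetic-data module generates every input the pipeline consumes
(population methylomes with planted DMRs, a wild-type/mutant pair, DEG
tables coupled to hypomethylated regions, maize/teosinte alignments with a
bottleneck) together with truth tables, so the whole pipeline is testable
without any external download.

## Worked example

```python
from huskmeth import simulate, dmr, popgen

cfg = simulate.SimConfig(seed=11)
wt, mut, truth = simulate.simulate_pair_methylomes(cfg)
regions = dmr.call_dmrs_pairwise(wt, mut, "CHG")
s = dmr.dmr_direction_summary(regions)
print(f"{s.n_total} CHG DMRs ({s.n_hypo} hypo / {s.n_hyper} hyper, "
      f"{s.pct_hypo}% hypomethylated)")
for d in regions[:3]:
    print(f"  {d.chrom}:{d.start}-{d.end}  WT {d.level_a:.3f}  "
          f"zmet2-1 {d.level_b:.3f}  diff {d.difference:+.3f}  {d.direction}")

res = popgen.selection_test(0.106, 20, 21, 5.0, n_reps=1000, seed=1)
print(f"selection test: ratio 0.106 -> p = {res.p_value:.4f} "
      f"({res.n_reps} replicates)")
```

prints

```
20 CHG DMRs (20 hypo / 0 hyper, 100.0% hypomethylated)
  chr1:400-600  WT 0.732  zmet2-1 0.000  diff -0.732  hypo
  chr1:7200-7400  WT 0.752  zmet2-1 0.056  diff -0.696  hypo
  chr1:10900-11000  WT 0.646  zmet2-1 0.000  diff -0.646  hypo
selection test: ratio 0.106 -> p = 0.0140 (1000 replicates)
```

The caller recovers the planted CHG depletions of the mutant fixture, all
hypomethylated as planted, and a locus retaining only 10.6% of ancestral
diversity sits in the lower tail of the neutral bottleneck distribution —
evidence of selection beyond demography.

The same stages are scriptable from the shell:

```bash
huskmeth simulate pair --seed 5 --out-dir sim/
huskmeth call-dmrs --mode pairwise --context CHG \
    --cytosine-reports 'sim/*.CX_report.txt' \
    --sample-sheet sim/sample_sheet.tsv --out dmrs.bed
huskmeth annotate --dmrs dmrs.bed --genes genes.gff3 --out features.tsv
huskmeth popgen selection-test --derived maize.fasta --ancestral teosinte.fasta \
    --reps 10000 --seed 1 --out selection.json
```

Every run writes a JSON manifest (parameters, seed, input checksums,
record counts per stage).

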