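# polysel

Polygenic selection scans for target gene sets: per-SNP selection
statistics, matched-gene resampling nulls, gene-set enrichment tests,
outlier calling, and genotype–environment association — with a seeded
synthetic-data generator so the whole chain runs end to end on a laptop.

## The scientific problem

Classical selection scans look for single outlier loci. Polygenic
adaptation instead shifts a whole *set* of functionally related genes —
say, the two families of zinc transporters that regulate zinc
homeostasis — by amounts that are individually unremarkable. Detecting
that shift requires set-level inference: score every gene in the genome,
then ask whether the target set as a whole is more extreme than sets of
comparable genes.

"Comparable" is the crux. Long genes, GC-rich genes, and genes in
low-recombination regions have systematically different score
distributions, so the null must be built from reference genes matched on
those confounders. This package implements that design:

1. **Per-SNP statistics** — Weir–Cockerham FST (variance components with
   the n_c correction; negative estimates preserved), EHH decay and
   iHS = ln(iHH_derived / iHH_ancestral) with the standard integration
   guards, XP-EHH with the pooled-EHH stopping rule, Tajima's D, and
   haplotype LD r².
2. **Per-gene aggregation** — weighted-average (ratio-of-sums) and
   maximum FST, max/average |iHS| after standardization within
   derived-allele-frequency bins.
3. **Matched resampling null** — each target gene is matched to
   reference genes within 20% on coding length, GC fraction, and
   recombination rate; null sets draw one matched gene per target with
   within-set distinctness.
4. **Enrichment tests** — rank test on the target mean, a proportion
   test on the fraction of target SNPs above each null set's own
   99th-percentile cutoff, and SUMSTAT (sum of per-gene maxima
   standardized within SNP-count bins, controlling SNP density).
5. **Outliers and candidates** — top-1% gene outliers against the
   reference distribution; SNP candidates by resampling consistency
   (above the cutoff in ≥ 95% of sets); a functional-relevance filter
   over CADD / Eigen / Eigen-PC / FitCons annotations.
6. **Genotype–environment association** — logistic regression of each
   genotype state's presence on a population-level environment value
   (zinc deficiency prevalence) with two genotype principal components
   as structure covariates; G (likelihood-ratio) and Wald scores, each
   Benjamini–Hochberg adjusted, significance requiring both; Spearman
   frequency–environment correlations as a complement.

Everything runs on synthetic inputs from `polysel.synthetic`:
Balding–Nichols structured genotypes, founder-mosaic haplotype regions
with an optional injected sweep, gene tables with guaranteed matched
pools, and an environment gradient with an optional causal SNP.

## Worked example

Per-gene FST from simulated two-population genotypes
(`examples/01_fst_scan.py`):

```text
simulated 2000 SNPs x 100 diploids in 2 populations
genome-wide ratio-of-sums FST: 0.0966  (generative F = 0.1)
per-SNP theta: mean 0.0809, min -0.0126, max 0.6172
negative estimates preserved: 444 SNPs below zero
first 30 SNPs as one gene: WA FST 0.1009, Max FST 0.5255
```

Matched resampling and enrichment (`examples/03_enrichment.py`):

```text
1300 genes, 24 targets; pool sizes 50..129
drew 500 matched null sets of 24 genes
null scores:     rank p = 0.976, SUMSTAT p = 0.976
targets +1 sigma: rank p = 0.002, SUMSTAT p = 0.002
```

The other examples cover the haplotype scans with an injected sweep
(`02`), the environment association (`04`), and the full pipeline with
its deterministic TSV outputs (`05`). A thin CLI wraps the same library
calls:

```bash
polysel simulate --n-genes 1300 --out genes.tsv
polysel run --config run.yaml --out-dir out/
```

## Layout

```
src/polysel/       library (synthetic, io, stats, matching, enrichment,
                   outliers, gea, pipeline, experiments, cli)
tests/             unit, property, and acceptance tests (+ brute-force oracles)
examples/          short narrative scripts, one per capability
scripts/           acceptance.py
docs/methods.md    model and parameter documentation
```
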