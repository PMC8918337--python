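# Methods note

What the statistics compute, what the synthetic generators emulate (and
deliberately don't), the package's default parameters and why, and the
numerical choices that affect results.

## Per-SNP statistics

**Weir–Cockerham FST.** Two-population method-of-moments estimator with
the a/b/c variance components and the n_c sample-size correction.
Inputs per population are the number of called diploids, the
alternate-allele frequency, and the observed heterozygote proportion;
missing genotypes are excluded before any of these are formed. Per-SNP
θ = a/(a+b+c) is NaN where both samples are monomorphic and *negative
estimates are preserved* — clipping at zero would bias every sum built
from the components. Per-gene summaries are the weighted-average FST
(ratio of sums Σa / Σ(a+b+c), not the mean of ratios) and the maximum
per-SNP θ.

**EHH / iHS.** EHH(d) is the probability that two random haplotypes of
an allele class are identical at every marker from the core out to
distance d, computed by incremental relabelling of extended haplotypes.
iHS = ln(iHH_derived / iHH_ancestral), where iHH integrates EHH over
physical distance (trapezoids between adjacent markers) with the usual
guards (`ScanParams` defaults): integrate until EHH < 0.05, cap the
extension at 1 Mb, abort the locus at an inter-marker gap > 200 kb, and
scale the contribution of gaps > 20 kb by 20 kb / gap. Cores with
derived frequency outside [0.05, 0.95], unknown ancestral state, or
fewer than two carriers in either class are skipped. With
`trunc_ok=False` (the strict default) a walk that reaches the region
edge before the cutoff invalidates the locus; simulated gene regions
here are only hundreds of kb, so every simulation-driven analysis sets
`trunc_ok=True` and keeps the partial integral. Raw scores are
standardized within 100 equal-width derived-frequency bins over [0, 1]
(thin bins merged into the nearest populated bin; a zero-variance bin
yields NaN, never a silent zero); downstream analyses use |iHS|.

**XP-EHH.** ln(iHH_obs / iHH_ref) with EHH computed per population over
*all* haplotypes (the core allele is part of the haplotype identity) and
each direction's integration stopped where the pooled two-population EHH
falls below the cutoff, so both populations integrate over the same
interval. The statistic is antisymmetric in the two populations.

**Tajima's D.** From per-site alternate allele counts: π from pairwise
differences via allele counts, S/a1, and the standard e1/e2 variance
constants. A region with no segregating sites returns NaN (the gene is
excluded, not scored 0).

## Matched resampling and enrichment

A reference gene matches a target when it differs by less than 20%
(strict inequality, denominator = the target's value) in coding length,
GC fraction, and recombination rate simultaneously. Targets never enter
pools. A target covariate of exactly zero falls back to an absolute
comparison against tol × the pool median. Null sets draw one pool member
per target slot with within-set distinctness enforced by rejection
resampling of clashing slots.

Rank and SUMSTAT p-values use the (1 + k)/(R + 1) convention and never
reach zero. SUMSTAT standardizes per-gene maxima within equal-occupancy
SNP-count quantile bins computed over the scored reference genes (z or
rank-based inverse normal), which removes the mechanical advantage of
SNP-dense genes. The proportion test follows its literal definition —
p = fraction of resample sets whose target exceedance proportion is at
or below the nominal 1% tail — and can therefore reach 0 or 1; an
`empirical` mode with the (1+k)/(R+1) convention is available.

## Genotype–environment association

Each SNP contributes up to three binary genotype-state indicators
(hom-ref / het / hom-alt). Presence is modelled by logistic regression
(Newton, tol 1e-8, max 50 iterations) on the population-level
environment value plus the first two genotype principal components
(computed from centred genotypes scaled by sqrt(p(1−p)); component signs
fixed by making the largest-magnitude loading positive). The
environment coefficient is scored by G = 2(LL_full − LL_null) against
the model omitting the environment, and by Wald = (β/SE)²; both referred
to χ²(1), each family BH-adjusted, and a state is significant only when
both adjusted values pass q ≤ 0.05 (conjunction switchable).
Non-convergence and quasi-separation (SE > 10³) mark a fit unusable so
it never enters the correction. Spearman frequency–environment
correlations exclude populations with ≤ 10 samples and use the exact
permutation distribution of ρ below 9 populations, the t approximation
above.

*Calibration caveat.* The environment is constant within a population,
so for a population-structured SNP the individual-level likelihood-ratio
test is anti-conservative: the effective sample size is the number of
populations, and two principal components estimated from a few dozen
SNPs cannot fully absorb that structure. The null-calibration experiment
therefore tests the model's own generative null (a SNP drawn with
environment slope 0, independent of structure), where the test holds its
nominal level; interpreting GEA hits at structured SNPs requires many
populations, which is why the reference power condition uses 12.

## Synthetic generators (what they emulate, what they don't)

**Structured genotypes.** Balding–Nichols: ancestral frequency
p ~ Uniform(0.05, 0.95) per SNP; each population's frequency is
Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes Binomial(2, p_pop). This
reproduces the mean differentiation F and is what the FST-recovery
experiment inverts. It does not model LD, admixture, or frequency
spectra under drift.

**Haplotype regions.** A founder-mosaic model: founder haplotypes carry
derived alleles at counts drawn from a neutral site-frequency spectrum
(P(count = i) ∝ 1/i), and each sample haplotype is a recombinant mosaic
of founders with exponential switch distances (mean 20 kb). The founder
count defaults to half the sample haplotype count (minimum 8) so the
sample spectrum tracks the founder spectrum; empirically this keeps
sample Tajima's D near zero (a uniform founder-frequency alternative is
retained as `founder_sfs="uniform"` but inflates D by design). This is
deliberately *not* a coalescent simulation: it gives controllable
extended-haplotype decay — all the haplotype statistics need — at a tiny
fraction of the cost, but its genealogies, LD patterns, and recombination
clustering are not population-genetically faithful.

**Sweep injection.** `round(carrier_fraction × n_haps)` haplotypes
receive the derived allele at the core plus a copy of one template
haplotype over a contiguous tract per side with Exponential(decay_bp)
extent. The marginal probability that a SNP at distance d is overwritten
is exactly exp(−d/decay), while carriers share unbroken homozygous
tracts — the way real sweep haplotypes are broken by single
recombination events — which is what gives the EHH contrast. An earlier
per-SNP independent overwrite with the same marginal probability
produced much weaker iHS signal and was replaced.

**Environment.** Each population draws a zinc-deficiency percentage
~ Uniform(0, 100). An optional causal SNP is resampled with dosage
Binomial(2, expit(α + slope·env)); by default α = −slope·mean(env), so
the baseline carrier probability is 1/2 and prevalence stays interior
for any slope.

**Gene tables.** Log-normal coding lengths, Beta GC, Gamma recombination
rates, roughly mimicking human protein-coding genes; the matched-pool
guarantee (≥ `min_pool` references per target) is met by seeding the
background with jittered copies of the targets inside the tolerance box
and verified by direct filtering.

## Reference validation conditions (`polysel.experiments`)

Chosen once as realistic desk-scale settings and then frozen; the
acceptance tests and `scripts/acceptance.py` run exactly these.

| Experiment | Condition | Expected behaviour |
|---|---|---|
| FST recovery | F ∈ {0.02, 0.1, 0.25}, 2 × 50 diploids, 2000 SNPs, 20 reps | mean ratio-of-sums FST within ±25% of F (observed < 1%) |
| Rank/SUMSTAT null | 1300 genes, 24 targets, 500 sets, 200 reps, iid N(0,1) scores, pseudo-target set redrawn from the pools each rep | rejection rate at p < 0.05 in [0.02, 0.09] |
| GEA G null | 4 pops × 30, 30 SNPs, F = 0.05, slope-0 generative null, 250 fits | rejection rate in [0.02, 0.09] |
| Sweep recovery | 200 reference genes + 1 swept (carrier 0.8, decay 100 kb), 60 SNPs / 400 kb / 60 diploids, 20 reps | swept gene in the top 1% of Max |iHS| in ≥ 90% |
| Environment effect | 12 pops × 25, 40 SNPs, slope 0.15/unit, 20 reps | causal SNP BH-significant in ≥ 80% |
| Determinism | pipeline run twice, one seed | byte-identical outputs |

The null-calibration replicates draw the "observed" target set from the
matched pools as well, making it exchangeable with the null sets — the
condition under which the empirical p-value is uniform by construction.
A fixed target set with scores drawn iid is *not* exchangeable with
matched sets (matching induces correlated reuse of pool genes) and shows
mild inflation; that contrast is a property of the design, not a bug.

## Numerical choices

- All randomness flows through `numpy.random.default_rng`; composite
  procedures derive child seeds (< 2³¹) from a master generator, so one
  seed fixes everything.
- Pipeline outputs carry a `# config_hash=… seed=…` header (SHA-256 over
  the sorted JSON config) and format floats with `%.10g`, making reruns
  byte-identical.
- Tied ranks use average ranks; quantiles and percentiles use linear
  interpolation (numpy defaults).
- Cutoff comparisons in the outlier/consistency machinery are strict
  (a tie does not count as exceeding).

## Limitations

- The founder-mosaic model's EHH decay scale is set by the switch
  distance, not by a recombination map; absolute iHS magnitudes are not
  comparable to real-data scans.
- The GEA model treats individuals as independent given the PCs (see the
  calibration caveat above).
- Only biallelic SNPs are supported end to end; multi-allelic records
  are dropped at VCF load.
- The proportion test's literal-definition p-values are granular at
  1/R and can be exactly 0 or 1.
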