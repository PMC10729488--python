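# Methods

`noninvrna` implements the statistical evaluation pipeline used to judge
whether noninvasive biospecimens (buccal swabs, hair follicles, saliva,
urine cell pellets) yield transcriptomes good enough for regulatory and
disease-relevant analysis. The pipeline covers quality gating,
depth matching, normalization, reference-space projection, cis-eQTL
association and replication, disease-gene coverage scores, the
allele-specific-expression (ASE) contrast for nonsense-mediated decay
(NMD), and triage of reads that do not map to the host genome. Every
stage can be exercised end to end on synthetic data with known ground
truth; this note records the models, the defaults and why, and the
choices made where the design was genuinely open.

## Synthetic data model

The generator emulates the longitudinal study design the pipeline is
built for: 19 donors, 4 tissues, up to 4 collections per donor.

* **Counts.** Gene relative expression weights are log-normal
  (log-SD 1.5, heavy-tailed as in bulk RNA-seq). Per-gene donor effects
  (log-SD 0.3, shared across collections of the same donor — the
  assumed dependence structure between repeat collections) and tissue
  effects (log-SD 1.0) shift the log-mean. Per-sample library sizes are
  log-normal around `depth_mean` (default 5e6 reads) with CV 0.3.
  Expected counts are renormalized per sample to the library size and
  drawn negative-binomially with dispersion φ (default 0.1;
  variance = μ + φμ²; φ = 0 gives Poisson). Gene lengths are
  log-uniform on 300 bp – 30 kb so length normalization is non-trivial;
  biotypes are protein_coding / lncRNA / other so the coding-depth
  metric is non-trivial.
* **Genotypes.** Hardy–Weinberg dosages in {0,1,2}; realized MAF is
  recorded next to the target.
* **Planted cis effects.** For a causal pair the gene's latent mean in
  every sample of donor *d* is multiplied by `exp(β·dosage_d)` before
  the count redraw, i.e. effects are additive on the log scale, the
  same scale as the donor/tissue effects.
* **p-value sets.** Uniform/Beta(a,1) mixtures with known alternative
  fraction π1 (a = 0.1 by default), the standard test-bed for π0
  estimators.
* **ASE sites.** Site totals are Poisson(depth); reference counts are
  Binomial(total, 0.5) at synonymous sites and Binomial(total, r) at
  stop-gain sites, r ∈ [0.5, 1) the planted imbalance.
* **Species reads.** Multinomial reads proportional to
  (profile × genome length), so length normalization recovers the
  profile exactly in expectation. Replicate pairs share a profile;
  optional per-pair log-normal jitter supplies the between-sample
  variation against which replicate concordance is meaningful.

What the generator does **not** emulate: GC/length capture bias,
batch/prep chemistry effects, LD between variants (variants are drawn
independently unless constructed otherwise), mapping bias at ASE sites,
cell-type mixture shifts, and real microbial community structure.
Passing tests therefore demonstrate the statistics are implemented and
calibrated correctly, not that real noninvasive data will replicate at
any particular rate.

## QC and normalization

* Prep gate: concentration > 2 nM **and** mean library size < 600 bp;
  failures carry reason codes, missing fields are UNEVALUABLE rather
  than silently passed.
* Sequencing gate: coding depth (reads in protein-coding + lncRNA
  genes) ≥ threshold, with presets 1e6 (cross-preparation), 2.5e6
  (in-house-only analyses) and 5e6 (reference comparisons). The
  boundary is inclusive: the failing condition is "less than" the
  threshold, so a sample exactly at threshold passes. The biotype set
  behind "coding depth" is a parameter, so a strictly protein-coding
  variant is available.
* Expression filter: a gene is expressed in a tissue if raw count ≥ 8
  and TPM ≥ 0.1 jointly in ≥ 20% of samples (preset "gtex" lowers the
  count floor to 6). All bounds inclusive; the filter is monotone in
  each threshold.
* TPM: count/length rates scaled to 1e6 per sample; zero-depth samples
  give all-zero columns with a warning.
* TMM factors: weighted (inverse asymptotic variance) mean of doubly
  trimmed log-ratios against a reference column (the sample whose 75th
  percentile of depth-scaled counts is closest to the mean of those
  percentiles), trimming 30% of each M tail and 5% of each A tail,
  exponentiated and renormalized to geometric mean 1. M and A are
  computed on **raw count ratios**, so the factor absorbs the
  library-size component and normalized expression is simply
  count/factor; this makes the factors recover a planted 2× depth
  shift directly and leaves them exactly invariant to rescaling all
  samples by one constant.
* Inverse normal transform: Φ⁻¹((rank − 3/8)/(n + 1/4)) with average
  ranks on ties (Blom offset; no offset is canonical, Blom is the
  common choice). Constant vectors map to zeros with a warning.
* For PCA input a simple variance-flattening transform is provided:
  log2(count/size-factor + 1) with median-of-ratios size factors. The
  projection module accepts any pre-normalized matrix, so this choice
  is swappable.

## Downsampling

Counts are thinned binomially with p = target/original depth,
independently 5 times, and averaged; the average is unbiased for
p·count with 1/5 the single-thinning variance, and is kept fractional
(operations with raw-count thresholds compare fractional values
directly). One master seed spawns a substream per (sample, replicate)
keyed by the sample label, so subsetting samples never changes other
samples' draws. Samples below the target are an error — they belong on
the failing side of the depth gate. The per-gene Binomial(trials =
gene count) reading is used; it is the only reading with the stated
expectation.

## Reference-space PCA

The reference cohort alone defines the space: top-1000 most variable
features (ties lexicographic), centering and scaling by reference
statistics, SVD. Queries are standardized by the reference means/SDs
by default and multiplied by the loadings; standardizing the query by
its own statistics is available behind `scaling="self"` because the
source procedure's wording admits either reading — neither is claimed
as "the" original. Model features missing from a query are mean-imputed
(zero score contribution) up to a 20% cap, beyond which it is an error.
Splicing inclusion (PSI) matrices go through a pre-filter: events with
zero inclusion in any sample of a tissue are dropped; surviving events
must be flagged significant upstream and have a per-tissue median
inclusion more than 2 cross-event SDs away from the reference mean
inclusion 0.3. The SD in that rule is taken across events (SD of
per-event overall median PSI); the source wording does not pin down
the population and this reading is documented, not claimed.

## cis scan

Variant hygiene removes monomorphic records, MAF < 0.05 (strictly
below; 0.05 itself is kept), multiallelic sites and indels. LD pruning
is greedy within sliding windows of 50 variants advancing by 5: while
any kept pair has dosage r² > 0.2 the lower-MAF member is dropped
(tie: later position). Genotype PCs standardize dosages by
Hardy–Weinberg moments (mean 2f, SD √(2f(1−f))); expression PCs above
15% variance explained are selectable as covariates. Candidate pairs
lie within 1 Mb of the TSS (inclusive bound, signed distance, 1-based
positions). The nominal scan residualizes expression and dosage
against the covariates with an intercept and takes the slope and
two-sided t-test from the residual-on-residual regression with
n − 2 − k degrees of freedom (intercept and genotype each cost one
beyond the k covariates; with k = 0 this is exactly the textbook
simple-regression test). Monomorphic-in-sample variants get p = 1,
slope 0 and a flag. Permutation-based eGene discovery is out of scope;
the nominal scan exists to feed the replication statistic.

## Replication (π1) and the matched null

π0 is estimated as in the q-value package: π̂0(λ) = #{p > λ}/(m(1−λ))
on λ = 0.05, 0.10, …, 0.95, smoothed by a natural cubic smoothing
spline with 3 effective degrees of freedom and evaluated at λ = 0.95.
The smoothing-spline boundary weights were checked against base-R
`smooth.spline(df = 3)` and agree to three decimals. Sets with fewer
than 100 p-values use the fixed λ = 0.5 point estimate instead (the
spline is unstable on tiny sets). Reported π1 = 1 − π̂0 is clipped to
[0, 1]. q-values follow q_i = min over p_j ≥ p_i of π̂0·m·p_j/rank_j
(with π0 = 1 this is Benjamini–Hochberg).

Discovery pairs are the per-gene top pair (smallest p; ties by
|distance| then variant id) passing MAF ≥ 0.05, q ≤ 0.05 and
|slope| ≥ 0.32 — the effect floor is the smallest significant effect
in the weakest-powered reference tissue (kidney cortex). The observed
π1 is computed on the replication cohort's p-values for the
intersected pairs. The null re-draws B = 1000 equally sized pair sets
from the replication cohort, matched on MAF in 0.05-wide bins over
[0.05, 0.5], without replacement within a draw (each null set is a set
with exactly the target's bin histogram; with-replacement sampling is
available behind a flag). Bins that cannot supply their demand widen
to adjacent bins with a warning. The permutation p-value is the
add-one estimate (1 + #{null π1 ≥ observed π1})/(B + 1), which can
never be 0 and is exact for exchangeable draws. The comparison uses
the **raw, unclipped** π1 statistics: clipping first would put an atom
at 0 under the null and destroy the uniformity a calibrated
permutation p must have.

Known estimator property (verified in the benchmarks and relevant to
interpretation): with Beta(0.1, 1) alternatives the smoothed π0
estimator underestimates π1 by ≈ 0.05 at π1 = 0.5 — the alternatives'
upper tail leaks into the λ grid — and the statistic's sampling SD on
a 200-pair set is ≈ 0.15. The permutation test is exactly calibrated
under the null regardless; the noise bounds its power at a few hundred
pairs (the `replication_power` benchmark measures ≈ 0.85 at 100
planted pairs of effect 1.0 among 200).

## Disease scores

Evidence rows need ≥ 5 sources (the stricter "> 5" variant is a flag;
the two readings coexist in the source material). Tissue gene sets are
the top 3,411 most-expressed tissue-elevated genes with median
TPM > 0; boundary ties are broken lexicographically and logged since
the 3,411 truncation is cohort-derived. The summed evidence score for
a disease is SES = Σ(scores of disease genes in the tissue set) /
Σ(scores of disease genes in the union of all analyzed tissue sets),
in [0, 1], undefined (NaN, never a division error) when the
denominator is 0. OMIM capture is the fraction of annotated OMIM genes
with median TPM strictly > 0.1; the upset decomposition counts every
captured gene in exactly one exclusive region.

## ASE / NMD contrast

Sites with fewer than 16 total counts are removed (a site at exactly
16 is kept — the figure-legend variant "> 16" is a flag). The
reference ratio is ref/(ref+alt). Donor outliers ("extreme ratios",
removed by inspection in the source study) are operationalized as a
robust rule: a donor whose mean ratio deviates from the cross-donor
median by more than 3 robust SDs (1.4826·MAD) is flagged; zero MAD or
fewer than 3 donors flags nothing, with a warning. The contrast
statistic is the allelic-imbalance magnitude |ratio − 0.5| compared
between stop-gain and synonymous sites by a two-sided Mann–Whitney
test — magnitude rather than raw ratio because NMD depletes whichever
allele carries the premature stop, so the direction depends on phase.
Stratification by tissue and collection is supported.

## Unmapped-read triage

Reads partition into mapped > remapped > repeated > unknown, in that
precedence, so the ledger is disjoint and exhaustive by construction;
claimed overlaps are tallied. Species abundance divides read counts by
genome length and renormalizes per sample (columns sum to 1). The top
0.5% of species are selected by mean abundance across all samples
(ceil on the species count; a per-species "max" statistic is a flag) —
the species-count reading of the ambiguous "top 0.5%" is implemented.
Replicate concordance is per-species Spearman across replicate pairs
(NaN when undefined). Per-tissue highlighting requires median
abundance strictly > 0.05. Read-to-species assignment and
repeated-sequence discovery are inputs, not computed.

## Orchestration and reproducibility

The `run` pipeline executes simulate → QC → downsample → normalize →
cis scan → replication → ASE → triage from one declarative config,
writing every intermediate as TSV/JSON plus a manifest with the config
snapshot, per-stage seeds, runtimes and SHA-256 digests. Floats are
rounded to 10 decimals on write so digests are stable; re-running with
the same config and seed reproduces identical digests. All randomness
flows from `numpy.random.Generator` substreams keyed by (seed, stage,
label), so subsetting inputs never perturbs unrelated draws. The
bundled demo config finishes in well under a minute on one CPU.

## Benchmark problem sizes

The benchmark experiments (`noninvrna.benchmarks`, also run by
`scripts/acceptance.py`) use: π1 recovery at m = 5,000 over 100 seeds
for π1 ∈ {0, 0.1, 0.3, 0.5}; permutation calibration with 200-pair
discovery sets from a 2,000-pair null pool, B = 200, 200 seeds;
replication power with 200 discovery pairs (100 causal, effect 1.0 at
MAF 0.3, 19 donors) over a 2,200-pair pool, B = 200, 100 seeds; a
2,000-gene downsampling toy with 200 Monte-Carlo replicates; a
5,000-pair null scan at 19 donors; 500 null and 100 powered ASE
contrasts at 100 sites/group and depth 50; and 1,000 randomized read
ledgers. These sizes keep each experiment between a second and about
a minute while leaving Monte-Carlo error well below the asserted
margins.

## Known limitations

* The π1 smoother's small negative bias for very spiky alternative
  distributions is inherent to the λ-grid construction (see above);
  results on sets of a few hundred pairs carry ≈ ±0.15 sampling noise.
* The nominal scan is single-variant OLS; it does not reproduce a
  full permutation-based eGene pipeline and is intended for
  replication input, not discovery.
* LD pruning uses the greedy windowed heuristic, which is
  order-dependent in the same way the standard tools are.
* The synthetic generator's independence assumptions (above) mean
  calibration results transfer to real data only to the extent those
  assumptions hold.
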