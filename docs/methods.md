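# Methods

`domestica` reproduces, on synthetic data with known ground truth, the
statistical workflow used to diagnose a domestication bottleneck from a
wild/domesticated ("crop") panel of a selfing plant: per-gene
coding-sequence diversity, differential expression and expression-diversity
loss, selection-signature classification with a diversity-matched
resampling null, and signed co-expression modules. This note records the
models, the defaults and why they are what they are, the numerical
decisions, and what the tests do and do not establish.

## The synthetic world

The generator (`domestica.simulate`) is a stated world, not a dial. Its
defaults are the design of the study being emulated: 9 wild and 11
domesticated accessions, wild per-site diversity θ = 1.6×10⁻³, a bottleneck
retaining 65% of wild diversity, inbreeding F = 0.42 (wild) and 0.99
(crop), planted πN/πS = 0.16, 5% DE genes with |log2FC| = 2 of which 82%
are down-regulated in the crop, mean expression CV 0.75 (wild) with the
crop keeping 84% of it, 10% swept genes, and three planted co-expression
modules of 50 genes. Library sizes are 0.5–2 M reads — scaled down from
the study's ≥12 M to keep desk-scale runtimes; every CPM-based threshold
is library-size-independent, so this changes power, not logic.

### Genotypes: an SFS sampler, not a coalescent

Per gene, an ancestral stop-free coding sequence receives independent
segregating sites. The number of sites is Binomial(L, θ·a₁), where a₁ is
the Watterson constant for 2N_wild haplotypes; the derived-allele count i
is drawn with probability ∝ 1/i. Under this spectrum the pairwise and
Watterson estimators of θ have equal expectation, so Tajima's D is centred
on zero by construction — verified by simulation (mean D = −0.02 at f = 0).
No genealogy is simulated: the analysis only consumes marginal
diversity/SFS structure, and the sampler is dependency-free and fast.
Genes are the linkage unit; there is no recombination or inter-gene LD.

Mutation placement is weighted per (position, alternative base): weight 1
for synonymous changes, `nonsyn_syn_ratio` (default 0.16) for
nonsynonymous, 0 for stop-creating changes. The realized NG86 πN/πS then
equals the parameter, and the ledger records the exact planted synonymous
and nonsynonymous heterozygosity of every gene as an oracle.

Selfing is modelled as probability-f duplication of one haplotype within
each accession, which gives E[1 − Hobs/Hexp] ≈ f by construction. Two side
effects are real and documented rather than removed: duplication removes
singletons faster than it removes π, biasing Tajima's D upward by ≈ +0.15
at f = 0.42; and it shrinks the observed π slightly (factor 1 − f/(2N−1)).

The bottleneck resamples crop lineages with replacement from the wild
lineage sample and then fixes each site independently with probability
1 − s, with survival s calibrated so the observed mean per-gene
π_crop/π_wild equals `bottleneck_ratio`. The calibration has an analytic
part (finite-sample resampling and selfing factors) and one empirical
constant (1.043, the Jensen inflation of a mean of ratios whose
denominators are noisy), measured once on 20k genes with ≈0.5% precision.
Recovery is tested at ratios 0.4/0.65/0.9 within ±0.05.

Swept genes (probability `prop_swept`) fix the crop at the wild haplotype
carrying a randomly chosen derived variant. This both forces π_crop = 0
and makes swept genes genuinely differentiated (they dominate the F_ST
tail), which is what lets selection-targeted expression signals be
detectable at F_ST percentiles at all. Missing genotype calls (both
haplotypes masked, default 10%) emulate coverage-based call filtering.

### Counts: NB with a lognormal noise budget

Counts are NB(mean = lib_i · q_g · 2^(±lfc/2) · noise, dispersion φ = 0.05)
with gene abundances q_g lognormal (σ = 1.2). The distributional form is a
stand-in — the study states none — and is configurable. Per-gene expression
variability is a lognormal accession-level factor whose variance is solved
so the sample CV hits its target; the crop pool's target is shrunk by
`cv_shrink_crop` (and additionally by `swept_cv_shrink` = 0.7 at swept
genes, emulating the ≥25% CV loss the workflow is designed to detect).
Because the sample CV of 9–11 skewed observations attenuates the population
CV, the population targets carry two empirically calibrated inflation
constants (1.20 on the CV level, 0.92 on the shrink) so the *observed*
mean CVs land on 0.75/0.63 and the observed ratio on 0.84.

Planted modules are a correlation split of that same noise budget: module
genes share a fraction `module_cor` (0.85) of their latent noise variance
with an accession-level factor. This yields within-module expression
correlation ≈ 0.7 after count-noise dilution — the regime where
co-expression modules are unambiguous — without inflating any gene's CV
beyond its target (an earlier additive-factor design did, and broke the
CV calibration; the correlation split is why it cannot).

What the generator does *not* emulate: read mapping and genotype calling
(missingness is the only trace), paralogy, recombination, multi-tissue
composition (one pooled profile per accession), any coupling between
polymorphism and expression level (the log-log regression slopes of real
data are absent here, so those operations are validated on planted lines
and null uniformity instead), and negative Tajima's D in the crop (our
bottleneck loses singletons, which pushes crop D positive; the real study
reports slightly negative values genome-wide).

## Estimators

* **π** — unbiased average pairwise difference per site,
  (1 − Σp²)·n/(n−1) with per-site sample sizes under missingness; equals
  the brute-force all-pairs average exactly (tested on random alignments).
* **πS, πN** — Nei–Gojobori (1986) with the mutation-fraction site
  convention (mutations to stops count as nonsynonymous, so syn + nonsyn
  sites sum to exactly 3 per codon); pairwise differences accumulate as a
  ratio of sums over haplotype pairs; multi-hit codons average over
  mutational pathways, excluding pathways through stops (falling back to
  all pathways if none is clean); codons with missing data or stops are
  skipped per pair. πN/πS is undefined when πS = 0.
* **Tajima's D** — Tajima (1989) constants from n; with missing data, n is
  the median per-site called-haplotype count and the pairwise-difference
  total sums the per-site unbiased values over callable sites. Undefined
  when S = 0.
* **F** — 1 − ΣHobs/ΣHexp over polymorphic sites (Nei's small-sample
  correction on Hexp), aggregated across genes as a ratio of sums;
  percentile bootstrap over genes for the CI.
* **F_ST** — Hudson (1992) as a ratio of sums over sites:
  1 − Σ(Hw)/Σ(Hb) with Hw the average of the two unbiased within-pool
  heterozygosities and Hb = 1 − Σ p₁ₐp₂ₐ. Chosen over Nei-style estimators
  for robustness at 9–11 samples. Negative estimates are kept; the
  regulatory-only candidate scan treats F_ST ≤ 0 as "no differentiation".
  Note the estimator's small-sample point mass at −1/(n−1) for identical
  pools; it vanishes asymptotically.
* **Site filter** — positions called in <5 individuals in either pool are
  removed, and any codon losing a position is dropped entirely so frames
  never shift.
* **Diversity ratio classes** — r = π_crop/π_wild: sweep_candidate (r = 0,
  wild polymorphic), reduced (0 < r < 0.65), baseline (0.65 ≤ r ≤ 1),
  elevated (r > 1), undefined (π_wild = 0). The total-π ratio is the
  default; πS- and πN-based ratios are also emitted.

## Expression

Genes are kept if CPM ≥ 1 in ≥ 5 accessions — the permissive reading of
the ambiguous "at least one CPM in each accession" filter (the strict
reading would discard nearly everything); both thresholds are arguments.
TMM normalization follows Robinson & Oshlack (2010): 75th-percentile
reference choice, M/A double trimming (30%/5%), inverse-asymptotic-variance
weights, geometric-mean-1 rescaling; it is checked against an independent
step-by-step implementation.

The exact test is the classic two-group NB conditional test: counts are
quantile-adjusted to the common effective library size by normal moment
matching (the simpler branch of the usual normal+gamma blend), a *common*
dispersion is estimated by conditional maximum likelihood
(Dirichlet-multinomial form), and the two-sided p sums all conditional
outcomes (beta-binomial over the group split) with probability ≤ the
observed one. No tagwise/empirical-Bayes shrinkage is attempted: with ~20
replicates the common-dispersion test already holds its type-I error
(0.05 ± 0.01 at a 5000-gene null; p-values uniform, KS < 0.02), which is
the property the downstream inference needs. Gene-list identity with any
particular external implementation is explicitly not a goal. logFC is
log2(wild/crop) with a 0.5 prior count: positive = down-regulated in the
crop. φ̂ ≈ 0 falls back to the exact binomial split. BH correction is the
standard step-up.

CV is the sample sd/mean of TMM-normalized CPM within a pool, undefined
for zero-mean genes. PCAs (genotype dosage with mean imputation; expression
log2(CPM+1)) are centered, with a deterministic sign convention
(largest-|loading| element positive).

## The matched-resampling CV-loss test

Outliers are genes at or above an F_ST percentile (90/95/99; a lower-tail
mode serves π-ratio candidates). For each of 1000 resamples, every outlier
is matched by one non-outlier drawn uniformly among those with π ≤ the
outlier's π (wild-pool total π by default — the matching variable is
configurable since the source is ambiguous). This is per-outlier matching,
the stricter reading of "equal or lower diversity"; an outlier with no
eligible donor relaxes to the nearest-π donor with a warning. The
empirical p is (1 + #{null ΔCV ≥ observed})/(n + 1), never zero,
bit-reproducible under a fixed seed. Fisher tests are two-sided by the
point-probability method (verified against full hypergeometric enumeration
for small margins); sample odds ratios use a Haldane 0.5 correction only
when a cell is zero.

## Network

Signed similarity (1+cor)/2 of log2(CPM+1) profiles, soft power β = 20 by
default (the scale-free scan — ≥10 connectivity bins, signed R², smallest
power with R² ≥ 0.8 — is available but the emulated analysis fixed 20),
standard TOM on the signed adjacency, average-linkage clustering of
1 − TOM.

The tree cut is deliberately simpler than the dynamic hybrid algorithm:

1. static cut at the 0.90 quantile of merge heights;
2. recursive splitting of each cluster at its top merge when the merge
   height steps up by more than 0.05 over the taller child subtree, *or*
   when the tighter half is ≥1.3× more cohesive (mean intra-cluster TOM)
   than the parent — this second rule separates distinct modules glued
   together by interleaved background genes; top merges that only peel a
   sub-minimum satellite are descended through;
3. a cohesion gate: a cluster becomes a module only if its mean
   intra-cluster TOM exceeds 2× the network-wide mean TOM (the bulk of
   unconnected genes sits at background and is sent to label 0);
4. eigengene merging: modules whose eigengenes (first PC of standardized
   module expression, sign-oriented to the module mean) correlate above
   1 − merge_height (default 0.25) are merged iteratively, closest first —
   this also undoes over-splitting from rule 2.

The path is deterministic (no RNG). Acceptance is planted-module recovery
(ARI > 0.8 over planted genes at the default world; measured 0.87–0.98
across seeds), not label identity with any external package. Module
enrichment is Fisher per module with BH across modules, plus a crop
up/down direction from mean log-expression; the accession report flags
|z| > 2.5 eigengene scores within a pool.

## Determinism and tolerances

All randomness flows from one seeded `numpy` Generator; pipeline runs with
the same seed are byte-identical (tested). The resolved configuration and
package version are written next to every run's results. Exact oracles are
held to 1e-10–1e-12; stochastic recovery bands (±0.05 on the diversity
ratio, ±0.1 on F, ±0.04 on the down-fraction, 0.05 ± 0.01 on type-I error)
are the pre-stated acceptance bands, evaluated at fixed seeds. Degenerate
inputs (empty genes after filtering, zero-mean genes, S = 0, πS = 0,
margins of zero) yield flagged nan/undefined values, never exceptions, and
are excluded from summaries.

A green suite establishes that the estimators are exact on their oracles
and that the inference machinery is calibrated and powerful *within this
stated world*; it does not establish anything about read processing,
genotype calling, or the biological correctness of the emulated study's
conclusions on real data.
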