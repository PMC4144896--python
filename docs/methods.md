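# Methods

This note records the models, parameter choices and numerical
conventions behind `chiptarget`, and what the synthetic-data tests do
and do not demonstrate about real data.

## The inference problem

A transcription factor (TF) of the TGA-type bZIP family binds a 6-bp
recognition word (TGACGT) preferentially close to transcription start
sites. Direct target genes are defined operationally as genes that are
(i) bound — a reproducible ChIP-seq binding region lies within the
400-bp window immediately upstream of the TSS in at least one condition
— and (ii) responsive — differentially expressed when the TF is
overexpressed. The pipeline computes both halves and intersects them.

## Binding-region model

Reads are reduced to their 5′ start positions and counted in
non-overlapping 100-bp tiles (`window_size`). Three criteria, each an
FDR over its own family of tests, must hold:

1. **Peak criterion** (BH-FDR < 0.001). Under a uniform-background
   null, a window's ChIP count is Binomial(N_chip, w/L). The one-sided
   upper tail is computed exactly with the scipy binomial survival
   function. This null ignores chromatin accessibility structure; on
   real data the input-enrichment criterion carries that burden.
2. **Input-enrichment criterion** (BH-FDR < 0.05). Conditional on the
   window total k + m, the ChIP count is Binomial(k + m, p) with
   p = N_chip/(N_chip + N_input) under the no-enrichment null — the
   standard exact two-sample binomial split. One pseudocount is added
   to the input count so windows with zero input coverage cannot reach
   arbitrarily small p-values. Library-size imbalance is handled
   through p, never by scaling counts.
3. **Strand-separation criterion** (BH-FDR < 0.05 over merged
   regions). A genuine protein-DNA contact produces plus-strand reads
   piling upstream and minus-strand reads downstream of the site. The
   statistic is mean(minus 5′) − mean(plus 5′); significance is the
   add-one permutation p-value over shuffled strand labels (default
   1,000 permutations, seeded). The test is one-sided: regions with the
   inverted orientation are rejected regardless of magnitude. A region
   with either strand absent gets p = 1 by convention.

Significant windows are merged when adjacent (`merge_gap` = 0 tiles by
default; an override exists because no canonical merge rule is
established). Replicate reproducibility is enforced by interval
intersection: the reported regions are the pieces of replicate-1
regions covered by replicate-2 regions, which makes the reported base
coverage symmetric in the replicate order even though the attached
statistics come from replicate 1.

Benjamini–Hochberg is implemented directly (step-up,
q_(i) = min_{j≥i} p_(j)·n/j, capped at 1) and property-tested against a
brute-force evaluation.

## Annotation model

Coordinates are 0-based half-open everywhere in memory; BED shares this
on disk and GFF3 is converted at the I/O boundary. Each gene has one
transcript; the TSS and TTS are its 5′ and 3′ ends in reading
direction. A region's compartment is decided by its midpoint with fixed
precedence upstream > gene body > downstream > intergenic (the printed
compartment tables are exhaustive and mutually exclusive, so a
precedence must exist; upstream-first reflects the promoter-centric
question). Within a compartment, the gene minimising |distance to its
anchor| wins; ties break lexicographically for determinism.

Candidate targets use interval overlap (≥ 1 bp) between the region and
the 400-bp upstream window — the inclusive reading of "possessing a
region within 400 bp" — while distance profiles use the midpoint, which
needs a single point. The positional test is per-bin
Binomial(n, 1/n_bins) with Bonferroni at family level
`positional_alpha` = 0.01 over the 40 bins spanning ±2 kbp.

## Motif analysis

Word scanning is exhaustive on both strands with overlapping matches
reported and palindromes counted once per strand; hits are attributed
to regions by their start position (a fixed convention; for 6-bp words
the alternative midpoint rule differs only at region edges). Fold
enrichment divides the hit rate inside merged regions by the rate in
the rest of the genome, matching the published phrasing of the
comparison; a shuffled-region null is not the default.

The Gibbs sampler is the classic one-site-per-sequence site sampler:
random initial sites, leave-one-out resampling proportional to the
pseudocounted matrix/background likelihood ratio over all offsets and
both strands, plus a per-sweep phase-shift move (slide all sites by ±1
or ±2 when that raises information content) — the standard refinement
against off-frame local optima. The highest-information-content state
visited is returned, and the result is deterministic under a fixed
seed. Because both strands are sampled, the motif is identified only up
to reverse complement; recovery tests accept either orientation. ZOOPS
(zero-or-one site) models are out of scope. With width 1 the sampler
degenerates honestly: the positive feedback of the site model
concentrates the single column on one base rather than reproducing the
background composition.

## Differential expression

The design is genotype (WT, OX) × time (0, 6, 24 h) × replicate
(4 by default; ≥ 2 per cell required). The genotype main effect is
tested per gene with a two-factor fixed-effects ANOVA; for balanced
designs the sums of squares are computed in closed form across all
genes at once (verified against statsmodels `anova_lm` in the tests),
and unbalanced designs fall back to per-gene OLS. BH-FDR is applied
across genes. Calls combine q ≤ `de_q` with an inclusive two-fold
threshold at ≥ 1 time point; when a gene crosses the threshold in both
directions at different times, the direction of larger magnitude wins
(such genes do not arise in the synthetic designs).

Clustering uses 1 − cosine similarity with average linkage (scipy
UPGMA, cross-checked against a naive cubic-time implementation).
All-zero profiles receive unit pseudo-norm so the distance stays
defined. Group counts (2 for up-targets, 3 for down-targets) are user
parameters; no automatic cut-height selection is attempted.

Report percentages round half-up (`decimal.ROUND_HALF_UP`) — the
convention that reproduces printed report tables exactly — and the
up/down target percentages are quoted against the per-condition
binding-region counts, the convention of the source tables, alongside a
clearly-labelled ratio against the DE gene counts.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions under which the pipeline's guarantees are asserted.

* **Genome**: 1 Mbp over 2 chromosomes of i.i.d. uniform bases; 120
  non-overlapping genes (length ~ N(2000, 500²) bp, clipped at 200,
  ≥ 1 kbp apart, both strands). 120 genes leave a large intergenic
  fraction; materially denser gene packing would leave no legal
  intergenic site placements once 2-kbp flanks are excluded.
* **Sites**: 20 anchors; 50% within 400 bp upstream of distinct TSSs,
  40% intergenic (outside every gene ± 2 kbp), the rest in gene bodies.
  Each site carries two copies of TGACGT (10-bp spacer) written onto
  the forward strand. 70% of sites are active in both conditions, the
  remainder in exactly one — emulating the observed ~70% overlap of
  binding regions between conditions.
* **ChIP reads**: fragments are 350 bp sequenced as one 100-bp read
  (the peak statistics need only 5′ starts and strands, so single-end
  suffices even for a paired-end protocol). A fragment is site-derived
  with probability n_active·F·(E−1)/(L + n_active·F·(E−1)), which makes
  coverage over a site footprint ≈ E-fold background (E = 20 by
  default; E = 1 is exactly uniform). Site fragments centre on the
  anchor with uniform jitter up to F/2 — the fragment-site geometry is
  a modelling choice, as no canonical model exists. Each fragment
  yields a plus-strand read at its start or a minus-strand read at its
  end with probability 1/2, producing the strand offset the third
  criterion detects. Input libraries are uniform with Bernoulli(1/2)
  strands. Mappability is uniform: no repeats, gaps, sequencing errors,
  PCR duplicates or GC bias.
* **Expression**: log2 intensities = gene baseline N(8, 1) + a shared
  per-gene time trajectory + the planted genotype effect
  (±log2(4) on ground-truth DE genes in OX samples) + N(0, 0.1) noise.
  All bound genes are planted responsive (75% up / 25% down) plus five
  unbound decoy DE genes, so the binding × expression intersection is
  exercised non-trivially.

Every operation is a pure function of (params, seed, condition,
replicate); read counts are conserved exactly and all reads stay within
chromosome bounds.

**What passing tests show — and don't.** Ground-truth recovery, FDR
control and calibration hold under this generator's idealisations:
uniform background, exact word planting, balanced designs, Gaussian
noise. Real ChIP-seq adds accessibility-correlated background,
mappability artefacts, and copy-number structure that only the input
control partially absorbs; real microarrays add probe effects and
normalisation residue. Results on real data therefore inherit the usual
caveats even though the inferential machinery is identical.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study conditions
(1-Mbp genome, 200k + 200k reads per replicate and condition); null
calibration suites use 20 seeds at 100k reads, 2,000 permutation-test
regions at 400 permutations, and 10 sampler seeds at 50 × 200-bp
sequences — sizes at which the asserted properties are statistically
sharp while the whole suite completes in well under a minute per suite.
Permutation p-values use the add-one estimator (never exactly zero);
binomial tails come from scipy's survival functions; BH never exceeds
1; percentage arithmetic goes through `decimal` to make half-up
rounding exact. Degenerate inputs (empty read sets, single-strand
regions, all-zero profiles, empty gene lists) take defined conventions
rather than raising, except where the input is unusable (zero-length
genome, unbalanced cells below two replicates, words outside A/C/G/T).

## Known limitations

* Tiles are non-overlapping; sliding windows would localise peaks
  slightly better at the cost of dependent tests.
* The strand-separation statistic uses means, which are sensitive to
  outlier reads in very wide regions.
* One transcript per gene; alternative TSSs are not modelled.
* The Gibbs sampler assumes exactly one site per sequence; sequences
  without a true site dilute the matrix rather than being excluded.
* Functional categories come from a user-supplied map; no annotation
  database lookup is attempted.
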