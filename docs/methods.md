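# Methods

This note documents the models, algorithms and numerical choices behind each
module, the parameters that matter, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Data model and conventions

The universal currency is the expression matrix: features × samples,
non-negative finite values, unique string identifiers on both axes, and a
processing-state flag (`raw` → `denoised` → `normalised`) so downstream
stages can warn when fed unexpected input. Sample order in the matrix is
canonical; metadata tables are reordered to match it, never the reverse.
Genomic coordinates are BED-convention throughout: 0-based, half-open
`[start, end)`. Gene identifiers are opaque strings — no identifier
conversion is attempted, and duplicate identifiers are rejected outright
(strict mode) rather than merged or suffixed, because silent merging changes
count totals and suffixing silently forks identities.

Matrices are written with `%.17g` formatting and read back with
correctly-rounded float parsing, so write∘read is the identity on doubles.

## Noise thresholding

Low-abundance counts are dominated by technical noise: across replicates the
correlation of counts collapses as abundance falls. The counts-based scan
sorts features by mean abundance (ties broken by feature id), slides a
window of `window_size` features with stride `step`, and records per window
the mean Pearson correlation over all sample pairs of the two samples'
values within the window (a zero-variance vector contributes correlation 0
to its pairs). The noise threshold is the mean abundance of the first window
from which the correlation reaches `similarity_threshold` *and stays there
in every later window*; if no suffix of windows qualifies, the threshold is
+inf and removal refuses to run, directing the user to the per-window
statistics and a manual threshold.

Defaults: `window_size=100`, `step=10`, `similarity_threshold=0.25`
(Pearson). The window must span a wide abundance band relative to the
biological coefficient of variation for the signal plateau to clear the
similarity threshold; on desk-scale simulated matrices (~2 000 features) a
window of ~25 % of the features behaves like the default does on genome-scale
data, and the examples and tests size windows accordingly.

Removal offers two modes: `drop` (default) removes features whose mean
abundance is below the threshold; `floor` raises sub-threshold values to the
threshold and then drops features left constant, preserving features whose
high-count samples carry signal.

## Normalisation

Five methods, all operating on the matrix as passed in (post-denoising, so
e.g. RPM totals are denoised library sizes — documented rather than hidden):

* **rpm** — value × 10⁶ / column total.
* **median** — value ÷ column median; a zero median is an error advising
  denoising first.
* **quantile** — every column is mapped onto the across-column mean order
  statistics; ties receive the mean of the tied ranks' reference values
  (implemented as linear interpolation of average ranks into the reference
  vector, which is exact for tied pairs and deterministic). After quantile
  normalisation the sorted value vector of every tie-free column is
  identical to machine precision.
* **median-of-ratios** — per-feature geometric-mean reference over features
  positive in every sample; the size factor is the per-sample median of
  value/reference; values are divided by the factor. Factors are *not*
  rescaled, so a column exactly double another yields factors
  (2^−½, 2^+½).
* **tmm** — reference sample: the column whose 75th percentile of positive
  values is closest to the mean such percentile. Per sample, M and A values
  against the reference over features positive in both; double trim keeping
  average-rank windows (30 % by M, 5 % by A, both configurable); scaling
  factor 2^(weighted mean of surviving M) with inverse asymptotic binomial
  variance weights (N−x)/(Nx) summed over the two samples; log factors are
  centred so the factors multiply to 1; normalised value = value ÷
  (library size × factor). A weighted mean below 1e−10 in magnitude is
  snapped to 0 to avoid a spurious factor from pure rounding noise.

## Differential expression

A single, fully specified two-group negative-binomial exact-test pipeline
(the classic count-based recipe), rather than a wrapper over external
tools; contrasting two DE runs (e.g. under different normalisations) is
supported by `compare_de`, which inner-joins two results and classifies
features as both/only_1/only_2/neither.

1. **Pseudo-equalisation.** Columns are scaled to the geometric-mean library
   size. This linear scaling is a documented approximation of
   quantile-to-quantile count adjustment; at the desk scale the two agree to
   well within the test's discreteness.
2. **Dispersion.** With equal library sizes the likelihood of a group's
   counts conditional on their total is free of the group mean:
   Σᵢ lnΓ(yᵢ+r) − n lnΓ(r) − lnΓ(z+nr) + lnΓ(nr), r = 1/φ. The common
   dispersion maximises this pooled over features (bounded scalar
   optimisation of log φ on [1e−6, 20]). Tagwise dispersions maximise the
   per-feature conditional likelihood plus `prior_weight` (default 10,
   in units of equivalent features) times the average curve — a
   weighted-likelihood empirical-Bayes shrinkage — evaluated on a 25-point
   grid spanning common × 2^[−8, 8] with parabolic refinement of interior
   maxima. `fixed_dispersion` bypasses estimation and is the only mode that
   permits single-replicate groups (e.g. the Poisson limit).
3. **Exact test.** Group totals are rounded to integers *per group* (this
   keeps the test exactly symmetric under swapping the two levels; rounding
   the grand total instead can break symmetry by one count). Conditional on
   the grand total s, the group-A total follows a negative hypergeometric
   law with shapes (n_A r, n_B r); for φ < 1e−8 the Poisson-limit binomial
   with p = n_A/(n_A+n_B) is used. The two-sided p doubles the smaller of
   the two inclusive tails, capped at 1. A feature with zero counts in both
   groups gets p = 1 and log2FC = 0.
4. **Fold change and flags.** log2FC = log₂((mean_B+c)/(mean_A+c)) with
   pseudo-count c = 0.5 on the pseudo-equalised per-sample mean scale.
   Benjamini–Hochberg adjustment within the comparison; a feature is flagged
   DE iff padj < α (default 0.05) and |log2FC| ≥ the fold cut (default 1).
   Both thresholds are user-adjustable at the API and CLI.

On a seeded null simulation (2 000 features, 3 vs 3, φ = 0.1) the empirical
type-I error at p < 0.05 is computed by the acceptance script and sits near
the nominal level; with a 4-fold shift planted in 10 % of features the same
script reports sensitivity and empirical FDR at padj < 0.05.

Volcano tables clamp padj = 0 to the smallest positive double before taking
−log₁₀ and map padj ≥ 1 to exactly 0. MA tables plot log₂(mean + 0.5) so
the abundance axis uses the same pseudo-count as the fold change.

## QC

* **Jaccard similarity** between per-sample sets of the
  ⌈`top_fraction`·n⌉ most-expressed features (default 0.25; ties broken by
  feature id ascending). The definition of "the expressed set" is not
  canonical, so an absolute `min_value` cut is offered as an alternative.
* **PCA** by SVD of the feature-centred (optionally unit-scaled,
  zero-variance features dropped and logged) samples × features matrix.
  Deterministic sign convention: each loading vector is oriented so its
  largest-magnitude entry is positive. Variance fractions are relative to
  total variance, hence sum ≤ 1 when components are truncated.
* **Z-scores** use the population (÷n) standard deviation; constant rows
  map to zero rows rather than NaN.

## Patterns

Per feature, condition means across the user-ordered levels; each
consecutive transition is labelled U if log₂((μ_{k+1}+c)/(μ_k+c)) exceeds
the threshold t (default 0.5, log₂ units), D below −t, else S; c = 1
guards zero-mean conditions. Reversing the condition order provably reverses
each string and swaps U↔D. Scaling the whole matrix by a constant leaves
patterns unchanged up to pseudo-count effects, which are O(c/μ) and
negligible for values ≫ c. A noise-threshold-based S-call (rather than a
fold threshold) would be a plausible alternative; the threshold parameter is
exposed so users can emulate either regime.

## Enrichment

Offline over-representation analysis: the query (typically the DE list) is
tested per GMT term with the upper-tail hypergeometric probability of the
observed-or-greater overlap, drawing |query| from |background| with the
background-restricted term size as successes. The background is by
convention all features surviving noise removal ("expressed"). Query genes
outside the background are dropped with a warning; terms empty after
restriction are skipped. Benjamini–Hochberg is used across tested terms — a
deliberate, documented divergence from service-specific corrections, chosen
for transparency and offline reproducibility. Ranked (running-sum) GSEA is
out of scope.

## Network inference

Per target, a random-forest regression (scikit-learn) predicts the target's
expression — standardised to zero mean, unit population variance — from all
candidate regulators except itself: fully grown trees,
⌈√p⌉ candidate features per split, `n_trees` default 1000 (tests and the
acceptance script use 200, which is past the importance-stabilisation point
at these problem sizes). The weight of regulator→target is the regulator's
variance-reduction importance summed over trees and divided by `n_trees`
(unnormalised per tree, so weights are comparable across targets through the
unit-variance standardisation). The per-target RNG seed hashes (seed,
target, sorted regulator ids), making results independent of regulator input
order and fully reproducible.

Neighbourhood extraction starts from the focus set and per hop keeps each
frontier node's `top_n` heaviest incident edges in *either* direction (which
direction "Top N connections" should count is ambiguous; both are used, and
ties break lexicographically on (regulator, target)), advancing at most
`max_hops` ∈ [1, 3] hops — the three-hop cap is a robustness guard, as
tree-ensemble weights beyond three hops are dominated by noise. Comparison
of 2–4 networks uses edge identity (regulator, target) only — weights are
ignored and annotation edges excluded — producing exclusive subset counts
(UpSet semantics) and a shared-edge list for highlighting. More than four
simultaneous inferences are rejected.

## Multi-omics integration

* **cis**: a non-focal element attaches to a focal node iff its interval
  intersects the focal interval extended by `window_bp` (default 1000) on
  the requested side(s); upstream/downstream are resolved by the focal
  strand (unknown → "+", logged). Attachment uses interval-extension
  intersection, not midpoint distance. The recorded relation
  (upstream/downstream/overlapping, with bp gap) refers to the gene body; a
  `tss_mode` flag collapses the focal interval to its strand-aware 5′ base
  before extension, for TSS-centred windows. Attached elements become
  unweighted annotation nodes/edges labelled by relation, so renderers can
  colour upstream and downstream links differently.
* **trans**: two matrices over identical sample sets (order harmonised to
  the first) are row-concatenated; colliding feature ids are suffixed with
  their modality tag; per-feature modality labels ride along so network
  nodes can be coloured by source. No re-normalisation or batch correction
  is applied at this step: the tree-ensemble standardises each feature,
  which absorbs between-modality scale differences.
* **custom**: rows of an external (regulator, target, source) table whose
  target exists in the network add the regulator as an annotation node with
  an unweighted edge; duplicates collapse, absent targets are counted and
  skipped; the operation is idempotent.

Annotation edges never enter network comparison — comparison is defined on
inferred co-expression edges only.

## Peaks

Two peaks match when the midpoint of one (floor of the mean coordinate,
half-open membership) lies within the other's range. The matching sentence
is direction-ambiguous in common usage, so the symmetric either-direction
rule is the default, with a strict both-direction mode behind a flag. Note
the half-open consequence: peaks can overlap without matching when both
midpoints fall outside the other's range. Cross-sample aggregation takes
connected components of the match relation (union-find with a coordinate
sweep; midpoint containment implies overlap, so only overlapping candidates
are tested), and each component's unified interval spans min(start) to
max(end) of its members. Amplitude over a unified interval is the summed
per-base bedGraph coverage divided by the read length — i.e. an estimated
read count (sum, not mean, so longer peaks with equal coverage score
higher); a mean-coverage alternative can be had by dividing by interval
length externally. The resulting matrix carries the `ChIP` modality tag and
enters the pipeline like any other expression matrix.

## Synthetic data

The generators are first-class, tested code and define the study conditions
used throughout the tests and the acceptance script:

* `simulate_counts` — NB counts (variance μ + φμ², default φ = 0.1) with
  log₂-uniform baseline means over [3, 10] (≈8–1024 counts, the informative
  range of a desk-scale library), a 10 % DE fraction at |log₂FC| = 2 with
  random sign applied to every non-reference group, and an optional noise
  tier of features replaced by i.i.d. uniform counts in [0, 5] — abundance-
  exchangeable across samples, which is exactly the signature the noise scan
  detects.
* `simulate_grn_expression` — the first half of genes are independent
  standard-normal drivers; planted edges are sampled from the
  regulator × target grid with ±1 effects; each target is its regulators'
  sum plus Gaussian noise at sd(signal)/SNR (default SNR 5). Values are
  mapped to an abundance scale by an affine 100 + 10z (floored at 0), which
  preserves every linear relation. Distinct regulator/target roles are
  deliberate: with expression data alone, the direction of a pairwise
  dependency is unidentifiable, so edge-recovery is scored over the
  regulator × target grid the roles define.
* `simulate_peaks` — shared true regions (400 bp, ≥2 kb apart so regions
  can never bridge) jittered per sample by ≤20 bp, with uniform per-region
  coverage heights; planted co-membership is recorded.
* `simulate_coords` — non-overlapping stranded intervals across three
  chromosomes.

What the generators do **not** emulate: heavy-tailed abundance
distributions, gene-length and GC biases, correlated dispersion–mean trends,
batch effects, overlapping genes, or read-level error. Passing tests
demonstrate algorithmic correctness and calibration under the stated model,
not robustness to every artefact of real libraries.

## Pipeline and determinism

`run_pipeline` executes preprocess → QC → DE (all configured contrasts) →
patterns → enrichment → GRN from a validated JSON config (unknown keys
rejected), writing each stage's tables, a manifest (version, seed, full
parameter set) and a static HTML index that is a pure function of the
on-disk outputs. Any stage failure aborts with the stage name and cause,
retaining earlier outputs next to a `FAILED` marker. Every source of
randomness is an explicit seed or derived from one; two runs with identical
config and seed produce byte-identical TSVs (verified by test and by the
acceptance script).

## Known limitations

* DE is two-group only: no GLM contrasts, multi-factor designs, or
  fold-change shrinkage.
* The exact test's pseudo-equalisation is linear scaling, slightly cruder
  than quantile adjustment when library sizes are wildly unbalanced.
* The hop-limited neighbourhood is greedy per frontier node; it is not a
  global top-k subgraph.
* cis annotation assumes interval coordinates fit in memory as an interval
  tree per chromosome; no chunking for genome-scale catalogues.
* bedGraph is the only coverage format (no bigWig parsing); bigWig inputs
  should be converted upstream.
* Enrichment treats gene sets as unordered (no ranked GSEA), and the
  hypergeometric assumes exchangeable genes — length/expression bias
  corrections are out of scope.
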