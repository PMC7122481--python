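# Methods

## Model and procedure

The package implements a rank-based diagnostic pipeline for two-group
expression data. Its unit of information is the within-sample relative
expression ordering (REO) of a gene pair (a, b): the indicator of
Ea > Eb in one sample. Because the comparison never leaves the sample,
every REO statistic in the package is exactly invariant under per-sample
strictly increasing transforms; this is tested bit-exactly, not
approximately.

Discovery proceeds in five stages:

1. **Stable pairs.** For each phenotype group separately, a pair is stable
   with direction GT (a over b) iff `n_gt / n_samples >= threshold`, with
   the analogous rule for LT. The threshold default is 0.95 and the
   comparison is inclusive ("at least"). The denominator is the full group
   size: ties (Ea = Eb) and samples where either gene is missing count
   *against* stability. This is the conservative reading; no exclusion rule
   is applied. Because counts are integers, the inclusive comparison is
   implemented as `count >= threshold*n - 1e-9` to absorb the binary
   representation error of products such as 0.95 × 20.
2. **Reversal pairs.** Pairs stable in both groups with opposite dominant
   directions. The positive group's direction becomes the pair's reference
   orientation, so an encoded 1 is the "typical positive" state.
3. **Ternary encoding.** Per sample and oriented pair: 1 if Ea > Eb, 0 if
   Ea < Eb, −1 if either gene is absent from the matrix or missing in that
   sample. Ties encode as 0 rather than introducing a fourth symbol; ties
   are measure-zero on continuous data and the alphabet stays {1, 0, −1}.
4. **mRMR + IFS.** Features are ranked by the greedy incremental
   "difference" scheme: the first feature maximises the plug-in mutual
   information I(g, T) with the phenotype (natural log, 0·ln 0 = 0, no
   pseudocounts or bias correction — the features are already discrete
   3-category variables); each subsequent feature maximises
   I(g, T) − |S|⁻¹ Σ_{s∈S} I(g, s) over the selected set S. The set-level
   min-redundancy/max-relevance objective is realised greedily because
   exact subset optimisation is exponential and the canonical mRMR
   algorithm is incremental. Incremental feature selection then evaluates
   stratified k-fold (default 5) cross-validated SVM accuracy on each
   ranking prefix, reusing one seeded fold split across all prefix sizes so
   the curve is comparable across k, and selects the smallest k attaining
   the maximum accuracy (parsimony at ties).
5. **SVM.** RBF kernel at C = 0.125, γ = 0.5 by default, unweighted
   classes, ternary features fed as numeric {1, 0, −1} without rescaling
   (the alphabet is bounded and symmetric). An optional grid search over
   powers of two (2⁻⁷ … 2⁷ for both C and γ, stratified five-fold CV, ties
   toward smaller C then smaller γ) replaces the default when requested.
   Fitted models serialise to versioned JSON carrying the signature, the
   kernel parameters and the support-vector state; the decision function
   is recomputed from that state, so round-trips are bit-identical.

Evaluation encodes a new matrix against the model's signature (a pair with
an unmeasured gene encodes −1 everywhere — prediction proceeds; it is an
error only when *none* of the signature's genes is present), thresholds the
decision score at 0, and reports sensitivity, specificity and accuracy with
the disease group as positive class. Metrics with empty denominators are
reported as absent, never as 0. ROC/AUC follow the Mann–Whitney convention
(tied positive–negative score pairs credited 0.5), equivalent to the
trapezoidal area under the tie-grouped ROC. Multi-cohort evaluation pools
by micro-averaging: confusion counts are summed before metrics are
computed. AUC confidence intervals are not part of the evaluation path; a
seeded bootstrap could be layered on top by the caller but no interval
method is claimed by the package.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.95 | minimum within-group ordering consistency (fraction of all group samples) |
| `ifs_folds` | 5 | stratified CV folds in IFS and grid search |
| `ifs_step` | 1 | prefix-size increment of the IFS sweep |
| `SvmConfig.C` | 0.125 | SVM cost |
| `SvmConfig.gamma` | 0.5 | RBF width (features are O(1), so γ of order 1 is a natural scale) |
| `SyntheticConfig.consistency` (π) | 1.0 | target within-group ordering consistency of planted pairs |
| `SyntheticConfig.mean_gap` | 2.0 | planted-gene mean separation, log-scale units (used when π = 1) |
| `SyntheticConfig.noise_sd` | 0.3 | per-measurement Gaussian noise, log-scale units |

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes in
real cohorts: a genes × samples log-scale matrix with a small set of
planted reversal pairs among background genes, additive Gaussian noise,
optional per-sample monotone distortions (batch-effect stand-ins of the
form a·x + b·exp(c·x), a, b, c > 0), and optional uniform missingness.
Defaults — 200 genes, 10 planted pairs, 100 samples per class, π = 1,
mean gap 2.0 against noise 0.3 — are the package's standard study
condition used by the end-to-end tests.

Consistency calibration: under the Gaussian model the per-sample
probability that a planted pair keeps its intended order is
Φ(gap / (√2·σ)), so for π < 1 the gap is set to Φ⁻¹(π)·√2·σ in closed
form. π = 1 has no finite calibrated gap under noise, so the configured
`mean_gap` is used directly; π < 1 with σ = 0 is infeasible and raises.
Realized per-group consistencies are measured on the generated matrix and
returned as ground truth, so tests compare detections against what was
actually generated.

Placement: a planted gene's mean moves between groups, so any third gene
whose constant mean fell inside that swing would form an unintended stable
reversal with it. Planted pair baselines therefore occupy reserved
expression bands above the (3σ-clipped) background mean range, spaced so
cross-pair orderings never flip. This makes the planted pairs provably the
only constructed reversals — the property that lets recovery tests demand
*exact* set equality rather than overlap. Background genes receive small
random group effects (σ = 0.05) as realistic null structure.

What the generator does **not** emulate: probe-level microarray artifacts,
count noise of RNA-seq, correlated gene modules, tumor purity or
copy-number confounding, and — by construction — reversal pairs whose genes
overlap other genes' expression ranges. Passing the recovery tests
therefore shows the pipeline's machinery is correct and batch-robust, not
that real cohorts contain pairs this clean; on real data the reversal set
is far larger and noisier and the IFS signature correspondingly longer.

## Numerical and design choices

- **Pair identity** is canonical (gene_a < gene_b lexicographically) with
  direction carried separately; all tie-breaks (mRMR, grid search, output
  ordering) are lexicographic, making every stage deterministic.
- **Pair enumeration** is chunked over gene blocks with bounded memory;
  results are independent of block size (tested). Full pairwise scans of
  ~20k-gene matrices are thereby possible without materialising all ~2×10⁸
  pairs, though the tested scales are smaller.
- **Missing data** are explicit NaN on the float path and "NA"/empty cells
  in TSV; probe collapsing averages per sample over non-missing probes
  only.
- **Gene intersection** across datasets is case-sensitive, no symbol
  aliasing (aliasing is curation, not computation), and returns rows in
  lexicographic order for cross-platform determinism.
- **Probe collapsing before or after pair discovery:** the library exposes
  the primitives separately, so either order can be composed; the pipeline
  runs discovery on the training matrix as given.
- **IFS chooses the smallest k at accuracy ties.** On perfectly consistent
  planted pairs this yields k = 1 — a single flawless ternary feature is a
  perfect classifier — whereas noisy features push k upward. Callers who
  want a redundant signature can widen `consistency` below 1 or take a
  longer ranking prefix.
- **Degenerate inputs:** single-class labels, empty pair sets, more folds
  than minority samples, thresholds outside (0.5, 1], and prediction
  profiles missing signature features all raise informative errors; a
  sample with no measured signature gene predicts (with a logged warning)
  rather than erroring, since unmeasured genes are an expected validation
  condition.

## Known limitations

- The stability rule's treatment of ties/missing (count against, full-group
  denominator) is a documented convention; other conventions change which
  borderline pairs pass at exactly 95%.
- The plug-in MI estimator is biased upward for tiny samples; with the
  3×2 tables used here the bias is immaterial for ranking but the absolute
  scores should not be interpreted as population MI.
- Decision-score calibration degrades when signature genes are unmeasured
  (features pinned at −1 shift all scores); the score *ranking* — hence
  AUC — is much more robust. See `examples/02`.
- The quadratic pair scan is exact, not approximate; at whole-transcriptome
  scale it is CPU-bound and should be run blocked (as implemented) on one
  pass, not repeatedly.
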