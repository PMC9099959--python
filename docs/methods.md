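# Methods

This note documents the models and procedures implemented in `toxsig`,
the tunable parameters and their defaults, what the synthetic benchmark
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Interaction-signature feature space

A compound's feature vector is its interaction score against every
protein in a library. Each protein carries predicted binding sites
consumed as input (site prediction itself is upstream of this package);
a site is a pair (BScore, ligand fingerprint), where BScore ∈ [0,1] is
the site-prediction confidence — required pre-normalized — and the
fingerprint is the ECFP4 (radius-2 circular, folded) bitset of the
site's co-crystallized ligand. The score is

    score(c, p) = max over sites s of p of BScore(s) · Dice(fp_c, fp_s).

Conventions where the definitions are silent:

* Dice of two empty fingerprints is 0 — no features is treated as no
  evidence of similarity, not identity.
* A protein with no predicted sites scores 0 against every compound
  (no interaction evidence).
* Fingerprint width defaults to 1024 bits and is configurable; scores
  are kept at full float precision in memory and rounded to 6 decimals
  in the TSV export (re-import is stable within that rounding).
* The feature space is restricted to structure-solved proteins by
  default (`solved_only`), since site predictions on unsolved proteins
  are not comparable.

## Label preprocessing

Replicate assay measurements are resolved per (compound, assay) pair:
the strictly more frequent label wins; an exact active/inactive tie is
ambiguous and the pair is dropped (dropping is per assay — a compound
ambiguous in one assay keeps its labels elsewhere). SMILES
standardization accepts any parsable single-fragment molecule and
canonicalizes it with the toolkit's canonical form; multi-fragment
entries (salts, mixtures) are rejected rather than salt-stripped, and
rejections are logged with a reason. The train/test split is an input
column, never re-randomized.

## SMOTE + ENN

SMOTE draws a minority base row, one of its `k_smote` (default 5)
nearest minority neighbours, and `u ~ U[0,1]`, emitting
`x + u·(x_nn − x)` until the minority count reaches
`target_ratio × majority` (default 1.0). ENN (`k_enn = 3`) then removes
every sample — of both classes by default, majority-only via
`enn_scope` — whose label loses the strict majority vote of its k
nearest neighbours, evaluated in a single pass against the unedited
data; a tied vote keeps the sample (removal requires positive evidence
of noise). Distances are Euclidean on raw interaction scores: all
features already share the [0,1] scale, so no standardization is
applied. Equal distances break by lower row index, which together with
seeded sampling makes the resampler bit-reproducible across platforms.
The `k` defaults follow the canonical definitions of the two methods.

## Forest training and Gini importance

Hyper-parameters (maximum depth and number of trees) are selected by
grid search under repeated stratified cross-validation — ten folds,
three repeats by default, both configurable — scored by balanced
accuracy. Resampling is fit inside each training fold only, so
validation folds retain the original imbalance and fold scores estimate
deployment performance; a `resample_inside_folds=False` mode replicates
the optimistic resample-before-CV protocol for comparison. All other
forest hyper-parameters stay at the scikit-learn defaults. A
permuted-label control in the test suite verifies the in-fold protocol
scores at chance (mean CV balanced accuracy in [0.45, 0.55]).

Gini importance is computed by traversing the fitted trees directly:
each internal node contributes

    (node weight / root weight) · [Gini(node) − w_L·Gini(left) − w_R·Gini(right)]

to its split feature, with `Gini(P) = 1 − Σ pᵢ²`. Contributions are
summed per tree, averaged over trees, and normalized once to sum 1 (an
option reproduces the normalize-per-tree-then-average convention, which
is used in tests as an independent cross-check against the library
implementation). Only ranks are consumed downstream, so the
normalization convention does not affect selection. Top-k selection
(k = 100 by default) breaks importance ties by lexicographic feature id
so ranked lists are reproducible.

## Enrichment analysis

Over-representation uses the hypergeometric upper tail P(X ≥ k) with
population N (universe), K pathway members, n selected proteins, k
overlap. The tail is accumulated via `logsumexp` over log-pmf terms for
stability at extreme parameters. A `stat="pmf"` option reports the
point probability P(X = k) instead, for replicating analyses that quote
pmf values; the tail is the default because "at least k" is the
meaningful enrichment event. Conventions:

* The universe defaults to proteins that are structure-solved AND
  pathway-annotated; `n` counts only top proteins inside that universe,
  so unannotated proteins cannot inflate significance.
* Pathways with overlap < 2 are not reported (configurable).
* Raw p-values are reported; a Benjamini–Hochberg column is available
  but off by default, matching the common presentation of ranked
  enrichment tables.

## Evaluation metrics

Confusion-matrix metrics follow the standard formulas with every 0/0
returning 0 (so a never-predict-positive classifier reports precision
and F1 of 0, and a zero MCC denominator reports 0). AUCROC is the rank
statistic with half credit for ties; AUPRC is untied step-wise average
precision (no linear interpolation), the conservative estimator for
rare positives. Hard predictions default to thresholding the forest's
class probability at 0.5. `reconstruct_confusion` inverts published
(class counts, recall, specificity) tuples to integer confusion
matrices by nearest-integer rounding, enabling arithmetic
cross-validation of published metric tables.

## Synthetic benchmark

The generator emulates the structure of a multi-assay qHTS panel and
plants a known mechanism:

* **Fingerprint model.** All fingerprints draw bits from a shared
  vocabulary: a general pool (256 bits, gentle 2:1 popularity gradient)
  modelling ordinary chemistry, and a disjoint toxicophore pool (80
  bits) used by causal binding-site ligands. Non-causal compounds are
  mutated copies of ~50 scaffolds (chemical series), so the compound
  cloud is clustered rather than isotropic — as in real libraries, and
  necessary for neighbourhood-based resampling to behave the way it
  does on real data (with isotropic high-dimensional noise, SMOTE
  interpolants concentrate near the centroid and ENN deletes the entire
  majority class by distance concentration).
* **Planted mechanism.** Each causal protein's first site gets a
  confident BScore (≥ 0.7) and a toxicophore ligand; causal-like
  compounds (15% of the library) blend bits from three causal ligands
  with general chemistry, so they score highly at all causal proteins.
  Causal pathways share ~75% of the causal protein set, mirroring how
  interconnected toxicity modules recruit the same core proteins — and
  making over-representation detectable when the selection (top-100 of
  500) covers a fifth of the universe.
* **Labels.** Per assay, labels are Bernoulli with logit
  `effect_size · Σ_j w_j · score_ij − b`, weights `w ~ U(0.5, 1.5)` on
  causal proteins only, and `b` calibrated by bisection so the realized
  post-noise imbalance ratio lands within 10% of its target (an error is
  raised when the target is unreachable, e.g. an extreme ratio under too
  much label noise). Label noise flips 2% of labels; 5% of compounds are
  re-emitted as replicates, a fifth of those with a contradictory label
  (exact 50/50 conflicts, recorded in the ground truth so preprocessing
  can be audited); 20% of compounds form the test split. Twelve assays
  share the causal weights and redraw intercepts and noise, mirroring
  the one-matrix/many-endpoints design of real panels.
* **Defaults as study conditions.** 2000 compounds × 500 proteins,
  20 causal proteins from 4 causal pathways among 40 (sizes 20–50),
  effect size 8, imbalance ratio 8. `effect_size = 0` is the null
  model: labels independent of features, calibration still enforced.

What the benchmark does *not* emulate: real chemistry (no SMILES-level
structure behind the fingerprints), assay biology or cross-assay label
correlation, binding-site prediction error structure, and pathway-size
/ annotation-bias distributions of curated databases. Passing recovery
tests therefore demonstrates that the pipeline's statistics behave as
designed under a known mechanism — not that comparable recovery rates
would be achieved on any particular real panel.

The standard recovery experiment (`toxsig.benchmark`) runs ten seeded
replicates of the default benchmark through resampling, a fixed
250-tree default-depth forest, importance ranking and enrichment.
A fixed forest rather than the full grid-CV is used here because the
experiment measures importance-ranking recovery, not model selection;
grid-CV is exercised separately at smaller scale in the test suite.

## Numerical and reproducibility choices

* Every stochastic stage consumes an explicit seed; derived seeds come
  from `SeedSequence` and stay below 2³¹. Bundles are byte-identical
  across runs of the same config.
* kNN distance ties break by lower row index; squared distances are
  rounded at 1e-12 before sorting so algebraically equal distances
  computed by different code paths compare equal.
* `gini_index` validates that probabilities sum to 1 within 1e-9;
  importance vectors must sum to 1 within 1e-9.
* Degenerate inputs raise informative errors rather than propagating
  NaNs: single-class resampling or training, zero-active imbalance
  ratios, empty post-filter feature spaces, folds that cannot hold a
  minority sample (the error suggests fewer folds), infeasible
  hypergeometric parameters.
* The pipeline manifest records the package version, seed, full
  parameter set and SHA-256 checksums of every input and output, so a
  run is auditable as a pure function of (inputs, config, seed).

## Known limitations

* BScore normalization is assumed done upstream; no attempt is made to
  recalibrate heterogeneous site-prediction scores.
* Mean-decrease-impurity importance dilutes over strongly correlated
  features; recovery of a correlated causal set is therefore bounded
  away from 100% even at large effect sizes (visible in the benchmark's
  per-seed spread).
* The enrichment stage reports raw p-values by design; users comparing
  many pathways across many assays should enable the BH column.
* Salt-containing SMILES are rejected, not stripped; libraries relying
  on counter-ion entries need upstream desalting.
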