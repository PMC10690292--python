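# Methods

This note documents the models and conventions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that make results exactly
reproducible.

## Profile tables and the metadata convention

All stages operate on a rectangular table whose columns are partitioned by
name: columns beginning with `Metadata_` (case-sensitive) are identifiers
and annotations; every other column is a numeric morphology feature. This
is the convention used throughout the image-based profiling community, and
it is enforced as an invariant: the two sets are disjoint, cover the table,
and metadata are never touched by numeric operations. On delimited input
the tokens `""`, `"NA"`, `"NaN"`, `"nan"` read as missing and missing
writes back as an empty field; Parquet round-trips exactly (snappy codec,
recorded in the file metadata). Unparseable feature cells become missing
rather than erroring, so a single corrupt cell cannot abort a screen.

## Single-cell stores and the compartment merge

Single-cell measurements arrive as a relational store in SQLite format: an
`image` table keyed by `ImageNumber` carrying plate/well metadata, and one
object table per compartment (`cells`, `cytoplasm`, `nuclei`) keyed by
`(ImageNumber, ObjectNumber)`. The cytoplasm table carries explicit
`Parent_Cells` and `Parent_Nuclei` link columns. The merge follows those
parent links rather than assuming equal object numbers across compartments
— image-analysis software emits parent links, and assuming equality
silently mispairs objects when segmentation orders differ (the synthetic
store deliberately permutes nuclei numbering to keep this honest). Objects
present in only some compartments are excluded from the merged table and
counted per compartment; image and object numbers are 1-based as produced
upstream and never renumbered, preserving traceability to the images.
Merging more than one compartment requires cytoplasm among them, because
the links live there; this is a convention choice and is validated with an
explicit error.

## Aggregation and consensus

Wells (or perturbation-level consensus profiles) are the per-group median
or mean of each feature, computed over observed cells only — single-cell
features are sporadically missing and dropping whole cells would bias the
per-well counts. The median of an even group is the mean of the two central
order statistics (stated so the test oracles are exact). A per-group
observation count is appended as metadata, and counts are conserved: they
sum to the input row count.

## Normalization

Normalization is strictly fit/apply. `fit_normalization` estimates
parameters on a reference population — selected by a pandas expression
such as `Metadata_compound == 'DMSO'`, a callable, or a mask — and the
frozen model records the selector, the fitted feature list in order, and
the reference size. Applying a model never consults the data it is applied
to; perturbing non-reference rows leaves the fitted parameters
bit-identical (tested).

- **standardize**: location = reference mean, scale = *population*
  standard deviation (ddof 0), matching the common scaler convention in
  profiling pipelines.
- **mad_robustize**: location = reference median, scale = 1.4826 × median
  absolute deviation. The constant makes the MAD an unbiased Gaussian
  scale estimate; it is the standard robust-scale convention.
- **spherize**: ZCA whitening of the reference covariance,
  W = E diag(1/√(λ + ε)) Eᵀ, centered at the reference mean. ZCA (rather
  than PCA) orientation keeps each output dimension aligned with an input
  feature, preserving interpretability. The covariance uses ddof 1 on
  complete reference rows; the regularization ε (default 1e-6, 1e-12 where
  an exact identity is being verified) floors eigenvalues so rank-deficient
  covariances still yield a finite transform. Rows with any missing feature
  propagate missing through the whitening.

All per-feature scales are floored at `epsilon` (default 1e-18), so a
constant reference feature yields a huge but finite output rather than a
division by zero. Location/scale normalization is affine-equivariant and
idempotent to 1e-9 (property-tested). Models serialize to a single JSON
document (vectors, whitening matrix, method, epsilon, feature list).

## Feature selection

Operations run in a configurable order (default: variance → missingness →
correlation → blocklist; cheap filters first) with first-rule-wins
attribution, so the report names exactly one rule and statistic per dropped
feature and covers every input feature exactly once.

- **variance threshold**: for each feature, r = count(2nd most frequent
  value)/count(most frequent value) and u = n_distinct/n_non-missing over
  observed entries; drop when r ≤ freq_cut (default 0.05 — at or below)
  or u ≤ unique_cut (default 0.01). The comparison directions are
  deliberate and tested at the boundary: the count-ratio rule drops *at*
  the cutoff, the missingness rule below does not.
- **missingness**: drop when the missing fraction strictly *exceeds*
  na_cutoff (default 0.05); a feature at exactly 5% missing of 100 rows is
  kept.
- **correlation threshold**: pairwise Pearson on pairwise-complete
  observations, with a minimum of 3 complete pairs (fewer, or a
  zero-variance partner, counts as r = 0 — removing constant features is
  the variance rule's job). While any pair reaches the threshold (default
  0.9), the pair with the largest |r| is taken (earliest in column order on
  ties) and the member with the larger mean absolute correlation to all
  remaining features is dropped; an exact tie drops the later column. The
  greedy procedure is verified against an exhaustive independent replay on
  randomized small tables.
- **blocklist**: shell-style name patterns for known-unreliable feature
  families.

Raising na_cutoff or corr_threshold never shrinks the survivor set;
raising freq_cut never grows it; row order never matters (all
property-tested).

## The injury classification pipeline

**Labeling.** A label scheme maps compound identifiers to one of 15 injury
classes (Control, Cytoskeletal, Hsp90, Kinase, Genotoxin, Miscellaneous,
Redox, HDAC, mTOR, Proteasome, Saponin, Mitochondria, Ferroptosis, Tannin,
Nonspecific Reactive). DMSO wells are Control; wells whose compound the
scheme does not know are removed and counted.

**Holdouts** are carved out in a fixed sequence — whole plates (default
10), whole treatments, then individual wells — and a well eligible for
several holdouts goes to the earliest, making the four sets pairwise
disjoint and exhaustive. Treatment holdout qualification: injuries with
more than 10 associated treatments contribute (by default) one whole
randomly chosen treatment; how many treatments to hold per qualifying
injury is configurable since only the qualification rule is fixed. Well
holdout takes 15 wells per remaining plate — 5 controls plus 10 injury
wells. The phrase "5 controls and 10 wells with each cell injury" is
ambiguous between 15 total and 5 + 10 per injury class; this implementation
takes 15 total, configurable. A plate short of controls contributes all it
has and the shortfall is recorded.

**Split.** The modeling remainder is split with a stratified 80/20 rule;
the test partition is ⌈0.2 n⌉, which yields 10,801/2,701 at n = 13,502,
and per-class proportions match the global split within one well.

**Training.** Multinomial logistic regression with
`class_weight="balanced"` (weights inversely proportional to class
frequencies, countering label imbalance), tuned by randomized search over
penalties {L1, L2, Elastic Net}, strengths {0.0001, 0.01, 0.1, 1, 10,
100}, tolerances {1e-6, 1e-3}, Elastic-Net ratios {0.1, 0.3, 0.5, 0.7,
0.9}, and solvers {newton-cg, lbfgs, liblinear, sag, saga}. Penalties are
expressed through `l1_ratio` (0 = L2, 1 = L1), the current scikit-learn
parameterization. Only valid penalty/solver combinations are sampled
(L1 → liblinear/saga, Elastic Net → saga); invalid combinations are
excluded from sampling rather than failing per-candidate, which would bias
the search. liblinear only fits binary problems in current scikit-learn
(its one-vs-rest wrapper was removed), so it participates only in
two-class searches. The search budget (default 50 candidates), fold count
(5, stratified, shuffled with the run seed) and scoring (macro-F1) are
explicit configuration, as is `max_iter` (default 200); non-convergence is
recorded on the model bundle as a flag, not raised. The bundle holds the
class list, the classes × features coefficient matrix with intercepts, the
chosen hyperparameters, the feature list in order, and the seed, and
serializes to a JSON document plus a CSV coefficient matrix.

**Evaluation** reports per-class precision/recall/F1 and a true-by-
predicted confusion matrix per split (rows sum to the split's true class
counts), plus the per-well class-probability table. The *shuffled
baseline* is a model with the same chosen hyperparameters refit on
label-permuted training data (features intact, fixed seed) — the
conventional permutation null; its macro-F1 sits near 1/n_classes and
calibrates how much of the real model's score is structure rather than
capacity.

**External application.** Feature spaces are matched by name intersection
(in the model list's order; an empty intersection is an error), treatments
by InChIKey. Probabilities per well sum to 1 and the argmax label is
appended.

## The synthetic-screen generator

The generator emulates a multi-plate cytotoxic-compound screen:
plate layouts with a DMSO control fraction (default 0.25 per plate) and
treatment wells cycled evenly across the configured injury classes
(default: all 14 non-control classes, 12 treatments each, 30 plates of
8×12 wells); a compound catalog with synthetic InChIKeys (DMSO keeps its
real public key). Features have four roles with exact ground truth:

- *informative*: unit-variance Gaussian, plus a class shift of
  `effect_size` SD (default 3) on a random half of the informative
  features per class (mimicking distinct phenotype signatures while
  keeping the Bayes classifier derivable), plus a plate batch offset;
- *near-constant*: a dominant value at frequency 0.97 — caught by the
  count-ratio rule;
- *duplicated*: an informative parent plus Normal(0, 1e-6) noise — caught
  by the correlation rule;
- *high-missing*: values missing completely at random at rate 0.2 —
  caught by the missingness rule. Missingness is MCAR only, which keeps
  the selection oracles exact.

Plate batch offsets act along one shared random direction over the
informative features, scaled so entries are marginally Normal(0,
`plate_effect_sd`). The low-rank structure matters: whitening fitted on
controls can only remove batch variation that is concentrated in a few
directions of the control covariance (independent per-feature offsets
would be invisible to it, since whitening a near-diagonal covariance is
just a per-feature rescale), and low-dimensional batch structure is also
what real plate effects look like. At `plate_effect_sd = 1` sphering on
controls cuts the between-plate variance fraction of informative features
by well over half (tested).

All randomness derives from one integer seed through named
`numpy.random.SeedSequence` child streams, so a fixture is byte-identical
across runs and the per-class shift vectors depend only on the seed and
feature composition — which is how an external screen generated from the
same seed shares the training screen's class geometry. External screens
carry a strict feature superset (exercising the intersection step), a
configurable number of wells whose InChIKeys map into the label scheme
(ground-truth overlap), and control-like decoys elsewhere. Single-cell
stores draw per-well cell counts from a Poisson (or fixed) distribution,
permute nuclei object numbers, and can withhold a fraction of cells from
the cells/cytoplasm tables to create orphans. Cell-level tables for the
end-to-end pipeline are wells expanded with Normal(0, 1) per-cell noise,
so aggregation recovers the well profiles up to sampling error.

What the generator does **not** emulate: realistic morphology covariance
between features (beyond the duplicate blocks and the batch direction),
concentration-response structure, spatial plate effects (edge wells),
segmentation errors, or non-random missingness. Passing tests therefore
demonstrate the correctness of the processing layer and the recoverability
of injected structure — not classifier performance on real screens, where
class geometry is far less separable than a 3-SD mean shift.

## Problem sizes and runtime

The test and acceptance workloads are sized for a single CPU: screens of
6–30 plates (up to ~2,900 wells), 60–120 features, classifier checks at
~200 wells per class over 5 classes with a 20-candidate search, and the
end-to-end determinism check on a 10-plate screen with 8 cells per well.
These sizes are deliberate scale-downs of a real screen's tens of
thousands of wells; every statistical contract they verify (recovery,
chance-level baselines, variance-fraction reduction) is scale-free.

## Known limitations

- The spherize model requires complete reference rows; heavily missing
  data should pass the missingness filter first.
- `feature_select` errors if an operation would drop every remaining
  feature rather than returning an empty table.
- The correlation rule computes the full feature-feature correlation
  matrix once (pairwise-complete); for very wide tables (tens of
  thousands of features) this is the memory bottleneck.
- The evaluation's macro-F1 averages only classes present in a split, so
  scores across splits with different class coverage are not directly
  comparable.
- Consensus is an unweighted median/mean; no replicate-correlation
  weighting is implemented.
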