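# Methods

## Problem and model

Plant specialized metabolites (alkaloids, terpenoids, phenylpropanoids,
glucosinolates, benzoxazinoids) are assembled from a limited set of
primary-metabolism precursors: amino acids, prenyl diphosphates (GPP, FPP,
GGPP), flavonoid intermediates, and a few others. `precursorpred` treats
precursor assignment as multi-label classification over molecular structure:
given a SMILES, predict a binary vector over a fixed precursor vocabulary,
where a compound may carry several positive labels (e.g. a monoterpenoid
indole alkaloid derives from both tryptophan and secologanin).

The pipeline is deliberately linear and traceable:

1. **Circular (Morgan) fingerprint.** Every atom-centered environment up to a
   topological radius is hashed into an `n_bits`-wide binary vector. The
   bit → (center atom, radius) map is retained. Defaults: radius 2,
   2048 bits — the community-standard parameters; neither is dictated by the
   task, and both are exposed in configuration and searchable. A layered
   fingerprint backend is available behind the same contract but carries no
   environment map, so models trained on it are declared non-traceable by
   the explanation layer.
2. **Variance-threshold feature selection.** A binary column with positive
   rate p has population variance p(1 − p); columns with variance ≤ τ are
   dropped. The default τ = 0.0628 removes bits seen in fewer than ~6.7 %
   (or more than ~93.3 %) of training molecules. The comparison is strict,
   so constant columns are removed even at τ = 0.
3. **One-vs-rest ridge classifier.** Per label, regularized least squares on
   ±1 targets: minimize ‖Xw + b·1 − y‖² + α‖w‖² with the intercept
   unpenalized (solved by centering, then the normal equations; Cholesky for
   α > 0). Default α = 1. α = 0 is permitted only when the centered design
   has full column rank; otherwise the fit aborts with advice to
   regularize. A label with a single class in training receives a constant
   predictor (w = 0, b = ±1) and is flagged, so the output shape always
   matches the vocabulary. Prediction thresholds the affine score at 0; a
   score of exactly 0 is inactive.

Model selection is an exhaustive (optionally seeded-subsampled) grid search
over (α, τ, radius) maximizing macro-F1 on the validation set; exact ties go
to the smaller α, then smaller τ, then smaller radius, so results are
reproducible. The training command refits the winning configuration on
train + validation before testing.

## Pathway labeling

Biosynthetic pathways are directed acyclic graphs (compounds as nodes,
reactions as directed substrate → product edges); cycles and self-loops are
rejected at construction with the offending cycle named. A compound's
precursors are found by reverse depth-first search that **stops at the first
vocabulary compound on each path** (nearest-precursor rule). Without this
rule every downstream class would inherit all upstream precursors — e.g.
diterpenoids would be labeled with GPP as well as GGPP, contradicting the
intended class → precursor assignments. The rule is recorded in the label
table's metadata. The alternative (collect all vocabulary ancestors) is a
one-line change and is exercised as a contrast in the test fixtures.

## Split regimes

* **Stratified (70/20/10).** Greedy rarest-label-first iterative
  stratification with hard per-subset capacity caps (largest-remainder
  apportionment), so subset sizes are exact to ±1 while per-label positive
  rates are approximately preserved. Ties are broken by remaining capacity,
  then by the seeded RNG.
* **Distant cluster.** Butina sphere-exclusion clustering on 1 − Tanimoto
  (default cutoff 0.6). Entire clusters least similar to the remaining data
  (by mean inter-cluster Tanimoto) form the test pool. A t-SNE-guided manual
  selection would not be reproducible; sphere exclusion is the standard
  deterministic surrogate. For each label, min_train_positives (default 2)
  positive compounds are pinned to the training set — pulled back from the
  test pool if necessary — so no precursor becomes unlearnable.
* **Class overlap.** Every compound in a cross-class pair with Tanimoto ≥
  threshold (default 0.7; "highly similar" is otherwise unquantified) is
  forced into the test set. With no qualifying pair the regime reports an
  empty adversarial core and falls back to plain stratification.

All regimes guarantee disjoint, exhaustive, seed-deterministic partitions.

## Metrics and model comparison

Per label: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean. A zero denominator scores 0 and sets a `degenerate` flag; degenerate
labels still enter the macro averages (mPrecision, mRecall, mF1 are literal
unweighted means), and the flag lets users exclude them consciously.

The Wilcoxon signed-rank test compares two models on paired per-label metric
values: zero differences dropped, |d| ranked with average ranks for ties,
W = min(W⁺, W⁻). The two-sided p-value is exact for n_effective ≤ 25 —
computed by dynamic programming over doubled ranks (equivalent to full
2ⁿ sign-flip enumeration, verified against it in tests) — and otherwise uses
a normal approximation with continuity and tie corrections. Sidedness is
recorded in the result; all-zero differences yield p = 1 with a flag rather
than an error. The cross-validation variant pools differences over all
(label, fold) pairs and then applies the identical procedure.

## Explanations

For a linear model the decision score decomposes exactly as
Σ coefficient·bit + intercept (asserted to 1e-9 in tests). Attributions rank
a label's coefficients by magnitude (ties by bit index) and classify each as
active/inactive × positive/negative; for active bits the atoms and bonds of
every environment hashing to the bit are reported. Hash collisions are kept
as separate environment entries rather than merged, so a collided bit is
visibly ambiguous. Default top_k = 10. SVG depiction with highlighted atoms
is a thin optional writer; the contract output is the JSON atom/bond sets.

## Synthetic data

The generator emulates the statistical shape of curated precursor datasets —
multi-label, imbalanced, with label-defining substructures — without
downloads. Each molecule is a random saturated scaffold (cyclohexane,
tetrahydropyran, piperidine, heptane, bicyclohexyl) optionally decorated
with one marker per label, attached by a single bond at an sp³ CH site so
all products are valence-valid. Default markers are chemically distinctive
moieties of the kind that genuinely drive precursor assignment: indole
(tryptophan-derived alkaloids), quinoline, catechol, a prenyl chain, furan,
at planted frequencies 0.45/0.32/0.22/0.15/0.10 to span the imbalance range
while staying inside the variance-filter band at τ = 0.0628. Label noise
flips final labels with a configurable rate (default 0).

What passing tests on this generator show: the pipeline recovers planted
substructure-label relationships essentially perfectly at zero noise
(held-out mF1 ≥ 0.95 with 300 training molecules) and degrades gracefully
under 20 % label noise while staying above the analytic frequency-matched
random baseline. What they do not show: performance on real metabolite
panels, where labels are not determined by a single clean substructure,
scaffolds correlate with classes, and curation noise is structured rather
than independent. Real-data accuracy must be established with a user-supplied
labeled dataset.

## Numerical choices and limitations

* Tanimoto of two empty fingerprints is defined as 1 (identical molecules
  with no features); similarity matrices have unit diagonal by convention.
* Canonical SMILES under the chemistry backend's default sanitization and
  aromaticity model is the stored molecular identity; canonicalization is
  idempotent and property-tested.
* Problem sizes in tests and the acceptance script (≤ 400 molecules,
  2048-bit fingerprints, 5 labels) were chosen as the smallest sizes at
  which every statistical property under test is well-resolved; the whole
  suite runs in seconds.
* Model files are versioned plain JSON (vocabulary, fingerprint config, τ,
  kept indices, W, b, α) — human-diffable, no opaque pickles.
* Known limitations: no count-based or neural fingerprints (kept out of
  scope as comparison methods), no probability calibration, no
  multiple-testing correction across metric families, and no automated
  retrieval from pathway or natural-product databases.
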