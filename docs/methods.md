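# Methods

## Problem and model

A single amino acid substitution is classified into one of three solubility
outcomes: *decrease*, *no_effect*, *increase*.  The predictor is
sequence-only: no structure, no homology search in the default
configuration.  Two architectures are implemented.

**Two-layer cascade (default).**  Layer 1 is a binary gradient-boosted tree
ensemble trained on all cases with the relabeling {increase, no_effect} →
*not-decreasing*; layer 2 is a second binary ensemble trained only on the
increase/no-effect cases.  At prediction time a case is called *decrease*
when the layer-1 probability meets the decision threshold (ties go to the
positive class); only otherwise is layer 2 consulted.  Predictions are
therefore invariant to layer 2 for every case layer 1 claims, which the test
suite asserts.  The cascade mirrors the biology of the task: the
decrease-vs-rest boundary is the best-supported signal in solubility
corpora, and separating it first lets the harder increase/no-effect boundary
be learned on its own subpopulation.

**Single softmax model.**  A three-class LightGBM model over the same
features, kept as a backend switch (`ModelSpec(kind="single")`) for
comparison.

Both layers are fitted independently even where their feature subsets
overlap; the six shared names are simply computed once and fed to both.

## Feature space

For a substitution (protein P, position p, wt → mut):

| category | count | definition |
|---|---|---|
| amino_acid | one per AAindex scale | `scale(mut) − scale(wt)` |
| variation_type | 400 + 36 | one-hots over ordered residue pairs and residue-group pairs |
| neighborhood | 20 + 5 | residue counts in the 23-window centered on p, plus NonPolarAA/PolarAA/ChargedAA/PosAA/NegAA |
| protein_type | 1 | chain length |

Choices that the feature definitions leave open, and how they are resolved
here:

* **AAindex encoding.**  Each scale contributes a single mutant-minus-wild-
  type delta.  A delta is antisymmetric (checked by property test), carries
  the direction of the physicochemical change, and keeps the per-scale
  dimensionality at one.  Encodings that pass (wt, mut) value pairs instead
  would double the width without changing what the trees can express about a
  substitution, since the one-hot block already identifies the residues.
* **AAindex completeness.**  Entries with any `NA` value are dropped at
  parse time; the number of retained entries is a property of the supplied
  flat file, logged rather than asserted.  The full feature-space size is
  `n_scales + 436 + 25 + 1`.
* **Window truncation.**  The 23-position window (11 each side, site
  included) is truncated at sequence ends — terminal positions see as few as
  12 residues.  Padding with virtual residues would fabricate composition;
  truncated counts remain interpretable as "what is actually there".
* **Neighborhood classes.**  NonPolar = {A,V,L,I,P,F,M,W,G}, Polar =
  {S,T,C,Y,N,Q}, Pos = {K,R,H}, Neg = {D,E}, Charged = Pos ∪ Neg — a
  standard biochemistry partition (C and G are the usual points of textbook
  disagreement).  The sets are a `FeatureSpace` parameter and are recorded
  with the space, so a different convention is a constructor argument, not a
  code change.
* **Conservation stub.**  Two conservation features (a SIFT-style score and
  a homology-hit count) exist in the schema but emit declared missing values
  and are excluded by default: they require external homology searches, and
  none of the shipped default feature subsets use them.
* **Residue alphabet.**  Only the 20 canonical letters are accepted;
  B/J/O/U/X/Z are rejected with a position-naming error rather than imputed,
  because every property table is 20-letter.

The shipped default feature subsets are the published 20-name lists for the
two layers (34 distinct, 6 shared), exposed as `LAYER1_FEATURES`,
`LAYER2_FEATURES` and `FINAL_FEATURES`.

## Learning and feature selection

The learner backend is LightGBM with library-default boosting
hyperparameters (100 rounds, learning rate 0.1, 31 leaves), pinned to
single-threaded deterministic mode so a fixed seed reproduces models
bit-for-bit; the effective parameter dict is stored in every model bundle.
No class reweighting is applied during fitting — imbalance is handled at
evaluation time by matrix normalization, keeping the two concerns separable.
Decision thresholds default to 0.5 per binary layer and are configuration
knobs.

RFE ranks features by total split gain, eliminates the `step` least
important (default 1), and refits until the target count remains; the full
elimination order is recorded.  Gain ties break toward keeping
earlier-listed features (stable sort).  The loop is cross-checked in the
test suite against scikit-learn's `RFE` on the planted-signal fixture.
Whether gain or split-count importance is "correct" is not determinable from
first principles; gain is the default because split counts saturate on
one-hot blocks.

## Validation protocol

Splits are group-atomic on (protein, position): hold-out splits use grouped
shuffling, CV uses stratified group k-fold (stratified by class as far as
group atomicity allows — this extends group atomicity from the blind split
to CV folds as the conservative reading, preventing intra-position leakage
during model selection too).  A fold whose training side lacks a class
aborts with a diagnostic rather than silently fitting a degenerate model.
Blind-test execution refuses to run if any group key is shared between the
sides.  CV reports both the pooled out-of-fold confusion matrix and per-fold
mean one-vs-rest counts, the form in which CV results are conventionally
tabulated (hence fractional counts).

## Evaluation

Raw and normalized reports are always produced in pairs.  Normalization
multiplies true-class row i by `w_i = x_ref / x_i` with *no_effect* as the
default reference; this scheme is the unique per-row rescaling consistent
with published raw/normalized count pairs (the reference row is unchanged).
All ratio measures, CPR and GC² are invariant to which class is the
reference (the choice only sets the global scale), and sensitivity is
invariant to normalization altogether — both asserted as properties.
Undefined ratios (0/0) are reported as NaN, never as 0.  GC² is the Pearson
chi-square against the independence expectation `e_ij = x_i y_j / N`,
divided by `N(K−1)`; it is checked against `scipy.stats.chi2_contingency` on
random matrices and is NaN when a margin is empty.  Per-class binary
measures use the standard one-vs-rest forms PPV = TP/(TP+FP), NPV =
TN/(TN+FN), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

**Matrix reconstruction.**  Published reports that print per-class TP and FP
in raw and normalized form over-determine the 3×3 matrix: each predicted
class column has two off-diagonal cells and two linear constraints (raw sum,
weighted sum), solvable when the two row weights differ.  The solver rounds
to integers and verifies all marginals within printing tolerance (0.5 by
default on normalized counts), raising on inconsistent input.  Equal class
sizes make the system degenerate — and also make reconstruction pointless,
since normalization is then the identity.

## Synthetic data

The fixture generator emulates the *shape* of a curated solubility corpus:
random canonical-alphabet sequences (default 60–300 residues), several
substitutions per sampled position (so grouped splitting is exercised), and
three-class labels at the 3136 : 2166 : 1026 decrease/no-effect/increase
imbalance of the emulated corpus when no signal is planted.  The planted
rule ties labels to features the models can see — hydrophobic → non-
hydrophobic substitutions decrease, the reverse increase, and otherwise a
charged-window count ≥ 8 marks increase — with `signal` interpolating
between the rule and proportion-only noise.  What it does **not** emulate:
real physicochemical determinants of solubility, realistic substitution
spectra, protein family structure, or label noise correlated with assay
type.  Passing the learning tests therefore demonstrates that the pipeline
can recover a learnable sequence-local rule without leakage — not that the
shipped feature set predicts real solubility at any particular accuracy.

Problem sizes used in the automated checks are desk-scale by design:
n = 500 × 51 features × 20 seeds for the RFE retention check, n = 2000 for
the cascade learning check, n ≈ 600–1500 for CV properties.  The
`write_synthetic_aaindex` helper emits an AAindex1-format file whose
accession strings match the shipped subset names but whose values are
random; it is labelled synthetic in its output and docstring and exists so
the 34-name subsets are assemblable without the real database file.

## Numerical and degenerate-input conventions

* Ties at a decision threshold go to the positive class (`≥`).
* Confusion matrices accept fractional counts (per-fold means, normalized
  rows); invariants (non-negativity, squareness) are enforced at
  construction.
* `normalize_confusion` refuses empty true-class rows; `gc2` returns NaN on
  empty margins; `cpr` raises on an empty matrix.
* Duplicate (protein, variant) dataset rows are an error by default,
  deduplicated under an explicit flag.
* All randomness flows through explicit integer seeds (`numpy` generators,
  LightGBM's `seed`, scikit-learn's `random_state`).

## Known limitations

* Conservation features are schema-only; enabling them meaningfully needs an
  external homology pipeline.
* The matrix reconstruction is implemented for K = 3 (the shape of the
  published summaries it targets).
* The class-rebalancing `downsample_class` utility is provided for curation
  workflows but results on rebalanced data are not separately validated.
* Model bundles store LightGBM text dumps; they are portable across
  platforms but not across major LightGBM format revisions.
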