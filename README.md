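# solvar

Sequence-based, three-class prediction of the effect of single amino acid
substitutions on protein solubility: does a variant **decrease** solubility,
**increase** it, or have **no effect**?

Solubility changes caused by point variants matter in disease genetics
(aggregation- and precipitation-linked disorders), protein engineering
(designing constructs that express solubly), and structural biology
(rescuing proteins that will not concentrate for crystallography or NMR).
`solvar` is aimed at computational biologists who need such calls for
individual variants or whole-protein saturation scans, and at method
developers who need the surrounding machinery: leakage-safe validation and
imbalance-aware evaluation of three-class variant predictors.

## The method

Each substitution is mapped to a named numeric feature vector built from
sequence alone:

* **AAindex property deltas** — for each amino acid property scale
  (isoelectric point, hydropathy, ...), `value(mut) − value(wt)`;
* **variation type** — a 20×20 one-hot over ordered (wt, mut) pairs plus a
  6×6 one-hot over residue groups (hydrophobic VILFMWYC, negative DE,
  positive RKH, conformational GP, polar NQS, other AT), 436 indicators;
* **neighborhood** — residue-type counts `AA20D.*` and polarity/charge
  summaries (NonPolarAA, PolarAA, ChargedAA, PosAA, NegAA) over the
  23-position window centered on the site;
* **protein type** — the chain length.

Classification uses a cascade of two binary LightGBM ensembles: layer 1
separates *decreasing* from *not-decreasing* on all cases; layer 2, trained
only on the not-decreasing cases, separates *increasing* from *no effect*.
A single 3-class softmax model is available as an alternative backend.
Feature subsets are chosen by recursive feature elimination (drop the
lowest-gain feature, refit, repeat); the shipped defaults are the published
20 + 20 layer subsets (34 distinct names, 6 shared).

Evaluation works on the K×K confusion matrix `z_ij` (rows = true class):
per-class PPV, NPV, sensitivity and specificity, the correct prediction
ratio `CPR = Σ_i z_ii / N`, and the generalized squared correlation
`GC² = χ² / (N(K−1))` with `e_ij = x_i y_j / N`.  Because solubility corpora
are dominated by decreasing variants, all scores are also reported on a
*normalized* matrix in which every true-class row is rescaled to the
no-effect class size (`w_i = x_ref / x_i`); a random three-class predictor
then scores CPR = 1/3.  Data splits — hold-out and 10-fold CV — are
*position-grouped*: all substitutions at one (protein, position) stay on one
side, preventing leakage from deep mutational scans.

## Worked example

Published three-class evaluations often print only per-class one-vs-rest
counts, raw and normalized.  The raw and normalized false-positive pairs
determine the full 3×3 matrix, which `solvar` reconstructs and scores:

```bash
python examples/evaluate_benchmark_counts.py
```

```
reconstructed confusion matrix (rows = true class):
           decrease  no_effect  increase
decrease        271         56        11
no_effect        43        159        35
increase         23         50        14

raw CPR 0.671 | normalized CPR 0.545 | raw GC2 0.181 | normalized GC2 0.157
```

Of 662 blind-test variants, 444 sit on the diagonal (CPR 0.671); after
rescaling each true class to the no-effect size, the balanced accuracy drops
to 0.545 — still well above the 1/3 random baseline — and the matrix's
association with the truth, scaled to [0, 1], is GC² 0.181.

Other runnable walkthroughs in `examples/`: `predict_variants.py` (train on
synthetic data, classify substitutions), `cross_validate.py`
(position-grouped 10-fold CV with the paired raw/normalized report),
`select_features.py` (RFE recovering a planted signal), and
`featurize_substitution.py` (what one feature vector contains).  A thin CLI
mirrors the pipeline (`solvar fixture | featurize | select-features | train |
cv | predict | evaluate`), including a `--saturation` mode that scores all
19·L substitutions of a sequence.

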