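"""Train a two-layer solubility-effect model on synthetic data and predict variants.

Builds a planted-rule training set, fits the decreasing/not-decreasing +
increasing/no-effect cascade, and classifies three substitutions on a held
protein.  Scores are the two layer probabilities: a case is called
"decrease" when score_decrease >= 0.5, otherwise layer 2 arbitrates between
"increase" (score_increase >= 0.5) and "no_effect".
"""

import tempfile
from pathlib import Path

import numpy as np

from solvar import (
    FeatureSpace, FixtureSpec, fit_two_layer, generate_fixture,
    load_aaindex, predict_two_layer, write_synthetic_aaindex,
)
from solvar.io import LabeledDataset, VariantRecord

work = Path(tempfile.mkdtemp())
write_synthetic_aaindex(work / "synthetic_aaindex.txt", seed=5)
space = FeatureSpace(load_aaindex(work / "synthetic_aaindex.txt"))

train = generate_fixture(FixtureSpec(n_proteins=10, n_variants=1500, signal=1.0, seed=0))
X = space.matrix(train)
y = np.array([v.label for v in train.variants])
model = fit_two_layer(X, y, seed=0)

# classify three substitutions on one of the proteins
pid = next(iter(train.proteins))
seq = train.proteins[pid].sequence
queries = [VariantRecord(pid, 30, seq[29], "S" if seq[29] != "S" else "T"),
           VariantRecord(pid, 31, seq[30], "L" if seq[30] != "L" else "I"),
           VariantRecord(pid, 32, seq[31], "D" if seq[31] != "D" else "E")]
Xq = space.matrix(LabeledDataset(train.proteins, queries))
pred = predict_two_layer(model, Xq)

print(f"training classes: {train.class_counts}")
for v, (_, row) in zip(queries, pred.iterrows()):
    print(f"{pid} {v.notation}: {row.predicted:9s} "
          f"P(decrease)={row.score_decrease:.3f}  P(increase|not-dec)={row.score_increase:.3f}")
print("Each line: predicted solubility effect of the substitution and the two "
      "cascade probabilities that produced the call.")
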