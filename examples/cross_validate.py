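"""Position-grouped 10-fold cross-validation on a synthetic dataset.

All substitutions at one (protein, position) stay in the same fold, so a
deep-mutational-scan position can never leak between training and test.
Prints the pooled raw/normalized report in the conventional paired layout.
"""

import tempfile
from pathlib import Path

from solvar import FeatureSpace, FixtureSpec, generate_fixture, load_aaindex, write_synthetic_aaindex
from solvar.metrics import table_report
from solvar.validation import ModelSpec, run_cv

work = Path(tempfile.mkdtemp())
write_synthetic_aaindex(work / "synthetic_aaindex.txt", seed=5)
space = FeatureSpace(load_aaindex(work / "synthetic_aaindex.txt"))

ds = generate_fixture(FixtureSpec(n_proteins=12, n_variants=1500, signal=0.9, seed=7))
result = run_cv(ds, space.matrix(ds), ModelSpec(kind="two_layer"), k=10, seed=0)

print(f"dataset: {len(ds)} variants, classes {ds.class_counts}\n")
print("pooled out-of-fold report (each cell raw/normalized):")
print(table_report(result.pooled), "\n")
print("per-fold mean counts (raw):")
print(result.fold_mean_counts.round(1))
print("\nWith 10% label noise the planted rule is recovered well above the "
      "1/3 random-predictor baseline for normalized CPR.")
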