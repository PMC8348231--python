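"""Rebuild a full confusion matrix from published one-vs-rest counts and score it.

Three-class evaluation tables often print only per-class TP/FP counts, raw
and normalized.  Because normalization weights each true-class row
differently, the raw and normalized false-positive counts of each predicted
class jointly pin down both off-diagonal cells of that column — so the full
3x3 matrix can be recovered and every metric recomputed from it.
"""

from solvar import cpr, gc2, normalize_confusion, reconstruct_full_matrix
from solvar.metrics import table_report

# blind-test summary of the reference two-layer 34-feature classifier:
# 662 variants; classes decrease/no_effect/increase
class_sizes = (338, 237, 87)
raw_tp = (271, 159, 14)
raw_fp = (66, 106, 46)
norm_fp = (105.7, 175.5, 42.7)

cm = reconstruct_full_matrix(raw_tp, raw_fp, norm_fp, class_sizes)
print("reconstructed confusion matrix (rows = true class):")
print(cm.to_frame().astype(int), "\n")
print(table_report(cm), "\n")
norm = normalize_confusion(cm)
print(f"raw CPR {cpr(cm):.3f} | normalized CPR {cpr(norm):.3f} | "
      f"raw GC2 {gc2(cm):.3f} | normalized GC2 {gc2(norm):.3f}")
print("CPR is the diagonal fraction; GC2 scales the matrix's chi-square "
      "against independence into [0,1]. Normalization rescales every true-class "
      "row to the no-effect class size so the majority class cannot dominate.")
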