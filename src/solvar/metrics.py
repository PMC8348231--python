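"""Confusion-matrix evaluation with class-imbalance normalization.

Solubility datasets are heavily skewed toward decreasing variants, so raw
counts overstate performance on the majority class.  Metrics are therefore
reported twice: on the raw K×K confusion matrix ``z`` (rows = true class i,
columns = predicted class j) and on a *normalized* matrix in which every
true-class row is rescaled to a common reference class size, ``z'_ij =
(x_ref / x_i) · z_ij``.  Per-class sensitivity is a within-row ratio and is
unchanged by the rescaling; PPV, NPV, specificity and the overall scores
shift toward what a balanced dataset would give.

Overall scores:

* **CPR** (correct prediction ratio) — the diagonal fraction ``Σ z_ii / N``.
  A random K-class predictor scores 1/K on a normalized matrix (1/3 here).
* **GC²** (generalized squared correlation) — the Pearson chi-square of the
  matrix against its independence expectation ``e_ij = x_i y_j / N``, scaled
  to [0, 1]: ``GC² = χ² / (N (K − 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLASSES


@dataclass
class ConfusionMatrix:
    """K×K confusion counts with optional per-true-class normalization weights."""

    z: np.ndarray
    labels: tuple[str, ...] = CLASSES
    normalized: bool = False
    weights: np.ndarray | None = None  # per-true-class multipliers, if normalized

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.labels) != self.z.shape[0]:
            raise ValueError("label count must match matrix dimension")
        if (self.z < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def K(self) -> int:
        return self.z.shape[0]

    @property
    def N(self) -> float:
        return float(self.z.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """x_i: number of cases whose true class is i."""
        return self.z.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """y_j: number of cases predicted as class j."""
        return self.z.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=list(self.labels), columns=list(self.labels))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest measures plus the overall CPR and GC² scores."""

    per_class: pd.DataFrame  # rows = classes; columns TP TN FP FN PPV NPV sensitivity specificity
    cpr: float
    gc2: float
    normalized: bool = False
    extras: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalized: {self.normalized}\n")
            for k, v in self.extras.items():
                fh.write(f"# {k}: {v}\n")
            self.per_class.to_csv(fh, sep="\t", float_format="%.6g")
            fh.write(f"CPR\t{self.cpr:.6g}\nGC2\t{self.gc2:.6g}\n")


def confusion_from_predictions(true_labels, predicted_labels, class_order=CLASSES) -> ConfusionMatrix:
    """Count a confusion matrix from aligned true/predicted label sequences."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    z = np.zeros((len(class_order), len(class_order)))
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        z[index[t], index[p]] += 1
    return ConfusionMatrix(z, tuple(class_order))


def normalize_confusion(cm: ConfusionMatrix, reference_class: str = "no_effect") -> ConfusionMatrix:
    """Rescale every true-class row to the reference class size.

    Row i is multiplied by ``w_i = x_ref / x_i``; the reference row is
    unchanged.  All ratio metrics computed downstream are invariant to which
    class is chosen as reference (the choice only sets the overall scale).
    """
    if reference_class not in cm.labels:
        raise ValueError(f"unknown reference class {reference_class!r}")
    x = cm.row_totals
    if (x == 0).any():
        empty = [c for c, xi in zip(cm.labels, x) if xi == 0]
        raise ValueError(f"cannot normalize: empty true class rows {empty}")
    ref = x[cm.labels.index(reference_class)]
    w = ref / x
    return ConfusionMatrix(cm.z * w[:, None], cm.labels, normalized=True, weights=w)


def _one_vs_rest(z: np.ndarray) -> pd.DataFrame:
    diag = np.diag(z)
    x = z.sum(axis=1)
    y = z.sum(axis=0)
    N = z.sum()
    tp = diag
    fn = x - diag
    fp = y - diag
    tn = N - x - y + diag
    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)
    return pd.DataFrame({
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    })


def per_class_measures(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest TP/TN/FP/FN and PPV/NPV/sensitivity/specificity per class.

    Undefined ratios (0/0 denominators) are reported as NaN, never as 0.
    """
    if cm.K < 2:
        raise ValueError("need at least two classes")
    out = _one_vs_rest(cm.z)
    out.index = list(cm.labels)
    return out


def cpr(cm: ConfusionMatrix) -> float:
    """Correct prediction ratio: diagonal mass over total."""
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.z) / cm.N)


def gc2(cm: ConfusionMatrix) -> float:
    """Generalized squared correlation: chi-square / (N·(K−1)), in [0, 1].

    Undefined (NaN) when any row or column margin is zero, since the
    independence expectation degenerates.
    """
    x, y, N = cm.row_totals, cm.col_totals, cm.N
    if N == 0:
        raise ValueError("empty confusion matrix")
    if (x == 0).any() or (y == 0).any():
        return float("nan")
    e = np.outer(x, y) / N
    chi2 = float(((cm.z - e) ** 2 / e).sum())
    return chi2 / (N * (cm.K - 1))


def evaluate(cm: ConfusionMatrix, *, normalized: bool | None = None) -> MetricsReport:
    """Full metrics report for one confusion matrix."""
    return MetricsReport(
        per_class=per_class_measures(cm),
        cpr=cpr(cm),
        gc2=gc2(cm),
        normalized=cm.normalized if normalized is None else normalized,
    )


def reconstruct_full_matrix(
    raw_tp,
    raw_fp,
    normalized_fp,
    class_sizes,
    labels=CLASSES,
    reference_class: str = "no_effect",
    atol: float = 0.5,
) -> ConfusionMatrix:
    """Recover a full 3×3 matrix from one-vs-rest raw and normalized counts.

    Published three-class reports often print only per-class TP/FP (raw and
    normalized) rather than the full matrix.  Because normalization weights
    the two off-diagonal cells of each predicted-class column differently
    (``w_a z_aj + w_b z_bj`` vs ``z_aj + z_bj``), the raw and normalized FP
    counts jointly determine both cells: a 2×2 linear solve per column.

    Parameters are per-class sequences aligned with ``labels``; the result is
    rounded to integers and validated: row sums must match ``class_sizes``
    and the normalized FPs must reproduce within ``atol``.
    """
    labels = tuple(labels)
    K = len(labels)
    if K != 3:
        raise ValueError("reconstruction implemented for K = 3")
    x = np.asarray(class_sizes, dtype=float)
    ref = x[labels.index(reference_class)]
    w = ref / x
    z = np.zeros((3, 3))
    np.fill_diagonal(z, raw_tp)
    for j in range(3):
        rows = [a for a in range(3) if a != j]
        A = np.array([[1.0, 1.0], [w[rows[0]], w[rows[1]]]])
        b = np.array([raw_fp[j], normalized_fp[j]])
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError(f"degenerate weights for column {labels[j]}: cannot separate rows")
        sol = np.linalg.solve(A, b)
        z[rows[0], j], z[rows[1], j] = sol
    z_int = np.rint(z)
    if (z_int < 0).any():
        raise ValueError("inconsistent marginals: negative reconstructed cell")
    # verify: raw FPs exact, normalized FPs within printing tolerance, row sums = class sizes
    for j in range(3):
        rows = [a for a in range(3) if a != j]
        if abs(z_int[rows, j].sum() - raw_fp[j]) > 1e-9:
            raise ValueError(f"inconsistent marginals: raw FP mismatch in column {labels[j]}")
        nfp = (w[rows] * z_int[rows, j]).sum()
        if abs(nfp - normalized_fp[j]) > atol:
            raise ValueError(
                f"inconsistent marginals: normalized FP {nfp:.2f} != "
                f"{normalized_fp[j]} in column {labels[j]}")
    if np.abs(z_int.sum(axis=1) - x).max() > 1e-9:
        raise ValueError("inconsistent marginals: row sums disagree with class sizes")
    return ConfusionMatrix(z_int, labels)


def table_report(raw: ConfusionMatrix, reference_class: str = "no_effect") -> pd.DataFrame:
    """Raw/normalized paired report in the conventional published layout.

    Rows TP/TN/FP/FN and the four ratios per class plus CPR and GC², each
    cell a ``raw/normalized`` string (counts to one decimal, ratios to three).
    """
    norm = normalize_confusion(raw, reference_class)
    pc_r, pc_n = per_class_measures(raw), per_class_measures(norm)
    rows = {}
    for meas in ("TP", "TN", "FP", "FN"):
        rows[meas] = [f"{pc_r.loc[c, meas]:.1f}/{pc_n.loc[c, meas]:.1f}" for c in raw.labels]
    for meas in ("PPV", "NPV", "sensitivity", "specificity"):
        rows[meas] = [f"{pc_r.loc[c, meas]:.3f}/{pc_n.loc[c, meas]:.3f}" for c in raw.labels]
    rows["CPR"] = [f"{cpr(raw):.3f}/{cpr(norm):.3f}"] + [""] * (raw.K - 1)
    rows["GC2"] = [f"{gc2(raw):.3f}/{gc2(norm):.3f}"] + [""] * (raw.K - 1)
    return pd.DataFrame(rows, index=list(raw.labels)).T
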