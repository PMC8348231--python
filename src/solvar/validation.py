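"""Position-grouped validation: train/test splits, 10-fold CV, blind testing.

Deep mutational scans contribute many substitutions at the same residue
position; letting variants of one position straddle the train/test boundary
leaks local sequence context.  Every split here is therefore *group-atomic*
on the (protein, position) key: all substitutions at one position land on
the same side of every partition.  Cross-validation folds are additionally
stratified by class as far as group atomicity allows, to keep the rarest
class present in every fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, StratifiedGroupKFold

from .io import CLASSES, LabeledDataset
from .learner import (
    TwoLayerModel,
    fit_single_multiclass,
    fit_two_layer,
    predict_single,
    predict_two_layer,
)
from .metrics import (
    ConfusionMatrix,
    confusion_from_predictions,
    evaluate,
    normalize_confusion,
    per_class_measures,
)


@dataclass
class ModelSpec:
    """What to fit inside a validation loop.

    kind: ``"two_layer"`` (default) or ``"single"``.  Feature lists default
    to all columns of the supplied matrix.
    """

    kind: str = "two_layer"
    layer1_features: list[str] | None = None
    layer2_features: list[str] | None = None
    features: list[str] | None = None
    params: dict | None = None
    num_rounds: int = 100
    decision_threshold: float = 0.5

    def fit(self, X: pd.DataFrame, y, seed: int):
        if self.kind == "two_layer":
            return fit_two_layer(X, y, self.layer1_features, self.layer2_features,
                                 self.params, seed,
                                 decision_threshold=self.decision_threshold,
                                 num_rounds=self.num_rounds)
        if self.kind == "single":
            return fit_single_multiclass(X, y, self.features, self.params, seed,
                                         num_rounds=self.num_rounds)
        raise ValueError(f"unknown model kind {self.kind!r}")

    def predict(self, model, X: pd.DataFrame) -> pd.DataFrame:
        if isinstance(model, TwoLayerModel):
            cols = sorted(set(model.layer1.feature_names) | set(model.layer2.feature_names))
            return predict_two_layer(model, X[cols] if set(cols) != set(X.columns) else X)
        return predict_single(model, X)


def _group_keys(dataset: LabeledDataset) -> list[tuple[str, int]]:
    return [v.group_key for v in dataset.variants]


def grouped_split(dataset: LabeledDataset, test_fraction: float, seed: int = 0):
    """Position-grouped random train/test partition.

    Returns ``(train, test)`` LabeledDatasets.  Whole (protein, position)
    groups are assigned to one side, so achieved fractions can deviate from
    ``test_fraction`` by up to the largest group size.
    """
    n = len(dataset.variants)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    keys = _group_keys(dataset)
    sizes = pd.Series(keys).value_counts()
    target = round(test_fraction * n)
    if sizes.max() > max(target, n - target):
        raise ValueError(
            f"largest group ({sizes.max()} variants) exceeds both split sides")
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    groups = pd.factorize(pd.Series(keys).astype(str))[0]
    train_idx, test_idx = next(splitter.split(np.zeros(n), groups=groups))
    return dataset.subset(train_idx), dataset.subset(test_idx)


def check_no_leakage(train: LabeledDataset, test: LabeledDataset) -> None:
    """Raise if any (protein, position) group appears on both sides."""
    shared = set(_group_keys(train)) & set(_group_keys(test))
    if shared:
        raise ValueError(f"group leakage between train and test: {sorted(shared)[:5]}")


@dataclass
class CVResult:
    """Pooled out-of-fold confusion matrix plus per-fold bookkeeping."""

    pooled: ConfusionMatrix
    report_raw: object
    report_normalized: object
    fold_matrices: list[ConfusionMatrix]
    fold_mean_counts: pd.DataFrame            # per-class mean TP/TN/FP/FN over folds
    fold_mean_counts_normalized: pd.DataFrame
    predictions: pd.DataFrame                 # per-variant out-of-fold predictions


def run_cv(
    dataset: LabeledDataset,
    X: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    reference_class: str = "no_effect",
) -> CVResult:
    """k-fold cross-validation with position-grouped, class-stratified folds.

    ``X`` is the precomputed feature matrix aligned row-for-row with
    ``dataset.variants``.  Out-of-fold predictions are pooled into one
    confusion matrix; per-fold one-vs-rest counts are also averaged, the
    form in which CV results are conventionally tabulated.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([v.label for v in dataset.variants])
    if any(lbl is None for lbl in y):
        raise ValueError("cross-validation needs fully labeled data")
    if len(X) != len(y):
        raise ValueError("feature matrix and dataset length disagree")
    groups = pd.factorize(pd.Series(_group_keys(dataset)).astype(str))[0]
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    X = X.reset_index(drop=True)

    oof = pd.Series(index=range(len(y)), dtype=object)
    fold_assign = np.full(len(y), -1)
    fold_matrices: list[ConfusionMatrix] = []
    fold_counts, fold_counts_norm = [], []
    for fold, (tr, te) in enumerate(splitter.split(X, y, groups)):
        missing = [c for c in CLASSES if c not in set(y[tr])]
        if missing:
            raise ValueError(
                f"fold {fold}: class(es) {missing} absent from training side; "
                f"use fewer folds or more data")
        model = spec.fit(X.iloc[tr], y[tr], seed)
        pred = spec.predict(model, X.iloc[te])["predicted"].to_numpy()
        oof.iloc[te] = pred
        fold_assign[te] = fold
        cm = confusion_from_predictions(y[te], pred)
        fold_matrices.append(cm)
        fold_counts.append(per_class_measures(cm)[["TP", "TN", "FP", "FN"]])
        cm_n = normalize_confusion(cm, reference_class)
        fold_counts_norm.append(per_class_measures(cm_n)[["TP", "TN", "FP", "FN"]])

    pooled = confusion_from_predictions(y, oof.to_numpy())
    preds = pd.DataFrame({
        "protein_id": [v.protein_id for v in dataset.variants],
        "variant": [v.notation for v in dataset.variants],
        "true": y, "predicted": oof.to_numpy(), "fold": fold_assign,
    })
    return CVResult(
        pooled=pooled,
        report_raw=evaluate(pooled),
        report_normalized=evaluate(normalize_confusion(pooled, reference_class)),
        fold_matrices=fold_matrices,
        fold_mean_counts=sum(fold_counts) / len(fold_counts),
        fold_mean_counts_normalized=sum(fold_counts_norm) / len(fold_counts_norm),
        predictions=preds,
    )


@dataclass
class BlindTestResult:
    confusion: ConfusionMatrix
    report_raw: object
    report_normalized: object
    predictions: pd.DataFrame
    model: object


def run_blind_test(
    train: LabeledDataset,
    test: LabeledDataset,
    X_train: pd.DataFrame,
    X_test: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    reference_class: str = "no_effect",
) -> BlindTestResult:
    """One fit on the training set, one frozen evaluation on the held-out set.

    Aborts if any (protein, position) group is shared between the sides.
    """
    check_no_leakage(train, test)
    y_train = np.array([v.label for v in train.variants])
    y_test = np.array([v.label for v in test.variants])
    model = spec.fit(X_train.reset_index(drop=True), y_train, seed)
    pred = spec.predict(model, X_test.reset_index(drop=True))
    cm = confusion_from_predictions(y_test, pred["predicted"].to_numpy())
    preds = pd.DataFrame({
        "protein_id": [v.protein_id for v in test.variants],
        "variant": [v.notation for v in test.variants],
        "true": y_test, "predicted": pred["predicted"].to_numpy(),
    })
    return BlindTestResult(
        confusion=cm,
        report_raw=evaluate(cm),
        report_normalized=evaluate(normalize_confusion(cm, reference_class)),
        predictions=preds,
        model=model,
    )


def downsample_class(dataset: LabeledDataset, label: str, keep: int, seed: int = 0) -> LabeledDataset:
    """Randomly drop cases of one class down to ``keep`` (a rebalancing utility).

    Provided for dataset curation workflows; results on rebalanced data are
    not otherwise validated here.
    """
    rng = np.random.default_rng(seed)
    idx_label = [i for i, v in enumerate(dataset.variants) if v.label == label]
    if keep >= len(idx_label):
        return dataset
    keep_set = set(rng.choice(idx_label, size=keep, replace=False).tolist())
    idx = [i for i in range(len(dataset.variants))
           if dataset.variants[i].label != label or i in keep_set]
    return dataset.subset(idx)
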