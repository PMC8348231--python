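"""Gradient-boosted tree learners, recursive feature elimination, and the two-layer cascade.

The three-class problem (decrease / no_effect / increase) is solved either by
a single multiclass ensemble or, in the shipped default, by a cascade of two
binary LightGBM ensembles: layer 1 separates *decreasing* from
*not-decreasing* substitutions on all training cases; layer 2 separates
*increasing* from *no effect* and is trained only on the not-decreasing
cases.  At prediction time layer 2 is consulted only when layer 1 scores a
case below its decision threshold, so its output is irrelevant for any case
called decreasing.

Feature subsets are chosen by recursive feature elimination (RFE): fit on
the current feature set, rank features by total gain, drop the least
important, repeat until the target count remains.  The default budgets are
20 features per cascade layer and 30 for the single multiclass model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd

from .io import CLASSES

log = logging.getLogger(__name__)

#: Default feature budgets.
N_FEATURES_PER_LAYER = 20
N_FEATURES_SINGLE = 30

#: LightGBM settings shared by every fit; user params are merged on top.
#: Single-threaded deterministic training so that a fixed seed reproduces
#: models bit-for-bit.
_BASE_PARAMS = {
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
}
_DEFAULT_NUM_ROUNDS = 100


def _prepare(X: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("feature matrix must be a pandas DataFrame with named columns")
    if X.columns.duplicated().any():
        dups = X.columns[X.columns.duplicated()].tolist()
        raise ValueError(f"feature-name collision: {dups}")
    return X


def _check_features(model_features: list[str], X: pd.DataFrame) -> pd.DataFrame:
    missing = [f for f in model_features if f not in X.columns]
    if missing:
        raise ValueError(f"feature mismatch: matrix lacks {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    return X[model_features]


@dataclass
class BinaryEnsembleModel:
    """A fitted binary LightGBM ensemble with its feature contract."""

    booster: lgb.Booster
    feature_names: list[str]
    positive_class: str
    negative_class: str
    decision_threshold: float = 0.5
    params: dict = field(default_factory=dict)
    num_rounds: int = _DEFAULT_NUM_ROUNDS
    seed: int = 0
    n_training_samples: int = 0

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class for each row."""
        Xm = _check_features(self.feature_names, _prepare(X))
        return np.asarray(self.booster.predict(Xm.to_numpy()))

    def predict_label(self, X: pd.DataFrame) -> np.ndarray:
        score = self.predict_score(X)
        return np.where(score >= self.decision_threshold,
                        self.positive_class, self.negative_class)

    def feature_importance(self, kind: str = "gain") -> pd.Series:
        imp = self.booster.feature_importance(importance_type=kind)
        return pd.Series(imp, index=self.feature_names)


@dataclass
class MulticlassEnsembleModel:
    """A fitted K-class LightGBM ensemble (softmax objective)."""

    booster: lgb.Booster
    feature_names: list[str]
    classes: tuple[str, ...]
    params: dict = field(default_factory=dict)
    num_rounds: int = _DEFAULT_NUM_ROUNDS
    seed: int = 0

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xm = _check_features(self.feature_names, _prepare(X))
        return np.asarray(self.booster.predict(Xm.to_numpy()))

    def predict_label(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    def feature_importance(self, kind: str = "gain") -> pd.Series:
        imp = self.booster.feature_importance(importance_type=kind)
        return pd.Series(imp, index=self.feature_names)


@dataclass
class TwoLayerModel:
    """Cascade of decreasing/not-decreasing and increasing/no-effect ensembles."""

    layer1: BinaryEnsembleModel
    layer2: BinaryEnsembleModel
    classes: tuple[str, ...] = CLASSES


@dataclass
class RFERanking:
    """Outcome of recursive feature elimination.

    ``elimination_order`` lists features first-eliminated first; the
    ``selected`` survivors come last in importance terms.  Together they are
    a permutation of the starting feature set.
    """

    elimination_order: list[str]
    selected: list[str]
    target_k: int

    @property
    def full_ranking(self) -> list[str]:
        """All features, least important first."""
        return self.elimination_order + self.selected


def _binarize(y, positive_class) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; nothing to learn")
    if len(classes) > 2:
        raise ValueError(f"expected binary labels, got {list(classes)}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    return (y == positive_class).astype(int)


def fit_binary(
    X: pd.DataFrame,
    y,
    params: dict | None = None,
    seed: int = 0,
    *,
    positive_class=None,
    decision_threshold: float = 0.5,
    num_rounds: int = _DEFAULT_NUM_ROUNDS,
) -> BinaryEnsembleModel:
    """Train a binary gradient-boosted ensemble.

    ``y`` may hold any two label values; ``positive_class`` selects which one
    the score refers to (defaults to the lexicographically larger label).
    Deterministic given (data, params, seed).
    """
    X = _prepare(X)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    y_bin = _binarize(y, positive_class)
    if positive_class is None:
        positive_class = classes[1]
    negative_class = next(c for c in classes if c != positive_class)
    if min(y_bin.sum(), len(y_bin) - y_bin.sum()) < 2:
        raise ValueError("need at least 2 examples per class")
    merged = {**_BASE_PARAMS, "objective": "binary", "seed": seed, **(params or {})}
    train = lgb.Dataset(X.to_numpy(), label=y_bin, params={"verbosity": -1})
    booster = lgb.train(merged, train, num_boost_round=num_rounds)
    return BinaryEnsembleModel(
        booster=booster, feature_names=list(X.columns),
        positive_class=positive_class, negative_class=negative_class,
        decision_threshold=decision_threshold, params=merged,
        num_rounds=num_rounds, seed=seed, n_training_samples=len(X))


def fit_multiclass(
    X: pd.DataFrame,
    y,
    params: dict | None = None,
    seed: int = 0,
    *,
    classes: tuple[str, ...] = CLASSES,
    num_rounds: int = _DEFAULT_NUM_ROUNDS,
) -> MulticlassEnsembleModel:
    """Train a K-class softmax ensemble over ``classes``."""
    X = _prepare(X)
    y = np.asarray(y)
    present = set(np.unique(y))
    if len(present) < 2:
        raise ValueError("labels contain a single class; nothing to learn")
    if not present <= set(classes):
        raise ValueError(f"labels {present - set(classes)} outside class order")
    index = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([index[v] for v in y])
    merged = {**_BASE_PARAMS, "objective": "multiclass", "num_class": len(classes),
              "seed": seed, **(params or {})}
    train = lgb.Dataset(X.to_numpy(), label=y_enc, params={"verbosity": -1})
    booster = lgb.train(merged, train, num_boost_round=num_rounds)
    return MulticlassEnsembleModel(
        booster=booster, feature_names=list(X.columns), classes=tuple(classes),
        params=merged, num_rounds=num_rounds, seed=seed)


def _importance_once(X, y, params, seed, num_rounds) -> pd.Series:
    classes = np.unique(np.asarray(y))
    if len(classes) == 2:
        model = fit_binary(X, y, params, seed, num_rounds=num_rounds)
    else:
        model = fit_multiclass(X, y, params, seed,
                               classes=tuple(sorted(classes)), num_rounds=num_rounds)
    return model.feature_importance("gain")


def rfe_select(
    X: pd.DataFrame,
    y,
    target_k: int,
    step: int = 1,
    seed: int = 0,
    params: dict | None = None,
    num_rounds: int = _DEFAULT_NUM_ROUNDS,
) -> RFERanking:
    """Recursive feature elimination down to ``target_k`` features.

    Each round fits an ensemble on the surviving features, ranks them by
    total gain, and removes the ``step`` least important (never dropping
    below ``target_k``).  Gain ties are broken toward the later column so
    the procedure is deterministic.
    """
    X = _prepare(X)
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if target_k > X.shape[1]:
        raise ValueError(f"target_k {target_k} exceeds feature count {X.shape[1]}")
    remaining = list(X.columns)
    eliminated: list[str] = []
    while len(remaining) > target_k:
        imp = _importance_once(X[remaining], y, params, seed, num_rounds)
        n_drop = min(step, len(remaining) - target_k)
        # stable sort ascending by gain; drop the weakest n_drop
        order = imp.sort_values(kind="stable").index.tolist()
        drop = order[:n_drop]
        eliminated.extend(drop)
        remaining = [f for f in remaining if f not in drop]
    return RFERanking(elimination_order=eliminated, selected=remaining, target_k=target_k)


def fit_two_layer(
    X: pd.DataFrame,
    y,
    layer1_features: list[str] | None = None,
    layer2_features: list[str] | None = None,
    params: dict | None = None,
    seed: int = 0,
    *,
    decision_threshold: float = 0.5,
    num_rounds: int = _DEFAULT_NUM_ROUNDS,
) -> TwoLayerModel:
    """Fit the two-layer cascade on a three-class labeled matrix.

    Layer 1 sees every case (decrease vs. rest); layer 2 is fitted only on
    the increase/no-effect cases.  ``layerN_features`` default to all
    columns; pass the published 20-name subsets to reproduce the compact
    model.  The two layers are fitted independently even where their feature
    sets overlap.
    """
    X = _prepare(X)
    y = np.asarray(y)
    counts = {c: int((y == c).sum()) for c in CLASSES}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"empty class(es) in training labels: {empty}")
    y1 = np.where(y == "decrease", "decrease", "not_decrease")
    m1 = fit_binary(X[layer1_features] if layer1_features else X, y1, params, seed,
                    positive_class="decrease", decision_threshold=decision_threshold,
                    num_rounds=num_rounds)
    mask2 = y != "decrease"
    X2 = (X[layer2_features] if layer2_features else X).loc[mask2]
    m2 = fit_binary(X2, y[mask2], params, seed,
                    positive_class="increase", decision_threshold=decision_threshold,
                    num_rounds=num_rounds)
    return TwoLayerModel(layer1=m1, layer2=m2)


def predict_two_layer(model: TwoLayerModel, X: pd.DataFrame) -> pd.DataFrame:
    """Predict classes and report both layer scores.

    A case is called *decrease* when the layer-1 score meets its threshold
    (ties go to the positive class); otherwise layer 2 decides between
    *increase* and *no_effect*.  Both scores are reported for every case even
    though layer 2 is decision-irrelevant for cases called decreasing.
    """
    s1 = model.layer1.predict_score(X)
    s2 = model.layer2.predict_score(X)
    decrease = s1 >= model.layer1.decision_threshold
    increase = s2 >= model.layer2.decision_threshold
    labels = np.where(decrease, "decrease", np.where(increase, "increase", "no_effect"))
    return pd.DataFrame({
        "predicted": labels,
        "score_decrease": s1,
        "score_increase": s2,
    }, index=X.index)


def fit_single_multiclass(
    X: pd.DataFrame,
    y,
    features: list[str] | None = None,
    params: dict | None = None,
    seed: int = 0,
    num_rounds: int = _DEFAULT_NUM_ROUNDS,
) -> MulticlassEnsembleModel:
    """Fit the single three-class model (default budget: 30 features)."""
    X = _prepare(X)
    return fit_multiclass(X[features] if features else X, y, params, seed,
                          num_rounds=num_rounds)


def predict_single(model: MulticlassEnsembleModel, X: pd.DataFrame) -> pd.DataFrame:
    proba = model.predict_proba(X)
    out = pd.DataFrame(proba, columns=[f"score_{c}" for c in model.classes], index=X.index)
    out.insert(0, "predicted", np.asarray(model.classes)[np.argmax(proba, axis=1)])
    return out


# ---------------------------------------------------------------------------
# Model persistence: a versioned directory bundle of plain-text artifacts.

_BUNDLE_VERSION = 1


def save_model(model: TwoLayerModel | MulticlassEnsembleModel, path) -> None:
    """Persist a model as a directory of LightGBM text dumps plus metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, TwoLayerModel):
        meta = {
            "bundle_version": _BUNDLE_VERSION,
            "kind": "two_layer",
            "classes": list(model.classes),
            "layers": {},
        }
        for name, layer in (("layer1", model.layer1), ("layer2", model.layer2)):
            (path / f"{name}.txt").write_text(layer.booster.model_to_string())
            meta["layers"][name] = {
                "feature_names": layer.feature_names,
                "positive_class": layer.positive_class,
                "negative_class": layer.negative_class,
                "decision_threshold": layer.decision_threshold,
                "params": layer.params,
                "num_rounds": layer.num_rounds,
                "seed": layer.seed,
            }
    else:
        meta = {
            "bundle_version": _BUNDLE_VERSION,
            "kind": "single",
            "classes": list(model.classes),
            "feature_names": model.feature_names,
            "params": model.params,
            "num_rounds": model.num_rounds,
            "seed": model.seed,
        }
        (path / "model.txt").write_text(model.booster.model_to_string())
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> TwoLayerModel | MulticlassEnsembleModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("bundle_version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('bundle_version')}")
    if meta["kind"] == "two_layer":
        layers = {}
        for name in ("layer1", "layer2"):
            lm = meta["layers"][name]
            layers[name] = BinaryEnsembleModel(
                booster=lgb.Booster(model_str=(path / f"{name}.txt").read_text()),
                feature_names=lm["feature_names"],
                positive_class=lm["positive_class"],
                negative_class=lm["negative_class"],
                decision_threshold=lm["decision_threshold"],
                params=lm["params"], num_rounds=lm["num_rounds"], seed=lm["seed"])
        return TwoLayerModel(layer1=layers["layer1"], layer2=layers["layer2"],
                             classes=tuple(meta["classes"]))
    if meta["kind"] == "single":
        return MulticlassEnsembleModel(
            booster=lgb.Booster(model_str=(path / "model.txt").read_text()),
            feature_names=meta["feature_names"], classes=tuple(meta["classes"]),
            params=meta["params"], num_rounds=meta["num_rounds"], seed=meta["seed"])
    raise ValueError(f"unknown model kind {meta['kind']!r}")
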