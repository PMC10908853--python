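"""Final-stage classifiers: a deterministic CART tree, bagging, and a random
forest, plus an adapter registry for external boosters.

The tree is greedy binary CART on Gini impurity with axis-aligned thresholds
at midpoints of consecutive distinct sorted values. Tie-breaking is fixed
(lowest feature index, then lowest threshold) so fits are bit-reproducible.
Bagging fits each tree on a bootstrap resample and votes; the random forest
additionally samples a random feature subset at every split. Hard labels come
from majority vote (ties at exactly 0.5 predict positive, favouring minority
detection); ``predict_scores`` returns mean leaf scores in [0, 1] for ROC use.

External gradient boosting (e.g. XGBoost) is consumed through
:func:`register_backend`/:func:`make_model`; a missing backend raises a named
error at use time, never at import time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import LabeledDataset

__all__ = [
    "TrainedModel",
    "DecisionTree",
    "BaggingEnsemble",
    "RandomForest",
    "ExternalModel",
    "MissingBackendError",
    "train_tree",
    "train_bagging",
    "train_random_forest",
    "feature_importance",
    "register_backend",
    "available_backends",
    "make_model",
    "save_model",
    "load_model",
]


class MissingBackendError(RuntimeError):
    """Requested external classifier backend is not available."""


# --------------------------------------------------------------------------
# Decision tree
# --------------------------------------------------------------------------

_MAX_DEPTH_CAP = 64


def _gini(n_pos: float, n_tot: float) -> float:
    if n_tot <= 0:
        return 0.0
    p = n_pos / n_tot
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _best_split(X, y, feat_indices, min_samples_leaf):
    """Best (gain, feature, threshold) over candidate features, or None.

    Ties in gain resolve to the lowest feature index then lowest threshold;
    thresholds are midpoints between consecutive distinct values.
    """
    n = y.size
    parent = _gini(y.sum(), n)
    best = None  # (gain, feature, threshold)
    for f in feat_indices:
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y[order]
        cut = np.flatnonzero(np.diff(xs) > 0)  # split after sorted position i
        if cut.size == 0:
            continue
        n_left = cut + 1
        n_right = n - n_left
        ok = (n_left >= min_samples_leaf) & (n_right >= min_samples_leaf)
        if not ok.any():
            continue
        cut, n_left, n_right = cut[ok], n_left[ok], n_right[ok]
        pos_cum = np.cumsum(ys)
        pos_left = pos_cum[cut]
        pos_right = pos_cum[-1] - pos_left
        pl = pos_left / n_left
        pr = pos_right / n_right
        gini_left = 1.0 - pl * pl - (1.0 - pl) ** 2
        gini_right = 1.0 - pr * pr - (1.0 - pr) ** 2
        weighted = (n_left * gini_left + n_right * gini_right) / n
        gains = parent - weighted
        i = int(np.argmax(gains))  # first max -> lowest threshold (xs ascending)
        gain = float(gains[i])
        thr = float(0.5 * (xs[cut[i]] + xs[cut[i] + 1]))
        if best is None or gain > best[0] + 1e-12:
            best = (gain, int(f), thr)
    return best


@dataclass
class TrainedModel:
    """Common classifier contract: scores in [0, 1], labels by threshold/vote."""

    kind: str
    params: dict = field(default_factory=dict)

    def predict_scores(self, X) -> np.ndarray:
        raise NotImplementedError

    def _vote_fraction(self, X) -> np.ndarray:
        # Default: score doubles as the voting statistic.
        return self.predict_scores(X)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self._vote_fraction(X) >= threshold).astype(int)


class DecisionTree(TrainedModel):
    """Greedy binary CART with Gini impurity; leaf score = positive fraction."""

    def __init__(self, max_depth=None, min_samples_leaf=1, features_per_split=None,
                 seed=0):
        super().__init__(kind="tree", params={
            "max_depth": max_depth, "min_samples_leaf": min_samples_leaf,
            "features_per_split": features_per_split, "seed": seed,
        })
        self.root: dict | None = None
        self.n_features: int = 0
        self._importance_raw: np.ndarray | None = None

    def fit(self, X, y, rng: np.random.Generator | None = None) -> "DecisionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] == 0:
            raise ValueError("cannot fit a tree on an empty dataset")
        self.n_features = X.shape[1]
        self._importance_raw = np.zeros(self.n_features)
        if rng is None:
            rng = np.random.default_rng(int(self.params["seed"]))
        max_depth = self.params["max_depth"]
        max_depth = _MAX_DEPTH_CAP if max_depth is None else int(max_depth)
        self.root = self._grow(X, y, depth=0, max_depth=max_depth,
                               n_root=X.shape[0], rng=rng)
        return self

    def _candidate_features(self, rng) -> np.ndarray:
        m = self.params["features_per_split"]
        if m is None or m >= self.n_features:
            return np.arange(self.n_features)
        return np.sort(rng.choice(self.n_features, size=int(m), replace=False))

    def _grow(self, X, y, depth, max_depth, n_root, rng) -> dict:
        n = y.size
        n_pos = float(y.sum())
        leaf = {"leaf": n_pos / n, "n": int(n)}
        if depth >= max_depth or n_pos in (0.0, n) or n < 2 * self.params["min_samples_leaf"]:
            return leaf
        feats = self._candidate_features(rng)
        best = _best_split(X, y, feats, self.params["min_samples_leaf"])
        if best is None and feats.size < self.n_features:
            # Sampled features were all constant on this node; fall back to all.
            best = _best_split(X, y, np.arange(self.n_features),
                               self.params["min_samples_leaf"])
        if best is None:
            return leaf
        gain, f, thr = best
        mask = X[:, f] <= thr
        self._importance_raw[f] += (n / n_root) * gain
        return {
            "feature": int(f),
            "threshold": float(thr),
            "left": self._grow(X[mask], y[mask], depth + 1, max_depth, n_root, rng),
            "right": self._grow(X[~mask], y[~mask], depth + 1, max_depth, n_root, rng),
        }

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        self._route(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _route(self, node, X, idx, out) -> None:
        if "leaf" in node:
            out[idx] = node["leaf"]
            return
        mask = X[idx, node["feature"]] <= node["threshold"]
        self._route(node["left"], X, idx[mask], out)
        self._route(node["right"], X, idx[~mask], out)

    @property
    def depth(self) -> int:
        def _d(node):
            if "leaf" in node:
                return 0
            return 1 + max(_d(node["left"]), _d(node["right"]))
        return _d(self.root)


class BaggingEnsemble(TrainedModel):
    """Bootstrap-aggregated trees; vote for labels, mean score for ranking."""

    def __init__(self, n_estimators=100, max_depth=None, min_samples_leaf=1,
                 features_per_split=None, bootstrap=True, seed=0, kind="bagging"):
        super().__init__(kind=kind, params={
            "n_estimators": n_estimators, "max_depth": max_depth,
            "min_samples_leaf": min_samples_leaf,
            "features_per_split": features_per_split,
            "bootstrap": bootstrap, "seed": seed,
        })
        self.trees: list[DecisionTree] = []

    def fit(self, X, y) -> "BaggingEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        p = self.params
        self.trees = []
        streams = np.random.SeedSequence(int(p["seed"])).spawn(p["n_estimators"])
        for ss in streams:
            rng = np.random.default_rng(ss)
            if p["bootstrap"]:
                idx = rng.integers(0, n, size=n)
            else:
                idx = np.arange(n)
            tree = DecisionTree(p["max_depth"], p["min_samples_leaf"],
                                p["features_per_split"], seed=0)
            tree.fit(X[idx], y[idx], rng=rng)
            self.trees.append(tree)
        return self

    def predict_scores(self, X) -> np.ndarray:
        return np.mean([t.predict_scores(X) for t in self.trees], axis=0)

    def _vote_fraction(self, X) -> np.ndarray:
        votes = [(t.predict_scores(X) >= 0.5).astype(float) for t in self.trees]
        return np.mean(votes, axis=0)


class RandomForest(BaggingEnsemble):
    """Bagged trees with a random feature subset considered at every split."""

    def __init__(self, n_estimators=100, max_depth=None, min_samples_leaf=1,
                 features_per_split=None, bootstrap=True, seed=0):
        super().__init__(n_estimators, max_depth, min_samples_leaf,
                         features_per_split, bootstrap, seed, kind="forest")

    def fit(self, X, y) -> "RandomForest":
        if self.params["features_per_split"] is None:
            d = np.asarray(X).shape[1]
            self.params["features_per_split"] = max(1, int(np.sqrt(d)))
        fps = self.params["features_per_split"]
        if not 1 <= fps <= np.asarray(X).shape[1]:
            raise ValueError(f"features_per_split={fps} outside [1, d]")
        return super().fit(X, y)


class ExternalModel(TrainedModel):
    """Wraps any fit/score backend behind the common contract."""

    def __init__(self, name: str, estimator, params=None):
        super().__init__(kind="external", params={"backend": name, **(params or {})})
        self.estimator = estimator

    def fit(self, X, y) -> "ExternalModel":
        self.estimator.fit(np.asarray(X, float), np.asarray(y, int).ravel())
        return self

    def predict_scores(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            scores = np.asarray(est.predict_proba(np.asarray(X, float)))[:, -1]
        else:
            scores = np.asarray(est.predict(np.asarray(X, float)), dtype=float)
        return np.clip(scores, 0.0, 1.0)


# --------------------------------------------------------------------------
# Training front-ends
# --------------------------------------------------------------------------

def _xy(train):
    if isinstance(train, LabeledDataset):
        return train.features, train.labels
    X, y = train
    return np.asarray(X, float), np.asarray(y, int)


def train_tree(train, max_depth=None, min_samples_leaf=1, seed=0) -> DecisionTree:
    X, y = _xy(train)
    if np.unique(y).size < 2 and y.size == 0:
        raise ValueError("empty training set")
    return DecisionTree(max_depth, min_samples_leaf, None, seed).fit(X, y)


def train_bagging(train, n_estimators=100, max_depth=None, min_samples_leaf=1,
                  bootstrap=True, seed=0) -> BaggingEnsemble:
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    X, y = _xy(train)
    return BaggingEnsemble(n_estimators, max_depth, min_samples_leaf, None,
                           bootstrap, seed).fit(X, y)


def train_random_forest(train, n_estimators=100, max_depth=None,
                        min_samples_leaf=1, features_per_split=None,
                        bootstrap=True, seed=0) -> RandomForest:
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    X, y = _xy(train)
    return RandomForest(n_estimators, max_depth, min_samples_leaf,
                        features_per_split, bootstrap, seed).fit(X, y)


def feature_importance(model: TrainedModel) -> np.ndarray:
    """Mean impurity decrease per feature, normalised to sum to 1.

    A model that never split (single leaf) has no defined importances; the
    result is then an all-NaN vector, flagging 'undefined' without silently
    pretending uniform relevance.
    """
    if isinstance(model, DecisionTree):
        raw = model._importance_raw
    elif isinstance(model, BaggingEnsemble):
        raw = np.mean([t._importance_raw for t in model.trees], axis=0)
    elif isinstance(model, ExternalModel):
        est = model.estimator
        if hasattr(est, "feature_importances_"):
            raw = np.asarray(est.feature_importances_, dtype=float)
        else:
            raise MissingBackendError(
                f"backend {model.params['backend']!r} exposes no feature importances"
            )
    else:
        raise TypeError(f"unsupported model kind {model.kind!r}")
    total = raw.sum()
    if total <= 0:
        return np.full(raw.shape, np.nan)
    return raw / total


# --------------------------------------------------------------------------
# External backend registry
# --------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., TrainedModel]] = {}


def register_backend(name: str, factory: Callable[..., TrainedModel]) -> None:
    _REGISTRY[name] = factory


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def make_model(name: str, **params) -> TrainedModel:
    """Instantiate a registered classifier by name (untrained)."""
    if name not in _REGISTRY:
        raise MissingBackendError(
            f"unknown classifier backend {name!r}; available: {available_backends()}"
        )
    return _REGISTRY[name](**params)


def _xgboost_factory(**params) -> ExternalModel:
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise MissingBackendError(
            "backend 'xgboost' requires the xgboost package to be installed"
        ) from exc
    seed = params.pop("seed", 0)
    defaults = dict(n_estimators=100, max_depth=6, eval_metric="logloss")
    defaults.update(params)
    return ExternalModel("xgboost", XGBClassifier(random_state=seed, **defaults),
                         params=defaults)


register_backend("tree", lambda **p: DecisionTree(
    p.get("max_depth"), p.get("min_samples_leaf", 1), None, p.get("seed", 0)))
register_backend("bagging", lambda **p: BaggingEnsemble(
    p.get("n_estimators", 100), p.get("max_depth"), p.get("min_samples_leaf", 1),
    None, p.get("bootstrap", True), p.get("seed", 0)))
register_backend("forest", lambda **p: RandomForest(
    p.get("n_estimators", 100), p.get("max_depth"), p.get("min_samples_leaf", 1),
    p.get("features_per_split"), p.get("bootstrap", True), p.get("seed", 0)))
register_backend("xgboost", _xgboost_factory)


# --------------------------------------------------------------------------
# JSON serialisation
# --------------------------------------------------------------------------

def _tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "params": tree.params,
        "n_features": tree.n_features,
        "root": tree.root,
        "importance_raw": tree._importance_raw.tolist(),
    }


def _tree_from_dict(d: dict) -> DecisionTree:
    p = d["params"]
    tree = DecisionTree(p["max_depth"], p["min_samples_leaf"],
                        p["features_per_split"], p["seed"])
    tree.n_features = d["n_features"]
    tree.root = d["root"]
    tree._importance_raw = np.asarray(d["importance_raw"], dtype=float)
    return tree


def save_model(model: TrainedModel, path) -> None:
    if isinstance(model, DecisionTree):
        payload = {"kind": "tree", "tree": _tree_to_dict(model)}
    elif isinstance(model, BaggingEnsemble):
        payload = {
            "kind": model.kind,
            "params": model.params,
            "trees": [_tree_to_dict(t) for t in model.trees],
        }
    else:
        raise TypeError("only built-in models serialise to JSON")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] == "tree":
        return _tree_from_dict(payload["tree"])
    p = payload["params"]
    cls = RandomForest if payload["kind"] == "forest" else BaggingEnsemble
    model = cls(p["n_estimators"], p["max_depth"], p["min_samples_leaf"],
                p["features_per_split"], p["bootstrap"], p["seed"])
    model.trees = [_tree_from_dict(t) for t in payload["trees"]]
    return model
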