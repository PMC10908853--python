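"""Cluster-weighted both-sampling: the CSBBoost resampling core.

The training set is split into majority and minority classes; each class is
K-means clustered (K chosen by mean silhouette). Cluster i of the majority
class, holding O_i of the N_ma majority rows, gets weight w_i = O_i / N_ma
and retention quota s_i = floor(w_i * N / 2), where N is the training size;
rows are drawn uniformly without replacement inside each cluster. Minority
cluster i (O'_i of N_mi rows) gets w'_i = O'_i / N_mi and a synthesis quota
s'_i = floor(w'_i * N / 2) - O'_i (clamped at 0), filled by SMOTE restricted
to that cluster: each synthetic point is x + u (z - x) with u ~ U(0, 1), x a
random cluster member and z one of its k nearest same-cluster neighbours.
The retained majority, original minority and synthetic minority rows merge
into a balanced set whose size matches the original up to quota rounding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from ._util import derive_seed, floor_quota
from .clustering import kmeans, select_k
from .data import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ClassSubset",
    "ClassSplit",
    "SamplingPlan",
    "BalancedDataset",
    "ResampleReport",
    "ResampleConfig",
    "SmoteResult",
    "QuotaError",
    "split_classes",
    "compute_weights",
    "plan_undersampling",
    "plan_oversampling",
    "undersample",
    "smote_within_cluster",
    "resample_with_assignments",
    "fit_resample",
]

ORIGIN_MAJORITY = "retained-majority"
ORIGIN_MINORITY = "original-minority"
ORIGIN_SYNTHETIC = "synthetic-minority"


class QuotaError(ValueError):
    """A sampling quota is inconsistent with the cluster it applies to."""


@dataclass
class ClassSubset:
    """The rows of one class, with clustering results once available."""

    rows: np.ndarray
    class_role: Literal["majority", "minority"]
    class_total: int
    assignments: np.ndarray | None = None
    cluster_sizes: np.ndarray | None = None

    def set_assignments(self, assignments: np.ndarray) -> None:
        assignments = np.asarray(assignments, dtype=int)
        if assignments.shape[0] != self.rows.shape[0]:
            raise ValueError("assignments length must match rows")
        sizes = np.bincount(assignments)
        if (sizes == 0).any():
            raise ValueError("every cluster must be non-empty")
        self.assignments = assignments
        self.cluster_sizes = sizes


@dataclass
class ClassSplit:
    majority: ClassSubset
    minority: ClassSubset
    tied: bool = False


@dataclass
class SamplingPlan:
    """Cluster weights and per-cluster quotas for one class."""

    weights: np.ndarray
    quotas: np.ndarray
    N: int
    mode: Literal["under", "over"]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.quotas = np.asarray(self.quotas, dtype=int)
        # Tolerance admits display-rounded weights (3-decimal tables); the
        # pipeline's own weights from compute_weights are exact to 1e-12.
        if abs(self.weights.sum() - 1.0) > 5e-3:
            raise ValueError("plan weights must sum to 1")
        if (self.quotas < 0).any():
            raise QuotaError("quotas must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.quotas.sum())

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "weights": [float(w) for w in self.weights],
            "quotas": [int(q) for q in self.quotas],
            "N": int(self.N),
        }


@dataclass
class SmoteResult:
    """Synthetic points with full parentage for geometry audits."""

    points: np.ndarray      # n_new x d
    parent_a: np.ndarray    # index of the base point x
    parent_b: np.ndarray    # index of the neighbour z
    u: np.ndarray           # interpolation coefficient in [0, 1)


@dataclass
class BalancedDataset:
    """The merged balanced training set with per-row provenance tags."""

    dataset: LabeledDataset
    origin: np.ndarray  # array of origin tag strings, length n

    def counts(self) -> dict[str, int]:
        tags, counts = np.unique(self.origin, return_counts=True)
        return dict(zip(tags.tolist(), counts.tolist()))

    def to_dataframe(self, label_column: str = "label"):
        df = self.dataset.to_dataframe(label_column)
        df["origin"] = self.origin
        return df

    def write_csv(self, path, label_column: str = "label") -> None:
        self.to_dataframe(label_column).to_csv(path, index=False)


@dataclass
class ResampleConfig:
    k_min: int = 2
    k_max: int | None = None
    k_neighbors: int = 5
    seed: int = 0
    scale_features: bool = False
    smote_pool: Literal["cluster", "class"] = "cluster"
    n_init: int = 10

    def to_dict(self) -> dict:
        return {
            "k_min": self.k_min,
            "k_max": self.k_max,
            "k_neighbors": self.k_neighbors,
            "seed": self.seed,
            "scale_features": self.scale_features,
            "smote_pool": self.smote_pool,
            "n_init": self.n_init,
        }


@dataclass
class ResampleReport:
    """Provenance of one resampling run: K choices, sizes, plans, counts."""

    n_train: int
    majority_k: int
    minority_k: int
    majority_cluster_sizes: list[int]
    minority_cluster_sizes: list[int]
    majority_plan: SamplingPlan | None
    minority_plan: SamplingPlan | None
    majority_out: int
    minority_out: int
    seed: int
    k_neighbors: int
    noop: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "majority_k": self.majority_k,
            "minority_k": self.minority_k,
            "majority_cluster_sizes": self.majority_cluster_sizes,
            "minority_cluster_sizes": self.minority_cluster_sizes,
            "majority_plan": self.majority_plan.to_dict() if self.majority_plan else None,
            "minority_plan": self.minority_plan.to_dict() if self.minority_plan else None,
            "majority_out": self.majority_out,
            "minority_out": self.minority_out,
            "seed": self.seed,
            "k_neighbors": self.k_neighbors,
            "noop": self.noop,
            "notes": self.notes,
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def split_classes(train: LabeledDataset) -> ClassSplit:
    """Separate majority and minority rows of the training set.

    The larger class is the majority; an exact 50/50 tie makes the class
    labelled 0 the nominal majority and flags the split so resampling can
    no-op.
    """
    n0, n1 = train.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("training set contains a single class")
    tied = n0 == n1
    maj_label = 0 if n0 >= n1 else 1
    maj_mask = train.labels == maj_label
    majority = ClassSubset(train.features[maj_mask], "majority", int(maj_mask.sum()))
    minority = ClassSubset(train.features[~maj_mask], "minority", int((~maj_mask).sum()))
    return ClassSplit(majority, minority, tied)


def compute_weights(cluster_sizes, class_total: int) -> np.ndarray:
    """Cluster weights w_i = O_i / class total, at full precision."""
    sizes = np.asarray(cluster_sizes, dtype=int)
    if class_total <= 0:
        raise ValueError("class_total must be positive")
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    if sizes.sum() != class_total:
        raise ValueError(
            f"cluster sizes sum to {sizes.sum()}, expected class_total={class_total}"
        )
    return sizes / float(class_total)


def plan_undersampling(weights, cluster_sizes, N: int) -> SamplingPlan:
    """Majority retention quotas s_i = floor(w_i * N / 2).

    Whenever the class really is the majority (N_ma >= N/2) every quota fits
    inside its cluster; a quota exceeding its cluster signals misuse and
    raises.
    """
    weights = np.asarray(weights, dtype=float)
    sizes = np.asarray(cluster_sizes, dtype=int)
    if N < 2:
        raise ValueError("N must be at least 2")
    quotas = np.array([floor_quota(w * N / 2.0) for w in weights], dtype=int)
    if (quotas > sizes).any():
        raise QuotaError(
            f"under-sampling quota exceeds cluster size (quotas={quotas.tolist()}, "
            f"sizes={sizes.tolist()}); is this really the majority class?"
        )
    return SamplingPlan(weights=weights, quotas=quotas, N=int(N), mode="under")


def plan_oversampling(weights, cluster_sizes, N: int) -> SamplingPlan:
    """Minority synthesis quotas s'_i = floor(w'_i * N / 2) - O'_i, floored at 0."""
    weights = np.asarray(weights, dtype=float)
    sizes = np.asarray(cluster_sizes, dtype=int)
    if N < 2:
        raise ValueError("N must be at least 2")
    quotas = np.array(
        [max(0, floor_quota(w * N / 2.0) - int(o)) for w, o in zip(weights, sizes)],
        dtype=int,
    )
    return SamplingPlan(weights=weights, quotas=quotas, N=int(N), mode="over")


def undersample(subset: ClassSubset, plan: SamplingPlan, seed: int = 0) -> np.ndarray:
    """Uniformly retain ``plan.quotas[c]`` rows from each cluster; returns row indices."""
    if plan.mode != "under":
        raise ValueError("undersample requires an under-mode plan")
    if subset.assignments is None or subset.cluster_sizes is None:
        raise ValueError("subset has no cluster assignments")
    if (plan.quotas > subset.cluster_sizes).any():
        raise QuotaError("quota exceeds cluster size")
    rng = np.random.default_rng(int(seed))
    kept: list[np.ndarray] = []
    for c, quota in enumerate(plan.quotas):
        members = np.flatnonzero(subset.assignments == c)
        if quota >= members.size:
            kept.append(members)
        elif quota > 0:
            kept.append(rng.choice(members, size=int(quota), replace=False))
    if not kept:
        return np.empty(0, dtype=int)
    return np.sort(np.concatenate(kept))


def smote_within_cluster(
    points: np.ndarray, n_new: int, k_neighbors: int = 5, seed: int = 0
) -> SmoteResult:
    """SMOTE interpolation restricted to one cluster's points.

    Each synthetic point is x + u (z - x), u ~ Uniform(0, 1), with x a
    uniformly chosen member and z one of x's ``min(k_neighbors, m - 1)``
    nearest Euclidean neighbours in the cluster (self excluded). A lone point
    (m = 1) is copied verbatim.
    """
    points = np.asarray(points, dtype=float)
    m, d = points.shape
    if n_new < 0:
        raise ValueError("n_new must be nonnegative")
    if m < 1:
        raise ValueError("need at least one point")
    rng = np.random.default_rng(int(seed))
    if n_new == 0:
        return SmoteResult(
            np.empty((0, d)), np.empty(0, int), np.empty(0, int), np.empty(0)
        )
    if m == 1:
        zeros = np.zeros(n_new, dtype=int)
        return SmoteResult(
            np.repeat(points, n_new, axis=0), zeros, zeros.copy(), np.zeros(n_new)
        )
    k_eff = min(int(k_neighbors), m - 1)
    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    neighbours = np.argsort(D, axis=1, kind="stable")[:, :k_eff]  # m x k_eff

    base = rng.integers(0, m, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    mate = neighbours[base, pick]
    u = rng.random(n_new)
    synth = points[base] + u[:, None] * (points[mate] - points[base])
    return SmoteResult(points=synth, parent_a=base, parent_b=mate, u=u)


def _cluster_class(
    subset: ClassSubset, config: ResampleConfig, stage: str, notes: list[str]
) -> int:
    """Cluster one class in place (optionally on z-scored features); returns K."""
    X = subset.rows
    if config.scale_features:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    seed = derive_seed(config.seed, stage)
    sel = select_k(X, k_min=config.k_min, k_max=config.k_max, seed=seed,
                   n_init=config.n_init)
    if sel.degenerate or sel.best_k == 1:
        subset.set_assignments(np.zeros(subset.rows.shape[0], dtype=int))
        notes.append(f"{subset.class_role}: too few rows to cluster, K=1")
        return 1
    model = kmeans(X, sel.best_k, seed=seed, n_init=config.n_init)
    subset.set_assignments(model.assignments)
    return sel.best_k


def resample_with_assignments(
    train: LabeledDataset,
    majority: ClassSubset,
    minority: ClassSubset,
    config: ResampleConfig,
    majority_k: int,
    minority_k: int,
    notes: list[str] | None = None,
) -> tuple[BalancedDataset, ResampleReport]:
    """Run the quota/sampling/SMOTE/merge stages on pre-clustered classes.

    Split out from :func:`fit_resample` so worked examples with known cluster
    assignments can exercise the arithmetic directly.
    """
    notes = list(notes or [])
    N = train.n
    maj_w = compute_weights(majority.cluster_sizes, majority.class_total)
    min_w = compute_weights(minority.cluster_sizes, minority.class_total)
    maj_plan = plan_undersampling(maj_w, majority.cluster_sizes, N)
    min_plan = plan_oversampling(min_w, minority.cluster_sizes, N)

    kept = undersample(majority, maj_plan, seed=derive_seed(config.seed, "undersample"))
    maj_rows = majority.rows[kept]

    synth_parts: list[np.ndarray] = []
    if config.smote_pool == "class":
        total_new = int(min_plan.quotas.sum())
        res = smote_within_cluster(
            minority.rows, total_new, config.k_neighbors,
            seed=derive_seed(config.seed, "smote"),
        )
        synth_parts.append(res.points)
    else:
        for c, quota in enumerate(min_plan.quotas):
            members = minority.rows[minority.assignments == c]
            res = smote_within_cluster(
                members, int(quota), config.k_neighbors,
                seed=derive_seed(config.seed, f"smote/{c}"),
            )
            synth_parts.append(res.points)
    synth = np.vstack(synth_parts) if synth_parts else np.empty((0, train.d))

    maj_label = 0 if train.class_counts()[0] >= train.class_counts()[1] else 1
    min_label = 1 - maj_label
    features = np.vstack([maj_rows, minority.rows, synth])
    labels = np.concatenate([
        np.full(maj_rows.shape[0], maj_label),
        np.full(minority.rows.shape[0], min_label),
        np.full(synth.shape[0], min_label),
    ])
    origin = np.concatenate([
        np.full(maj_rows.shape[0], ORIGIN_MAJORITY),
        np.full(minority.rows.shape[0], ORIGIN_MINORITY),
        np.full(synth.shape[0], ORIGIN_SYNTHETIC),
    ])
    balanced = BalancedDataset(
        LabeledDataset(features, labels, list(train.feature_names), train.positive_label),
        origin,
    )
    report = ResampleReport(
        n_train=N,
        majority_k=majority_k,
        minority_k=minority_k,
        majority_cluster_sizes=[int(s) for s in majority.cluster_sizes],
        minority_cluster_sizes=[int(s) for s in minority.cluster_sizes],
        majority_plan=maj_plan,
        minority_plan=min_plan,
        majority_out=int(maj_rows.shape[0]),
        minority_out=int(minority.rows.shape[0] + synth.shape[0]),
        seed=config.seed,
        k_neighbors=config.k_neighbors,
        notes=notes,
    )
    logger.info(
        "resampled N=%d: majority %s -> %d kept, minority %s -> %d total",
        N, report.majority_cluster_sizes, report.majority_out,
        report.minority_cluster_sizes, report.minority_out,
    )
    return balanced, report


def _passthrough(train: LabeledDataset, config: ResampleConfig, note: str,
                 ) -> tuple[BalancedDataset, ResampleReport]:
    n0, n1 = train.class_counts()
    origin = np.where(
        train.labels == (0 if n0 >= n1 else 1), ORIGIN_MAJORITY, ORIGIN_MINORITY
    )
    balanced = BalancedDataset(
        LabeledDataset(train.features.copy(), train.labels.copy(),
                       list(train.feature_names), train.positive_label),
        origin,
    )
    report = ResampleReport(
        n_train=train.n, majority_k=0, minority_k=0,
        majority_cluster_sizes=[], minority_cluster_sizes=[],
        majority_plan=None, minority_plan=None,
        majority_out=max(n0, n1), minority_out=min(n0, n1),
        seed=config.seed, k_neighbors=config.k_neighbors,
        noop=True, notes=[note],
    )
    return balanced, report


def fit_resample(
    train: LabeledDataset, config: ResampleConfig | None = None
) -> tuple[BalancedDataset, ResampleReport]:
    """Full cluster-weighted both-sampling of a training set.

    Pipeline: split classes -> per-class K selection + K-means ->
    cluster weights -> under-sampling plan (majority) and over-sampling plan
    (minority) -> uniform within-cluster retention -> within-cluster SMOTE ->
    merge. Already-balanced input is returned unchanged (flagged no-op), as is
    a degenerate minority of fewer than two rows.
    """
    config = config or ResampleConfig()
    split = split_classes(train)
    if split.tied:
        logger.warning("classes already balanced; resampling is a no-op")
        return _passthrough(train, config, "classes tied 50/50; no-op")
    if split.minority.class_total < 2:
        logger.warning("minority class has <2 rows; passing data through unchanged")
        return _passthrough(train, config, "degenerate minority (<2 rows); pass-through")

    notes: list[str] = []
    maj_k = _cluster_class(split.majority, config, "cluster/majority", notes)
    min_k = _cluster_class(split.minority, config, "cluster/minority", notes)
    return resample_with_assignments(
        train, split.majority, split.minority, config, maj_k, min_k, notes
    )
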