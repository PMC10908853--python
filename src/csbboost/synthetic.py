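"""Synthetic imbalanced datasets with known cluster structure.

Each class is a Gaussian mixture, mirroring the premise that observations
group by similarity and that balancing should respect those groups. The
generator controls the total size n, the imbalance ratio IR (minority size
round(n / (1 + IR))), the per-class components (weight, mean, covariance) and
an optional label-noise fraction, and it returns the ground-truth component
of every row so clustering recovery can be scored.

Two canonical scenarios are provided: a well-separated one (components at
least ~10 sigma apart, so silhouette-based K selection must recover the
generating K) and an overlapping one (minority components sitting inside the
majority mass, the regime where class imbalance actually damages a
classifier). ``case_study_fixture`` reproduces the cluster-size structure of
the worked example: 695 majority rows in clusters of (89, 550, 56) and 55
minority rows in clusters of (44, 11).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = [
    "MixtureComponent",
    "SyntheticSpec",
    "GeneratedData",
    "generate",
    "separated_spec",
    "overlapping_spec",
    "case_study_fixture",
    "CASE_STUDY_MAJORITY_SIZES",
    "CASE_STUDY_MINORITY_SIZES",
]

CASE_STUDY_MAJORITY_SIZES = (89, 550, 56)
CASE_STUDY_MINORITY_SIZES = (44, 11)


@dataclass
class MixtureComponent:
    weight: float
    mean: np.ndarray
    cov: np.ndarray  # full covariance matrix

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 0:
            cov = float(cov) * np.eye(self.mean.size)
        self.cov = cov
        eigvals = np.linalg.eigvalsh(self.cov)
        if (eigvals < -1e-10).any():
            raise ValueError("covariance must be positive semi-definite")


@dataclass
class SyntheticSpec:
    n: int
    imbalance_ratio: float
    majority_clusters: list[MixtureComponent]
    minority_clusters: list[MixtureComponent]
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imbalance_ratio <= 1:
            raise ValueError("imbalance_ratio must exceed 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for comps in (self.majority_clusters, self.minority_clusters):
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("mixing weights per class must sum to 1")
        if self.n_minor < 1:
            raise ValueError("n and imbalance_ratio leave no minority rows")

    @property
    def n_minor(self) -> int:
        return int(round(self.n / (1.0 + self.imbalance_ratio)))

    @property
    def n_major(self) -> int:
        return self.n - self.n_minor

    @property
    def d(self) -> int:
        return self.majority_clusters[0].mean.size


@dataclass
class GeneratedData:
    dataset: LabeledDataset
    components: np.ndarray   # ground-truth component index within each row's class
    noise_mask: np.ndarray   # True where the label was flipped
    spec: SyntheticSpec = field(repr=False, default=None)


def _sample_class(rng, comps, n_class, counts=None):
    if counts is None:
        counts = rng.multinomial(n_class, [c.weight for c in comps])
    rows, comp_ids = [], []
    for j, (comp, m) in enumerate(zip(comps, counts)):
        if m > 0:
            rows.append(rng.multivariate_normal(comp.mean, comp.cov, size=int(m)))
            comp_ids.append(np.full(int(m), j))
    return np.vstack(rows), np.concatenate(comp_ids)


def generate(spec: SyntheticSpec) -> GeneratedData:
    """Draw a dataset from the spec; deterministic for a given seed.

    Rows are shuffled so class and component are not encoded in row order;
    ``label_noise`` flips round(noise * n) uniformly chosen labels.
    """
    rng = np.random.default_rng(int(spec.seed))
    maj_X, maj_c = _sample_class(rng, spec.majority_clusters, spec.n_major)
    min_X, min_c = _sample_class(rng, spec.minority_clusters, spec.n_minor)
    X = np.vstack([maj_X, min_X])
    y = np.concatenate([np.zeros(spec.n_major, int), np.ones(spec.n_minor, int)])
    comps = np.concatenate([maj_c, min_c])

    perm = rng.permutation(spec.n)
    X, y, comps = X[perm], y[perm], comps[perm]

    n_flip = int(round(spec.label_noise * spec.n))
    noise_mask = np.zeros(spec.n, dtype=bool)
    if n_flip:
        flip = rng.choice(spec.n, size=n_flip, replace=False)
        y[flip] = 1 - y[flip]
        noise_mask[flip] = True

    ds = LabeledDataset(X, y, [f"x{j}" for j in range(spec.d)], positive_label=1)
    return GeneratedData(dataset=ds, components=comps, noise_mask=noise_mask, spec=spec)


def _grid_means(k: int, spacing: float, offset: float = 0.0) -> list[np.ndarray]:
    # Lay centroids on a 2-D grid with nearest-neighbour distance `spacing`.
    pts = []
    side = int(np.ceil(np.sqrt(k)))
    for i in range(k):
        pts.append(np.array([(i % side) * spacing + offset,
                             (i // side) * spacing + offset]))
    return pts


def separated_spec(
    n: int,
    imbalance_ratio: float,
    n_major_clusters: int = 3,
    n_minor_clusters: int = 2,
    sigma: float = 1.0,
    separation: float = 12.0,
    label_noise: float = 0.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Well-separated scenario: inter-centroid distance = separation * sigma.

    With the default 12-sigma spacing, silhouette K selection recovers the
    generating component count, so the full pipeline is exercised end to end.
    """
    spacing = separation * sigma
    maj_means = _grid_means(n_major_clusters, spacing)
    # Minority centroids sit on their own grid shifted well above the
    # majority's, so the classes (not just the clusters) are separated — a
    # single axis-aligned threshold tells them apart by construction.
    maj_top = max(m[1] for m in maj_means)
    min_means = [m + np.array([spacing / 2.0, maj_top + 2.0 * spacing])
                 for m in _grid_means(n_minor_clusters, spacing)]
    maj_w = np.linspace(1.0, 2.0, n_major_clusters)
    maj_w /= maj_w.sum()
    min_w = np.linspace(1.0, 2.0, n_minor_clusters)
    min_w /= min_w.sum()
    cov = sigma**2 * np.eye(2)
    return SyntheticSpec(
        n=n,
        imbalance_ratio=imbalance_ratio,
        majority_clusters=[MixtureComponent(w, m, cov) for w, m in zip(maj_w, maj_means)],
        minority_clusters=[MixtureComponent(w, m, cov) for w, m in zip(min_w, min_means)],
        label_noise=label_noise,
        seed=seed,
    )


def overlapping_spec(n: int, imbalance_ratio: float, seed: int = 0) -> SyntheticSpec:
    """Overlapping scenario: minority components inside the majority mass.

    This is the regime where imbalance hurts — with fully separated classes
    any classifier is perfect regardless of class ratio. The minority means
    sit roughly 1-2 component standard deviations from the nearest majority
    mean, giving substantial class overlap at the decision boundary.
    """
    maj_cov = 1.8**2 * np.eye(2)
    min_cov = 1.2**2 * np.eye(2)
    return SyntheticSpec(
        n=n,
        imbalance_ratio=imbalance_ratio,
        majority_clusters=[
            MixtureComponent(0.5, np.array([0.0, 0.0]), maj_cov),
            MixtureComponent(0.3, np.array([6.0, 0.0]), maj_cov),
            MixtureComponent(0.2, np.array([0.0, 6.0]), maj_cov),
        ],
        minority_clusters=[
            MixtureComponent(0.7, np.array([2.0, 2.0]), min_cov),
            MixtureComponent(0.3, np.array([6.0, 3.0]), min_cov),
        ],
        seed=seed,
    )


def case_study_fixture(seed: int = 0) -> GeneratedData:
    """A 750-row training set shaped like the worked clinical example.

    Majority: 695 rows in three clusters of exactly (89, 550, 56); minority:
    55 rows in two clusters of exactly (44, 11). Cluster centres are >= 10
    component standard deviations apart, so silhouette K selection recovers
    K = 3 and K = 2 and the cluster weights truncate to (0.128, 0.791, 0.080)
    and (0.8, 0.2).
    """
    rng = np.random.default_rng(int(seed))
    sigma = 1.0
    maj_means = [np.array([0.0, 0.0]), np.array([30.0, 0.0]), np.array([0.0, 30.0])]
    min_means = [np.array([15.0, 15.0]), np.array([45.0, 45.0])]
    cov = sigma**2 * np.eye(2)

    maj_comps = [MixtureComponent(m / 695.0, mu, cov)
                 for m, mu in zip(CASE_STUDY_MAJORITY_SIZES, maj_means)]
    min_comps = [MixtureComponent(m / 55.0, mu, cov)
                 for m, mu in zip(CASE_STUDY_MINORITY_SIZES, min_means)]
    maj_X, maj_c = _sample_class(rng, maj_comps, 695,
                                 counts=np.array(CASE_STUDY_MAJORITY_SIZES))
    min_X, min_c = _sample_class(rng, min_comps, 55,
                                 counts=np.array(CASE_STUDY_MINORITY_SIZES))
    X = np.vstack([maj_X, min_X])
    y = np.concatenate([np.zeros(695, int), np.ones(55, int)])
    comps = np.concatenate([maj_c, min_c])
    perm = rng.permutation(750)
    ds = LabeledDataset(X[perm], y[perm], ["x0", "x1"], positive_label=1)
    spec = SyntheticSpec(
        n=750, imbalance_ratio=695 / 55.0,
        majority_clusters=maj_comps, minority_clusters=min_comps, seed=seed,
    )
    return GeneratedData(dataset=ds, components=comps[perm],
                         noise_mask=np.zeros(750, bool), spec=spec)
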