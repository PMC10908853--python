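"""Dataset model and I/O: labelled tabular data, CSV and KEEL readers, splits.

The central container is :class:`LabeledDataset`: an ``n x d`` float feature
matrix with binary labels where 1 marks the positive (minority, event of
interest) class. Readers map the original label values onto {0, 1} and record
the mapping; rows with missing or unparseable cells are dropped and counted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDataset",
    "SplitPair",
    "DatasetError",
    "MissingLabelColumnError",
    "TooManyLabelsError",
    "EmptyDatasetError",
    "MalformedKeelError",
    "read_csv_dataset",
    "read_keel_dataset",
    "write_csv_dataset",
    "train_test_split",
]


class DatasetError(ValueError):
    """Base class for dataset loading/validation failures."""


class MissingLabelColumnError(DatasetError):
    pass


class TooManyLabelsError(DatasetError):
    pass


class EmptyDatasetError(DatasetError):
    pass


class MalformedKeelError(DatasetError):
    pass


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels (1 = positive/minority by convention)."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    positive_label: object = 1
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise DatasetError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise EmptyDatasetError("dataset needs at least one row and one column")
        if self.labels.shape[0] != n:
            raise DatasetError("labels length does not match feature rows")
        values = set(np.unique(self.labels).tolist())
        if not values <= {0, 1}:
            raise DatasetError(f"labels must be binary 0/1, got {sorted(values)}")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise DatasetError("feature_names length does not match columns")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def is_degenerate(self) -> bool:
        """True when only one class is present."""
        return np.unique(self.labels).size < 2

    def class_counts(self) -> tuple[int, int]:
        """(count of label 0, count of label 1)."""
        ones = int(self.labels.sum())
        return self.n - ones, ones

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[index],
            self.labels[index],
            list(self.feature_names),
            self.positive_label,
        )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels
        return df


@dataclass
class SplitPair:
    """A train/test partition of one dataset (disjoint rows, exhaustive)."""

    train: LabeledDataset
    test: LabeledDataset
    seed: int
    test_fraction: float


def _map_labels(raw: pd.Series, positive_label) -> tuple[np.ndarray, object]:
    values = pd.unique(raw)
    if len(values) > 2:
        raise TooManyLabelsError(
            f"label column has {len(values)} distinct values; at most two allowed"
        )
    if positive_label is None:
        # Default: minority class is positive; ties broken lexicographically.
        counts = raw.value_counts()
        low = counts.min()
        candidates = sorted(str(v) for v, c in counts.items() if c == low)
        positive_label = next(v for v in counts.index if str(v) == candidates[0])
    elif positive_label not in set(values):
        raise DatasetError(f"positive_label {positive_label!r} not present in labels")
    labels = (raw == positive_label).to_numpy().astype(int)
    return labels, positive_label


def read_csv_dataset(
    path,
    label_column: str,
    positive_label=None,
    delimiter: str = ",",
) -> LabeledDataset:
    """Read a header-rowed CSV into a :class:`LabeledDataset`.

    Non-numeric or missing feature cells cause the whole row to be dropped
    (and counted in ``n_dropped``); the label column keeps its raw values
    until they are mapped onto {0, 1} via ``positive_label``.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    if df.shape[0] == 0:
        raise EmptyDatasetError(f"{path}: no data rows")
    if label_column not in df.columns:
        raise MissingLabelColumnError(
            f"{path}: label column {label_column!r} not found in {list(df.columns)}"
        )
    raw_labels = df[label_column]
    feats = df.drop(columns=[label_column]).apply(pd.to_numeric, errors="coerce")
    keep = feats.notna().all(axis=1) & raw_labels.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing/unparseable cells", path, n_dropped)
    feats, raw_labels = feats[keep], raw_labels[keep]
    if feats.shape[0] == 0:
        raise EmptyDatasetError(f"{path}: all rows dropped")
    labels, positive_label = _map_labels(raw_labels, positive_label)
    ds = LabeledDataset(
        feats.to_numpy(float), labels, list(feats.columns), positive_label
    )
    ds.n_dropped = n_dropped
    return ds


def write_csv_dataset(ds: LabeledDataset, path, label_column: str = "label") -> None:
    ds.to_dataframe(label_column).to_csv(path, index=False)


_KEEL_ATTR = re.compile(
    r"@attribute\s+(?P<name>[\w.\-]+)\s*(?P<spec>\{.*\}|\w+.*)", re.IGNORECASE
)


def read_keel_dataset(path) -> LabeledDataset:
    """Read a KEEL ``.dat`` file (@relation/@attribute/@data dialect).

    Nominal attributes are integer-coded in declaration order; the class
    attribute is the one named by ``@outputs`` (or the last declared), and the
    class with fewer instances maps to label 1.
    """
    names: list[str] = []
    nominal: dict[str, list[str]] = {}
    outputs: str | None = None
    data_lines: list[str] = []
    in_data = False
    saw_relation = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if in_data:
                data_lines.append(line)
                continue
            low = line.lower()
            if low.startswith("@relation"):
                saw_relation = True
            elif low.startswith("@attribute"):
                m = _KEEL_ATTR.match(line)
                if not m:
                    raise MalformedKeelError(f"{path}: bad attribute line {line!r}")
                name, spec = m.group("name"), m.group("spec").strip()
                names.append(name)
                if spec.startswith("{"):
                    cats = [c.strip() for c in spec.strip("{}").split(",")]
                    nominal[name] = cats
                elif re.match(r"(real|integer|numeric)\b", spec, re.IGNORECASE):
                    pass
                else:
                    raise MalformedKeelError(
                        f"{path}: unknown attribute type in {line!r}"
                    )
            elif low.startswith("@outputs"):
                outputs = line.split(None, 1)[1].strip().rstrip(",")
            elif low.startswith("@inputs"):
                pass
            elif low.startswith("@data"):
                in_data = True
    if not saw_relation or not in_data:
        raise MalformedKeelError(f"{path}: missing @relation or @data section")
    if not names or not data_lines:
        raise MalformedKeelError(f"{path}: no attributes or no data records")
    class_attr = outputs if outputs is not None else names[-1]
    if class_attr not in names:
        raise MalformedKeelError(f"{path}: @outputs names unknown attribute {class_attr!r}")

    records = [[c.strip() for c in ln.split(",")] for ln in data_lines]
    df = pd.DataFrame(records, columns=names)
    for name in names:
        if name in nominal and name != class_attr:
            codes = {c: i for i, c in enumerate(nominal[name])}
            df[name] = df[name].map(codes)
        elif name != class_attr:
            df[name] = pd.to_numeric(df[name], errors="coerce")
    raw_labels = df[class_attr]
    feats = df.drop(columns=[class_attr])
    keep = feats.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    feats, raw_labels = feats[keep], raw_labels[keep]
    if feats.shape[0] == 0:
        raise EmptyDatasetError(f"{path}: all rows dropped")
    labels, positive = _map_labels(raw_labels, None)
    ds = LabeledDataset(feats.to_numpy(float), labels, list(feats.columns), positive)
    ds.n_dropped = n_dropped
    return ds


def train_test_split(
    ds: LabeledDataset,
    test_fraction: float = 0.25,
    seed: int = 0,
    stratified: bool = False,
) -> SplitPair:
    """Uniform random train/test partition (optionally class-stratified).

    The paper's evaluation protocol holds out 25% of rows at random for
    testing; stratification (per-class fractions within one observation of
    ``test_fraction``) is available but off by default.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DatasetError("test_fraction must lie in (0, 1)")
    if ds.n < 2:
        raise DatasetError("need at least two rows to split")
    n_test = int(round(ds.n * test_fraction))
    if n_test == 0 or n_test == ds.n:
        raise DatasetError(
            f"test_fraction={test_fraction} leaves an empty train or test set (n={ds.n})"
        )
    idx = np.arange(ds.n)
    stratify = ds.labels if stratified else None
    train_idx, test_idx = _sk_split(
        idx, test_size=n_test, random_state=int(seed) % 2**31, stratify=stratify
    )
    return SplitPair(ds.subset(train_idx), ds.subset(test_idx), seed, test_fraction)
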