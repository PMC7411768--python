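"""Initial solution space: mean-threshold binarization and population seeding.

The selector starts by turning the raw table into a 0/1 matrix: every
numeric cell becomes 1 when its value is at least the (rounded) column
mean, every categorical cell becomes 1 when it equals the modal token.
Per-attribute counts of 1 entries then act as a crude relevance score: the
attribute with the fewest 1s is eliminated before the genetic search
begins, and the same counting rule ranks attributes at the end of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import TabularDataset

__all__ = [
    "BinarizationSpec",
    "BinaryMatrix",
    "OnesCountTable",
    "Population",
    "column_means",
    "binarize",
    "ones_count",
    "drop_min_count",
    "min_count_attribute",
    "initial_population",
    "rank_attributes",
]


def _is_integer_column(values: np.ndarray) -> bool:
    v = values[~np.isnan(values)]
    return bool(len(v)) and bool(np.all(v == np.round(v)))


def column_means(ds: TabularDataset, rounding: str = "auto") -> dict[str, float]:
    """Per-numeric-attribute mean over non-missing cells.

    With ``rounding="auto"`` (the default) integer-valued columns are
    rounded to the nearest integer and real-valued columns to one decimal,
    mirroring how such tables are conventionally printed; ``"none"``
    returns raw means.  Ties round half-to-even (numpy convention).
    """
    means: dict[str, float] = {}
    for a in ds.schema:
        if a.kind != "numeric":
            continue
        col = ds.X[a.name].to_numpy(dtype=float)
        valid = col[~np.isnan(col)]
        if not len(valid):
            raise ValueError(f"column {a.name!r} has no non-missing values")
        m = float(valid.mean())
        if rounding == "auto":
            m = float(np.round(m)) if _is_integer_column(col) else float(np.round(m, 1))
        elif rounding != "none":
            raise ValueError(f"unknown rounding mode {rounding!r}")
        means[a.name] = m
    return means


@dataclass
class BinarizationSpec:
    """Thresholds (numeric) and positive tokens (categorical), one per attribute."""

    thresholds: dict[str, float] = field(default_factory=dict)
    categorical_positive: dict[str, str] = field(default_factory=dict)
    rounding: str = "auto"  # "auto" | "none"
    missing_as: str = "zero"  # "zero" | "mean"

    @classmethod
    def from_dataset(
        cls, ds: TabularDataset, rounding: str = "auto", missing_as: str = "zero"
    ) -> "BinarizationSpec":
        """Derive thresholds from column means and positive tokens from modes."""
        thresholds = column_means(ds, rounding=rounding)
        cat = {}
        for a in ds.schema:
            if a.kind == "categorical":
                col = ds.X[a.name].dropna()
                if len(col):
                    cat[a.name] = col.mode().iloc[0]  # highest occurrence rate -> 1
                else:
                    cat[a.name] = a.positive_token
        return cls(thresholds=thresholds, categorical_positive=cat, rounding=rounding,
                   missing_as=missing_as)

    def covers(self, ds: TabularDataset) -> bool:
        return all(
            (a.name in self.thresholds) if a.kind == "numeric"
            else (a.name in self.categorical_positive)
            for a in ds.schema
        )


@dataclass
class BinaryMatrix:
    """0/1 matrix (rows x attributes) with its column names."""

    values: np.ndarray
    attribute_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.attribute_names):
            raise ValueError("matrix shape must be (rows, attributes)")
        if len(self.values) and not np.isin(self.values, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.attribute_names)


@dataclass
class OnesCountTable:
    """Per-attribute count of 1 entries in a binary matrix."""

    attribute_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.attribute_names):
            raise ValueError("one count per attribute required")
        if len(self.counts) and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    def __getitem__(self, name: str) -> int:
        return int(self.counts[self.attribute_names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.counts], columns=self.attribute_names,
                            index=["ones_count"])


def binarize(ds: TabularDataset, spec: BinarizationSpec) -> BinaryMatrix:
    """Apply the >= threshold rule (numeric) / positive-token rule (categorical).

    Missing cells map to 0 under the default policy (absence of evidence of
    the symptom), or to the thresholded column mean under ``missing_as="mean"``.
    """
    if not spec.covers(ds):
        raise ValueError("binarization spec does not cover every attribute")
    cols = []
    for a in ds.schema:
        if a.kind == "numeric":
            v = ds.X[a.name].to_numpy(dtype=float)
            th = spec.thresholds[a.name]
            if spec.missing_as == "mean":
                col_mean = np.nanmean(v) if np.isfinite(v).any() else 0.0
                v = np.where(np.isnan(v), col_mean, v)
                bits = (v >= th).astype(np.int8)
            else:
                bits = np.where(np.isnan(v), 0, (v >= th)).astype(np.int8)
        else:
            pos = spec.categorical_positive[a.name]
            raw = ds.X[a.name]
            known = set(raw.dropna().unique())
            if known - ({pos} | known):  # pragma: no cover - defensive
                raise ValueError("unknown categorical token")
            bits = np.where(raw.isna(), 0, (raw == pos)).astype(np.int8)
        cols.append(bits)
    values = np.column_stack(cols) if cols else np.empty((ds.n_rows, 0), dtype=np.int8)
    return BinaryMatrix(values=values, attribute_names=ds.attribute_names)


def ones_count(bm: BinaryMatrix) -> OnesCountTable:
    """Column sums of a binary matrix."""
    return OnesCountTable(
        attribute_names=list(bm.attribute_names),
        counts=bm.values.sum(axis=0) if len(bm.values) else
        np.zeros(len(bm.attribute_names), dtype=int),
    )


def min_count_attribute(counts: OnesCountTable) -> str:
    """The attribute attaining the minimum count (leftmost under ties)."""
    return counts.attribute_names[int(np.argmin(counts.counts))]


def drop_min_count(schema: list[str], counts: OnesCountTable) -> list[str]:
    """Eliminate the single least-count attribute, preserving order.

    Ties go to the leftmost column.  Refuses to drop from a single-attribute
    schema: selection must always retain at least one attribute.
    """
    if len(schema) < 2:
        raise ValueError("cannot drop from a schema with fewer than 2 attributes")
    if set(schema) != set(counts.attribute_names):
        raise ValueError("schema and count table name different attributes")
    loser = min_count_attribute(counts)
    return [name for name in schema if name != loser]


@dataclass
class Population:
    """Fixed-length 0/1 chromosome set; bit j set means attribute j included."""

    chromosomes: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=np.int8)
        if self.chromosomes.ndim != 2:
            raise ValueError("population must be a 2-D bit matrix")
        if (self.chromosomes.sum(axis=1) == 0).any():
            raise ValueError("all-zero chromosomes are not admissible")

    @property
    def size(self) -> int:
        return len(self.chromosomes)

    @property
    def n_bits(self) -> int:
        return self.chromosomes.shape[1]


def initial_population(n_attrs: int, pop_size: int, seed: int) -> Population:
    """Draw pop_size distinct non-zero bitstrings uniformly without replacement."""
    if n_attrs < 1:
        raise ValueError("need at least one attribute")
    if not 1 <= pop_size <= 2 ** n_attrs - 1:
        raise ValueError(
            f"pop_size must lie in [1, 2^{n_attrs} - 1] = [1, {2 ** n_attrs - 1}]"
        )
    rng = np.random.default_rng(seed)
    seen: set[bytes] = set()
    rows = []
    while len(rows) < pop_size:
        bits = rng.integers(0, 2, size=n_attrs, dtype=np.int8)
        if not bits.any():
            continue
        key = bits.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rows.append(bits)
    return Population(chromosomes=np.array(rows, dtype=np.int8), seed=seed)


def rank_attributes(counts: OnesCountTable) -> dict[str, int]:
    """Rank attributes by descending 1's count; rank 1 is best.

    Ties are broken by attribute (column) order, so the ranks are always a
    permutation of 1..m.
    """
    m = len(counts.attribute_names)
    order = sorted(range(m), key=lambda j: (-int(counts.counts[j]), j))
    ranks = {}
    for pos, j in enumerate(order, start=1):
        ranks[counts.attribute_names[j]] = pos
    return ranks
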