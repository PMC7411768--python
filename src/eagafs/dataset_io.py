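"""Tabular dataset I/O: ARFF/CSV reading and writing, schemas, splits and folds.

The package works on small clinical tables: a handful of numeric or
categorical attributes plus a binary class label (disease present / absent).
Datasets are carried around as a :class:`TabularDataset`, a thin wrapper
over a :class:`pandas.DataFrame` plus an ordered attribute schema and a 0/1
label vector.  ARFF (the WEKA dialect: ``@relation`` / ``@attribute`` /
``@data``, ``?`` as the missing marker) and headered CSV are supported in
both directions and round-trip losslessly.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import arff as _scipy_arff

logger = logging.getLogger(__name__)

MISSING_TOKEN = "?"

__all__ = [
    "AttributeSpec",
    "TabularDataset",
    "SplitPlan",
    "FoldPlan",
    "ArffFormatError",
    "SchemaError",
    "read_arff",
    "write_arff",
    "read_csv",
    "write_csv",
    "split_train_test",
    "make_folds",
]


class ArffFormatError(ValueError):
    """Raised when an ARFF file cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a dataset's schema violates the binary-class contract."""


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of the schema.

    ``positive_token`` is the categorical value coded as "disease present";
    it is empty exactly for numeric attributes.  ``missing_count`` records
    how many cells of the source file carried the missing marker.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    positive_token: str = ""
    missing_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if (self.kind == "numeric") != (self.positive_token == ""):
            raise SchemaError(
                f"attribute {self.name!r}: positive_token must be empty "
                "iff the attribute is numeric"
            )


@dataclass
class TabularDataset:
    """Attribute schema + row-major values + binary class labels.

    Numeric columns are float64 with NaN for missing cells; categorical
    columns hold string tokens with NaN for missing.  ``labels`` is a 0/1
    integer vector aligned with the rows.  ``rejected_rows`` counts input
    rows dropped during reading (e.g. missing class label), so that
    rows_in_file == n_rows + rejected_rows.
    """

    schema: list[AttributeSpec]
    X: pd.DataFrame
    labels: np.ndarray
    relation: str = "dataset"
    class_name: str = "class"
    class_tokens: tuple[str, str] = ("0", "1")
    rejected_rows: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        names = [a.name for a in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("attribute names must be unique")
        if list(self.X.columns) != names:
            raise SchemaError("column order must match schema order")
        if len(self.X) != len(self.labels):
            raise SchemaError("row count must equal label count")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise SchemaError("labels must take only values 0 and 1")

    # -- conveniences -----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_attributes(self) -> int:
        return len(self.schema)

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.schema]

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.schema:
            if a.name == name:
                return a
        raise KeyError(name)

    def select_attributes(self, names: list[str]) -> "TabularDataset":
        """Project onto a subset of attributes, preserving schema order."""
        keep = [a for a in self.schema if a.name in set(names)]
        if not keep:
            raise ValueError("attribute subset must be non-empty")
        return TabularDataset(
            schema=keep,
            X=self.X[[a.name for a in keep]].copy(),
            labels=self.labels.copy(),
            relation=self.relation,
            class_name=self.class_name,
            class_tokens=self.class_tokens,
        )

    def equals(self, other: "TabularDataset") -> bool:
        if self.schema != other.schema:
            return False
        if not np.array_equal(self.labels, other.labels):
            return False
        if self.X.shape != other.X.shape:
            return False
        for col in self.X.columns:
            a, b = self.X[col].to_numpy(), other.X[col].to_numpy()
            if self.attribute(col).kind == "numeric":
                if not np.array_equal(a.astype(float), b.astype(float), equal_nan=True):
                    return False
            else:
                am, bm = pd.isna(a), pd.isna(b)
                if not np.array_equal(am, bm) or not np.array_equal(a[~am], b[~bm]):
                    return False
        return True


@dataclass(frozen=True)
class SplitPlan:
    """A train/test partition of row indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class FoldPlan:
    """A k-way partition of row indices for cross-validation."""

    folds: list[np.ndarray]
    k: int
    seed: int


# ---------------------------------------------------------------------------
# ARFF
# ---------------------------------------------------------------------------

def read_arff(path, class_mapping: dict[str, int] | None = None) -> TabularDataset:
    """Read a WEKA-dialect ARFF file with a two-valued nominal class last.

    The class attribute (the last declared attribute) is removed from the
    schema and stored as the 0/1 label vector; by default its first declared
    value maps to 0 and the second to 1.  ``?`` cells are counted into each
    attribute's ``missing_count``.  Rows whose class cell is missing are
    rejected (and counted in ``rejected_rows``).
    """
    try:
        data, meta = _scipy_arff.loadarff(str(path))
    except Exception as err:  # scipy raises ParseArffError naming the line
        raise ArffFormatError(f"{path}: {err}") from err

    names = list(meta.names())
    if len(names) < 2:
        raise SchemaError(f"{path}: need at least one attribute plus a class")
    class_attr = names[-1]
    ctype, cvalues = meta[class_attr]
    if ctype != "nominal" or len(cvalues) != 2:
        raise SchemaError(
            f"{path}: class attribute {class_attr!r} must be nominal with "
            f"exactly 2 values, got {ctype} {tuple(cvalues)}"
        )
    if class_mapping is None:
        class_mapping = {cvalues[0]: 0, cvalues[1]: 1}

    n = len(data)
    raw_class = np.array(
        [data[class_attr][i].decode() if n else "" for i in range(n)], dtype=object
    )
    keep = raw_class != MISSING_TOKEN
    rejected = int((~keep).sum())

    schema: list[AttributeSpec] = []
    columns: dict[str, np.ndarray] = {}
    for name in names[:-1]:
        atype, avalues = meta[name]
        if atype == "numeric":
            col = np.asarray(data[name], dtype=float)[keep] if n else np.empty(0)
            missing = int(np.isnan(col).sum())
            schema.append(AttributeSpec(name, "numeric", "", missing))
            columns[name] = col
        else:
            toks = np.array(
                [data[name][i].decode() for i in range(n)], dtype=object
            )[keep] if n else np.empty(0, dtype=object)
            missing = int((toks == MISSING_TOKEN).sum())
            col = toks.copy()
            col[toks == MISSING_TOKEN] = np.nan
            # positive token defaults to the last declared nominal value
            schema.append(AttributeSpec(name, "categorical", avalues[-1], missing))
            columns[name] = col

    labels = np.array([class_mapping[t] for t in raw_class[keep]], dtype=int)
    tokens = sorted(class_mapping, key=class_mapping.get)
    return TabularDataset(
        schema=schema,
        X=pd.DataFrame(columns, columns=[a.name for a in schema]),
        labels=labels,
        relation=meta.name or "dataset",
        class_name=class_attr,
        class_tokens=(tokens[0], tokens[-1]),
        rejected_rows=rejected,
    )


def _fmt_num(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return MISSING_TOKEN
    f = float(v)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def write_arff(ds: TabularDataset, path) -> None:
    """Serialize losslessly to WEKA-dialect ARFF (round-trips via read_arff)."""
    buf = io.StringIO()
    buf.write(f"@relation {ds.relation}\n\n")
    for a in ds.schema:
        if a.kind == "numeric":
            buf.write(f"@attribute {a.name} numeric\n")
        else:
            col = ds.X[a.name]
            toks = sorted({str(t) for t in col.dropna()} | {a.positive_token})
            buf.write(f"@attribute {a.name} {{{','.join(toks)}}}\n")
    buf.write(f"@attribute {ds.class_name} {{{ds.class_tokens[0]},{ds.class_tokens[1]}}}\n")
    buf.write("\n@data\n")
    for i in range(ds.n_rows):
        cells = []
        for a in ds.schema:
            v = ds.X.iloc[i][a.name]
            if a.kind == "numeric":
                cells.append(_fmt_num(v))
            else:
                cells.append(MISSING_TOKEN if pd.isna(v) else str(v))
        cells.append(ds.class_tokens[int(ds.labels[i])])
        buf.write(",".join(cells) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv(
    path,
    class_column: str = "class",
    class_mapping: dict[str, int] | None = None,
) -> TabularDataset:
    """Read a headered CSV with a two-valued class column.

    Columns whose non-missing cells all parse as numbers are numeric;
    anything else is categorical.  Without an explicit mapping the
    lexicographically larger class token maps to 1.  Empty cells and ``?``
    are treated as missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if class_column not in df.columns:
        raise SchemaError(f"{path}: class column {class_column!r} not found")

    df = df.replace({"": None, MISSING_TOKEN: None})
    raw_class = df[class_column]
    keep = raw_class.notna()
    rejected = int((~keep).sum())
    df = df.loc[keep]
    raw_class = raw_class.loc[keep]

    tokens = sorted(raw_class.unique())
    if class_mapping is None:
        if len(tokens) != 2:
            raise SchemaError(
                f"{path}: class column must have exactly two distinct values, "
                f"got {tokens}"
            )
        class_mapping = {tokens[0]: 0, tokens[1]: 1}
    unmapped = set(tokens) - set(class_mapping)
    if unmapped:
        raise SchemaError(f"{path}: unmappable class values {sorted(unmapped)}")
    labels = raw_class.map(class_mapping).to_numpy(dtype=int)

    schema: list[AttributeSpec] = []
    columns: dict[str, np.ndarray] = {}
    for name in df.columns:
        if name == class_column:
            continue
        col = df[name]
        missing = int(col.isna().sum())
        numeric = pd.to_numeric(col, errors="coerce")
        if (numeric.notna() | col.isna()).all():
            schema.append(AttributeSpec(name, "numeric", "", missing))
            columns[name] = numeric.to_numpy(dtype=float)
        else:
            toks = sorted(col.dropna().unique())
            schema.append(AttributeSpec(name, "categorical", toks[-1], missing))
            columns[name] = col.to_numpy(dtype=object)

    order = sorted(class_mapping, key=class_mapping.get)
    return TabularDataset(
        schema=schema,
        X=pd.DataFrame(columns, columns=[a.name for a in schema]).reset_index(drop=True),
        labels=labels,
        class_name=class_column,
        class_tokens=(str(order[0]), str(order[-1])),
        rejected_rows=rejected,
    )


def write_csv(ds: TabularDataset, path) -> None:
    """Serialize to comma-separated UTF-8 with header (round-trips via read_csv)."""
    out = pd.DataFrame(index=range(ds.n_rows))
    for a in ds.schema:
        if a.kind == "numeric":
            out[a.name] = [_fmt_num(v).replace(MISSING_TOKEN, "") for v in ds.X[a.name]]
        else:
            out[a.name] = ["" if pd.isna(v) else str(v) for v in ds.X[a.name]]
    out[ds.class_name] = [ds.class_tokens[int(v)] for v in ds.labels]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splits and folds
# ---------------------------------------------------------------------------

def split_train_test(
    ds: TabularDataset,
    fraction: float = 0.6,
    seed: int = 0,
    stratify: bool = True,
) -> SplitPlan:
    """Partition rows into a train share of round(fraction * n) and the rest.

    Stratified by class by default (per-class counts allocated by largest
    remainder so the total is exact); falls back to an unstratified shuffle
    with a warning when a class has fewer than 2 members.
    """
    n = ds.n_rows
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    counts = np.bincount(ds.labels, minlength=2)
    if stratify and counts.min() < 2:
        warnings.warn(
            "stratified split requested but a class has <2 members; "
            "falling back to unstratified",
            stacklevel=2,
        )
        stratify = False

    if not stratify:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    else:
        targets = {c: fraction * counts[c] for c in (0, 1) if counts[c]}
        base = {c: int(math.floor(t)) for c, t in targets.items()}
        short = n_train - sum(base.values())
        order = sorted(targets, key=lambda c: targets[c] - base[c], reverse=True)
        for c in order:
            if short <= 0:
                break
            if base[c] < counts[c]:
                base[c] += 1
                short -= 1
        train_parts = []
        test_parts = []
        for c, take in base.items():
            idx = np.flatnonzero(ds.labels == c)
            perm = rng.permutation(idx)
            train_parts.append(perm[:take])
            test_parts.append(perm[take:])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
    return SplitPlan(train_indices=train, test_indices=test, seed=seed, fraction=fraction)


def make_folds(ds: TabularDataset, k: int, seed: int = 0) -> FoldPlan:
    """Shuffle rows and cut them into k folds whose sizes differ by at most 1."""
    n = ds.n_rows
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    return FoldPlan(folds=folds, k=k, seed=seed)
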