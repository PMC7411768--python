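"""Wrapper fitness: score a chromosome by held-out classifier error.

A chromosome (0/1 attribute mask) is scored by training a classifier on
the selected columns and measuring its misprediction rate MPR = 1 -
accuracy on a held-out share, plus a penalty proportional to the number of
excluded attributes z:

    fn(x) = MPR + ff * z / n        (normalized, default)
    fn(x) = MPR + ff * z            (raw, opt-in)

Lower fn is better; rank 1 is the best chromosome of a population.  The
penalty direction means the selector prefers *larger* subsets at equal
error: dropping an attribute must pay for itself through accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Perceptron
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .dataset_io import TabularDataset, split_train_test

__all__ = [
    "FitnessConfig",
    "FitnessRecord",
    "subset_dataset",
    "design_matrix",
    "misprediction_rate",
    "fitness",
    "rank_population",
    "WrapperEvaluator",
    "StubEvaluator",
]


@dataclass
class FitnessConfig:
    """Knobs of the fitness function.

    ``classifier_factory`` returns a fresh sklearn-style estimator per
    evaluation; the default is a standardized few-epoch perceptron — a fast
    surrogate, since wrapper selection cost is dominated by fitness calls.
    ``eval_protocol`` is ``"holdout"`` (seeded stratified split with
    ``train_fraction``) or ``"resubstitution"`` (train and score on all rows).
    """

    ff: float = 0.5  # fitness factor weighting the zero-count penalty
    normalize_z: bool = True
    classifier_factory: Callable | None = None
    eval_seed: int = 0
    train_fraction: float = 0.6
    eval_protocol: str = "holdout"

    def __post_init__(self) -> None:
        if self.ff < 0:
            raise ValueError("fitness factor ff must be non-negative")

    def make_classifier(self):
        if self.classifier_factory is not None:
            return self.classifier_factory()
        return make_pipeline(
            StandardScaler(),
            Perceptron(max_iter=10, tol=None, random_state=self.eval_seed),
        )


@dataclass(frozen=True)
class FitnessRecord:
    """One scored chromosome: error, zero count, combined fitness, rank."""

    chromosome: tuple[int, ...]
    mpr: float
    z: int
    fn: float
    rank: int = 0


def _as_bits(chromosome: Sequence[int]) -> np.ndarray:
    bits = np.asarray(chromosome, dtype=np.int8)
    if bits.ndim != 1 or (len(bits) and not np.isin(bits, (0, 1)).all()):
        raise ValueError("chromosome must be a flat 0/1 vector")
    return bits


def subset_dataset(ds: TabularDataset, chromosome: Sequence[int]) -> TabularDataset:
    """Project the dataset onto the attributes at set bits (original order)."""
    bits = _as_bits(chromosome)
    if len(bits) != ds.n_attributes:
        raise ValueError(
            f"chromosome length {len(bits)} != attribute count {ds.n_attributes}"
        )
    if not bits.any():
        raise ValueError("all-zero chromosome selects an empty attribute subset")
    names = [a.name for a, b in zip(ds.schema, bits) if b]
    return ds.select_attributes(names)


def design_matrix(ds: TabularDataset) -> np.ndarray:
    """Numeric matrix for classifier input.

    Numeric columns keep their values with missing cells mean-imputed
    (all-missing columns become 0); categorical columns become a 0/1
    indicator of the schema's positive token, with missing as 0.
    """
    cols = []
    for a in ds.schema:
        if a.kind == "numeric":
            v = ds.X[a.name].to_numpy(dtype=float)
            if np.isnan(v).any():
                fill = np.nanmean(v) if np.isfinite(v).any() else 0.0
                v = np.where(np.isnan(v), fill, v)
            cols.append(v)
        else:
            raw = ds.X[a.name]
            cols.append(np.where(raw.isna(), 0, (raw == a.positive_token)).astype(float))
    return np.column_stack(cols) if cols else np.empty((ds.n_rows, 0))


def misprediction_rate(
    ds: TabularDataset, chromosome: Sequence[int], cfg: FitnessConfig
) -> float:
    """1 - accuracy of the configured classifier on the chromosome's subset."""
    sub = subset_dataset(ds, chromosome)
    X = design_matrix(sub)
    y = sub.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to evaluate fitness")
    clf = cfg.make_classifier()
    if cfg.eval_protocol == "resubstitution":
        clf.fit(X, y)
        acc = float(np.mean(clf.predict(X) == y))
    elif cfg.eval_protocol == "holdout":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = split_train_test(sub, cfg.train_fraction, seed=cfg.eval_seed)
        tr, te = plan.train_indices, plan.test_indices
        try:
            clf.fit(X[tr], y[tr])
        except Exception as err:
            raise RuntimeError(
                f"classifier training failed for chromosome "
                f"{tuple(int(b) for b in chromosome)}: {err}"
            ) from err
        acc = float(np.mean(clf.predict(X[te]) == y[te]))
    else:
        raise ValueError(f"unknown eval protocol {cfg.eval_protocol!r}")
    return 1.0 - acc


def fitness(
    ds: TabularDataset, chromosome: Sequence[int], cfg: FitnessConfig
) -> FitnessRecord:
    """Full fitness record: MPR plus the zero-count penalty."""
    bits = _as_bits(chromosome)
    mpr = misprediction_rate(ds, bits, cfg)
    z = int((bits == 0).sum())
    penalty = cfg.ff * (z / len(bits) if cfg.normalize_z else z)
    return FitnessRecord(
        chromosome=tuple(int(b) for b in bits), mpr=mpr, z=z, fn=mpr + penalty
    )


def rank_population(records: Sequence[FitnessRecord]) -> list[FitnessRecord]:
    """Sort ascending by fn (lower fitness = higher priority) and assign ranks.

    Ties break by fewer zeros, then by bit-vector lexicographic order, so
    the ranking is a deterministic bijection onto 1..P.
    """
    if not records:
        raise ValueError("cannot rank an empty population")
    ordered = sorted(records, key=lambda r: (r.fn, r.z, r.chromosome))
    return [replace(r, rank=i) for i, r in enumerate(ordered, start=1)]


class WrapperEvaluator:
    """Chromosome -> FitnessRecord, memoized.

    The wrapper fitness is deterministic given (dataset, config), so
    repeated evaluations of the same mask are served from a cache; the GA
    revisits masks constantly and this dominates run time.  An audit log of
    first evaluations (chromosome, mpr, z, fn) is kept for export.
    """

    def __init__(self, ds: TabularDataset, cfg: FitnessConfig | None = None):
        self.ds = ds
        self.cfg = cfg or FitnessConfig()
        self._cache: dict[tuple[int, ...], FitnessRecord] = {}
        self.audit_log: list[FitnessRecord] = []

    @property
    def n_bits(self) -> int:
        return self.ds.n_attributes

    def __call__(self, chromosome: Sequence[int]) -> FitnessRecord:
        key = tuple(int(b) for b in chromosome)
        rec = self._cache.get(key)
        if rec is None:
            rec = fitness(self.ds, key, self.cfg)
            self._cache[key] = rec
            self.audit_log.append(rec)
        return rec

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": ["".join(map(str, r.chromosome)) for r in self.audit_log],
                "mpr": [r.mpr for r in self.audit_log],
                "z": [r.z for r in self.audit_log],
                "fn": [r.fn for r in self.audit_log],
            }
        )


class StubEvaluator:
    """Deterministic fitness from a user function of the mask (for testing
    operators and for oracle comparisons against exhaustive search)."""

    def __init__(self, fn_of_mask: Callable[[tuple[int, ...]], float], n_bits: int):
        self.fn_of_mask = fn_of_mask
        self.n_bits = n_bits

    def __call__(self, chromosome: Sequence[int]) -> FitnessRecord:
        key = tuple(int(b) for b in chromosome)
        val = float(self.fn_of_mask(key))
        return FitnessRecord(chromosome=key, mpr=val, z=key.count(0), fn=val)
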