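"""Synthetic fixtures: the packaged 15-row worked-example table and a
generator of diabetes-style tabular data with planted structure.

``worked_example_fixture`` returns the small 15 x 8 sample of the Pima-style
attribute table that the worked example of the selector operates on
(pregnancy count, plasma glucose, blood pressure, skin-fold thickness,
serum insulin, body-mass index, pedigree function, age).  The table
carries no class column; labels default to an all-zero placeholder so only
label-free operations apply, or to a synthetic plasma-glucose threshold
rule (clearly a stand-in, not clinical truth) when fitness evaluation is
needed.

``generate`` produces Pima-like tables with a chosen number of informative
attributes (class-conditionally shifted Gaussians), pure-noise attributes,
optional integer rounding and missing values injected completely at
random.  It exists so every stage of the selector is testable without any
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import AttributeSpec, TabularDataset, write_arff

__all__ = [
    "SyntheticSpec",
    "WORKED_EXAMPLE_COLUMNS",
    "worked_example_fixture",
    "generate",
    "write_fixture_arff",
]

WORKED_EXAMPLE_COLUMNS = ("Preg", "Plas", "Pres", "Skin", "Insu", "Mass", "Pedi", "Age")

# 15-row worked-example sample; integer vitals plus real-valued BMI,
# pedigree and age columns.
_WORKED_EXAMPLE_ROWS = (
    (5, 166, 72, 19, 175, 25.8, 0.587, 51),
    (5, 97, 60, 23, 0, 28.2, 0.423, 22),
    (7, 114, 66, 0, 0, 32.8, 0.258, 42),
    (1, 89, 76, 34, 37, 32.2, 0.192, 23),
    (8, 183, 64, 0, 0, 23.3, 0.672, 32),
    (7, 160, 54, 32, 175, 30.5, 0.588, 39),
    (4, 146, 85, 27, 100, 28.9, 0.189, 27),
    (13, 126, 90, 0, 0, 43.4, 0.583, 42),
    (2, 197, 70, 45, 543, 30.5, 0.158, 53),
    (3, 83, 58, 31, 18, 34.3, 0.336, 25),
    (2, 141, 58, 34, 128, 25.4, 0.699, 24),
    (15, 136, 70, 32, 110, 37.1, 0.153, 43),
    (2, 110, 74, 29, 125, 32.4, 0.698, 27),
    (3, 120, 70, 30, 135, 42.9, 0.452, 30),
    (4, 173, 70, 14, 168, 29.7, 0.361, 35),
)


def worked_example_fixture(labels: str = "zeros") -> TabularDataset:
    """The packaged 15 x 8 worked-example table.

    ``labels="zeros"`` (default) attaches the all-zero placeholder;
    ``labels="plas-threshold"`` attaches the synthetic rule
    label = 1 iff Plas >= 136, for operations that need both classes.
    """
    X = pd.DataFrame(
        [list(map(float, row)) for row in _WORKED_EXAMPLE_ROWS],
        columns=list(WORKED_EXAMPLE_COLUMNS),
    )
    if labels == "zeros":
        y = np.zeros(len(X), dtype=int)
    elif labels == "plas-threshold":
        y = (X["Plas"] >= 136).astype(int).to_numpy()
    else:
        raise ValueError(f"unknown label mode {labels!r}")
    return TabularDataset(
        schema=[AttributeSpec(name, "numeric") for name in WORKED_EXAMPLE_COLUMNS],
        X=X,
        labels=y,
        relation="worked_example_sample",
    )


@dataclass
class SyntheticSpec:
    """Recipe for a generated table.

    ``effect_size`` is the between-class mean shift of each informative
    attribute in units of its within-class standard deviation.
    ``integer_columns`` lists column indices to round (and clip at 0),
    emulating count-like vitals.  Defaults match the selector's standard
    benchmark: 800 rows, 5 informative attributes at effect size 1.5, 10
    noise attributes, balanced classes, no missing cells.
    """

    n_rows: int = 800
    n_informative: int = 5
    n_noise: int = 10
    effect_size: float = 1.5
    class_balance: float = 0.5
    missing_rate: float = 0.0
    integer_columns: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be positive")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one attribute")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("attribute counts must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie strictly between 0 and 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def generate(spec: SyntheticSpec | None = None, **kwargs) -> TabularDataset:
    """Generate a table per the spec (deterministic per seed).

    Labels are Bernoulli(class_balance).  Informative columns are
    class-conditional Gaussians N(mu, sd) vs N(mu + effect_size * sd, sd)
    with per-column location and scale drawn once in clinically plausible
    ranges; noise columns are class-independent Gaussians.  Missing cells
    are injected completely at random at ``missing_rate``.
    """
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a spec or keyword fields, not both")
    rng = np.random.default_rng(spec.seed)
    n, k_inf, k_noise = spec.n_rows, spec.n_informative, spec.n_noise
    m = k_inf + k_noise

    y = (rng.random(n) < spec.class_balance).astype(int)
    locs = rng.uniform(10.0, 150.0, size=m)
    sds = rng.uniform(5.0, 40.0, size=m)

    cols = {}
    names = [f"informative_{i + 1}" for i in range(k_inf)] + [
        f"noise_{i + 1}" for i in range(k_noise)
    ]
    for j, name in enumerate(names):
        base = rng.normal(locs[j], sds[j], size=n)
        if j < k_inf:
            base = base + y * spec.effect_size * sds[j]
        if j in spec.integer_columns:
            base = np.clip(np.rint(base), 0, None)
        cols[name] = base

    X = pd.DataFrame(cols, columns=names)
    missing_counts = [0] * m
    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        X = X.mask(pd.DataFrame(mask, columns=names))
        missing_counts = mask.sum(axis=0).tolist()

    schema = [
        AttributeSpec(name, "numeric", "", int(mc))
        for name, mc in zip(names, missing_counts)
    ]
    return TabularDataset(schema=schema, X=X, labels=y, relation="synthetic")


def write_fixture_arff(ds: TabularDataset, path) -> None:
    """Lossless ARFF serialization (round-trips through read_arff)."""
    write_arff(ds, path)
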