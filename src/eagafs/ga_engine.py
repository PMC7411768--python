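"""Genetic search engine: operators, adaptive rate controller, and drivers.

Four driver variants share one generational loop over binary attribute
masks:

* ``GA``    — fixed-rate 2-point crossover + 1-bit mutation, no elitism.
* ``E-GA``  — GA plus an elitist merge of the pre- and post-crossover
  populations each generation (best fitness can never worsen).
* ``A-GA``  — GA plus a self-adaptive controller that nudges the crossover
  rate (CRR) and mutation rate (MRR) against each other every generation,
  driven by the mean per-event fitness-change magnitudes of the two
  operators (CM_alpha vs MM_alpha).
* ``EAGA``  — elitism + adaptive rates + a final-generation "restrict
  mutate" pass that upturns a zero bit per chromosome (a high-order bit for
  good solutions, a low-order bit for poor ones).

A run starts from the mean-threshold initialization stage (one attribute
eliminated by minimum 1's count), evolves masks over the survivors, and
finishes by counting 1 bits per attribute over the final population,
eliminating the minimum-count attribute, and ranking the rest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .dataset_io import TabularDataset
from .init_space import (
    BinarizationSpec,
    OnesCountTable,
    Population,
    binarize,
    drop_min_count,
    initial_population,
    min_count_attribute,
    ones_count,
    rank_attributes,
)
from .wrapper_fitness import (
    FitnessConfig,
    FitnessRecord,
    WrapperEvaluator,
    rank_population,
)

logger = logging.getLogger(__name__)

VARIANTS = ("GA", "E-GA", "A-GA", "EAGA")

__all__ = [
    "AdaptiveState",
    "GenerationLedger",
    "RunConfig",
    "SelectionResult",
    "VARIANTS",
    "two_point_crossover",
    "one_bit_mutation",
    "elitist_swap",
    "update_rates",
    "restrict_mutate",
    "run",
]


# ---------------------------------------------------------------------------
# Adaptive rate controller
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveState:
    """Crossover/mutation rates plus the per-generation event accumulators.

    Each crossover contributes |f1 - f2| to ``cov_log`` and each mutation
    |f_new - f_old| to ``mtv_log``; at generation close their means become
    CM_alpha and MM_alpha.  Whichever operator moved fitness more gets its
    rate raised by its adaptability step (q for CRR, w for MRR) while the
    other is lowered, clamped to ``bounds``.
    """

    crr: float = 0.20
    mrr: float = 0.20
    q: float = 0.05
    w: float = 0.05
    cov_log: list[float] = field(default_factory=list)
    mtv_log: list[float] = field(default_factory=list)
    cm_alpha: float = 0.0
    mm_alpha: float = 0.0
    bounds: tuple[float, float] = (0.05, 0.95)
    last_case: str = ""

    def record_crossover(self, f1: float, f2: float) -> None:
        self.cov_log.append(abs(f1 - f2))

    def record_mutation(self, f_new: float, f_old: float) -> None:
        self.mtv_log.append(abs(f_new - f_old))

    def close_generation(self) -> None:
        """Compute CM_alpha / MM_alpha as generation means (empty log -> 0)."""
        self.cm_alpha = float(np.mean(self.cov_log)) if self.cov_log else 0.0
        self.mm_alpha = float(np.mean(self.mtv_log)) if self.mtv_log else 0.0
        self.cov_log = []
        self.mtv_log = []

    def snapshot(self) -> "AdaptiveState":
        return replace(self, cov_log=list(self.cov_log), mtv_log=list(self.mtv_log))


def update_rates(state: AdaptiveState) -> AdaptiveState:
    """Apply the two-case rate update, clamped to the state's bounds.

    CM_alpha > MM_alpha: crossover is doing the work -> CRR += q, MRR -= w.
    CM_alpha < MM_alpha: the reverse.  Exact equality leaves both untouched.
    """
    lo, hi = state.bounds
    out = state.snapshot()
    if state.cm_alpha > state.mm_alpha:
        out.crr = min(max(state.crr + state.q, lo), hi)
        out.mrr = min(max(state.mrr - state.w, lo), hi)
        out.last_case = "crossover-favoured"
    elif state.cm_alpha < state.mm_alpha:
        out.crr = min(max(state.crr - state.q, lo), hi)
        out.mrr = min(max(state.mrr + state.w, lo), hi)
        out.last_case = "mutation-favoured"
    else:
        out.last_case = "unchanged"
    logger.debug("rate update: %s (crr=%.3f mrr=%.3f)", out.last_case, out.crr, out.mrr)
    return out


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def _repair_all_zero(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fitness is undefined on the empty subset: set one random bit."""
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(0, len(bits))] = 1
    return bits


def two_point_crossover(
    p1: Sequence[int],
    p2: Sequence[int],
    cuts: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exchange the half-open segment [c1, c2) between two parents.

    Total Hamming weight is conserved across the offspring pair; an
    all-zero offspring is repaired by setting one uniformly chosen bit
    (requires ``rng``).
    """
    a = np.asarray(p1, dtype=np.int8)
    b = np.asarray(p2, dtype=np.int8)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("parents must be 1-D bit vectors of equal length")
    c1, c2 = cuts
    if not 0 <= c1 < c2 <= len(a):
        raise ValueError(f"cut points {cuts} invalid for length {len(a)}")
    o1, o2 = a.copy(), b.copy()
    o1[c1:c2], o2[c1:c2] = b[c1:c2], a[c1:c2]
    if rng is not None:
        o1, o2 = _repair_all_zero(o1, rng), _repair_all_zero(o2, rng)
    return o1, o2


def one_bit_mutation(
    c: Sequence[int],
    rng: np.random.Generator,
    index: int | None = None,
) -> np.ndarray:
    """Flip one bit (uniformly chosen unless ``index`` is given).

    The result is at Hamming distance exactly 1 from the input, except that
    an all-zero result is repaired to a random one-bit vector.
    """
    bits = np.asarray(c, dtype=np.int8)
    if bits.ndim != 1 or len(bits) < 1:
        raise ValueError("chromosome must be a non-empty 1-D bit vector")
    j = int(rng.integers(0, len(bits))) if index is None else index
    out = bits.copy()
    out[j] ^= 1
    return _repair_all_zero(out, rng)


def elitist_swap(
    pre: Sequence[FitnessRecord], post: Sequence[FitnessRecord]
) -> list[FitnessRecord]:
    """Keep the P best records of the union of two equally sized populations.

    Duplicate chromosomes collapse to their better record, then additional
    copies are re-admitted (worst first) if needed to restore size P, so
    the population size is invariant and the best fitness of the output is
    at most the best of either input.
    """
    if len(pre) != len(post):
        raise ValueError("pre and post populations must have equal size")
    p = len(pre)
    pool = sorted(list(pre) + list(post), key=lambda r: (r.fn, r.z, r.chromosome))
    kept: list[FitnessRecord] = []
    seen: set[tuple[int, ...]] = set()
    for r in pool:
        if r.chromosome not in seen:
            kept.append(r)
            seen.add(r.chromosome)
    if len(kept) < p:  # re-admit duplicates of the best records
        for r in pool:
            kept.append(r)
            if len(kept) == p:
                break
    return rank_population(kept[:p])


def restrict_mutate(
    c: Sequence[int], fn_value: float, threshold: float
) -> np.ndarray:
    """Final-generation upturn of one zero bit.

    Good solutions (fn below the threshold) get their highest-order
    (leftmost) zero bit set; poor ones their lowest-order (rightmost) zero
    bit.  A chromosome with no zero bit is returned unchanged.
    """
    bits = np.asarray(c, dtype=np.int8).copy()
    if len(bits) < 2:
        raise ValueError("restrict mutate needs chromosomes of length >= 2")
    zeros = np.flatnonzero(bits == 0)
    if not len(zeros):
        return bits
    j = zeros[0] if fn_value < threshold else zeros[-1]
    bits[j] = 1
    return bits


# ---------------------------------------------------------------------------
# Run configuration and results
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a driver needs; fully determines a run together with the data."""

    variant: str = "EAGA"
    generations: int = 100
    pop_size: int = 10
    crr0: float = 0.20
    mrr0: float = 0.20
    ff: float = 0.5
    q: float = 0.05
    w: float = 0.05
    seed: int = 0
    restrict_mutate_threshold: float | None = None  # None -> median fn
    rate_bounds: tuple[float, float] = (0.05, 0.95)
    initial_elimination: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")


@dataclass
class GenerationLedger:
    """Per-generation audit record."""

    generation_index: int
    pre_fitness: list[FitnessRecord]
    post_fitness: list[FitnessRecord]
    best_fn: float
    mean_fn: float
    state_snapshot: AdaptiveState


@dataclass
class SelectionResult:
    """Outcome of a driver run."""

    selected_attributes: list[str]
    final_population: Population
    attribute_ranks: dict[str, int]
    ledger: list[GenerationLedger]
    best_record: FitnessRecord
    initial_dropped: str | None
    final_dropped: str
    final_counts: OnesCountTable
    manifest: dict


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _crossover_phase(
    chroms: np.ndarray,
    records: list[FitnessRecord],
    crr: float,
    rng: np.random.Generator,
    state: AdaptiveState,
) -> np.ndarray:
    """Pair the top-ranked chromosomes and exchange random 2-point segments.

    ceil(crr * P), rounded up to an even number and capped at P, of the
    top-ranked chromosomes are paired in rank order; offspring replace
    their parents in place, the rest of the population is untouched.
    ``records`` must be aligned with ``chroms`` row for row.
    """
    p, n = chroms.shape
    n_cross = math.ceil(crr * p)
    if n_cross % 2:
        n_cross += 1
    n_cross = min(n_cross, p - (p % 2))
    if n_cross < 2:
        return chroms.copy()
    ranked_idx = sorted(
        range(p), key=lambda i: (records[i].fn, records[i].z, records[i].chromosome, i)
    )
    out = chroms.copy()
    for a_pos in range(0, n_cross, 2):
        i, j = ranked_idx[a_pos], ranked_idx[a_pos + 1]
        cuts = tuple(sorted(rng.choice(n + 1, size=2, replace=False)))
        o1, o2 = two_point_crossover(chroms[i], chroms[j], cuts, rng)
        state.record_crossover(records[i].fn, records[j].fn)
        out[i], out[j] = o1, o2
    return out


def _mutation_phase(
    chroms: np.ndarray,
    mrr: float,
    rng: np.random.Generator,
    state: AdaptiveState,
    evaluator: Callable[[Sequence[int]], FitnessRecord],
    protect: tuple[int, ...] | None,
) -> np.ndarray:
    """Flip one random bit in ceil(mrr * P) randomly chosen chromosomes.

    In the elitist variants the current best chromosome is exempt, so that
    mutation cannot destroy the retained optimum.
    """
    p = len(chroms)
    n_mut = min(math.ceil(mrr * p), p)
    if n_mut < 1:
        return chroms.copy()
    candidates = list(range(p))
    if protect is not None:
        shielded = [i for i in candidates
                    if tuple(int(b) for b in chroms[i]) == protect]
        if shielded and len(candidates) > 1:
            candidates.remove(shielded[0])
            n_mut = min(n_mut, len(candidates))
    picks = rng.choice(len(candidates), size=n_mut, replace=False)
    out = chroms.copy()
    for k in picks:
        i = candidates[int(k)]
        old_fn = evaluator(out[i]).fn
        mutant = one_bit_mutation(out[i], rng)
        state.record_mutation(evaluator(mutant).fn, old_fn)
        out[i] = mutant
    return out


def run(
    ds: TabularDataset,
    cfg: RunConfig,
    evaluator: Callable[[Sequence[int]], FitnessRecord] | None = None,
    fitness_config: FitnessConfig | None = None,
) -> SelectionResult:
    """Run one driver variant end to end and return the selection result.

    ``evaluator`` may be any chromosome -> FitnessRecord callable (e.g. a
    deterministic stub for benchmarking, in which case ``ds`` may be None
    and attribute names default to bit positions); by default a memoized
    classifier wrapper over the working dataset is built.  Fully
    reproducible: all randomness flows from ``cfg.seed``.
    """
    if evaluator is None:
        if ds is None:
            raise ValueError("a dataset is required unless an evaluator is given")
        if len(np.unique(ds.labels)) < 2:
            raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    elitist = cfg.variant in ("E-GA", "EAGA")
    adaptive = cfg.variant in ("A-GA", "EAGA")

    # Initialization stage: mean-threshold binarization and 1's-count drop.
    initial_dropped: str | None = None
    work = ds
    if ds is not None and cfg.initial_elimination and ds.n_attributes >= 2:
        spec = BinarizationSpec.from_dataset(ds)
        counts0 = ones_count(binarize(ds, spec))
        survivors = drop_min_count(ds.attribute_names, counts0)
        initial_dropped = min_count_attribute(counts0)
        work = ds.select_attributes(survivors)
        logger.info("initialization dropped %r by minimum 1's count", initial_dropped)

    if evaluator is None:
        fcfg = fitness_config or FitnessConfig(ff=cfg.ff, eval_seed=cfg.seed)
        evaluator = WrapperEvaluator(work, fcfg)
    if work is not None:
        n_bits = work.n_attributes
        attr_names = work.attribute_names
    else:
        n_bits = evaluator.n_bits
        attr_names = [f"attr_{j + 1}" for j in range(n_bits)]

    pop_seed = int(rng.integers(0, 2 ** 31))
    population = initial_population(n_bits, cfg.pop_size, pop_seed).chromosomes

    state = AdaptiveState(
        crr=cfg.crr0, mrr=cfg.mrr0, q=cfg.q, w=cfg.w, bounds=cfg.rate_bounds
    )
    ledger: list[GenerationLedger] = []
    best_record: FitnessRecord | None = None

    for gen in range(1, cfg.generations + 1):
        pre_records = [evaluator(c) for c in population]
        pre_ranked = rank_population(pre_records)
        crr = state.crr if adaptive else cfg.crr0
        mrr = state.mrr if adaptive else cfg.mrr0

        crossed = _crossover_phase(population, pre_records, crr, rng, state)
        post_ranked = rank_population([evaluator(c) for c in crossed])

        if elitist:
            merged = elitist_swap(pre_ranked, post_ranked)
            population = np.array([m.chromosome for m in merged], dtype=np.int8)
            protect: tuple[int, ...] | None = merged[0].chromosome
        else:
            population = crossed
            protect = None

        population = _mutation_phase(population, mrr, rng, state, evaluator, protect)

        state.close_generation()
        if adaptive:
            state = update_rates(state)

        current = rank_population([evaluator(c) for c in population])
        best_record = current[0] if best_record is None or not elitist else (
            current[0] if current[0].fn <= best_record.fn else best_record
        )
        ledger.append(
            GenerationLedger(
                generation_index=gen,
                pre_fitness=pre_ranked,
                post_fitness=post_ranked,
                best_fn=current[0].fn,
                mean_fn=float(np.mean([r.fn for r in current])),
                state_snapshot=state.snapshot(),
            )
        )

    # Final-generation restrict mutate (EAGA only).
    if cfg.variant == "EAGA":
        records = [evaluator(c) for c in population]
        thr = cfg.restrict_mutate_threshold
        if thr is None:
            thr = float(np.median([r.fn for r in records]))
        population = np.array(
            [restrict_mutate(c, r.fn, thr) for c, r in zip(population, records)],
            dtype=np.int8,
        )

    # Final per-attribute 1's count over the population; drop the minimum.
    final_counts = OnesCountTable(
        attribute_names=attr_names,
        counts=population.sum(axis=0),
    )
    selected = drop_min_count(attr_names, final_counts)
    final_dropped = min_count_attribute(final_counts)
    survivor_counts = OnesCountTable(
        attribute_names=selected,
        counts=[final_counts[nm] for nm in selected],
    )
    ranks = rank_attributes(survivor_counts)

    manifest = {
        "variant": cfg.variant,
        "generations": cfg.generations,
        "pop_size": cfg.pop_size,
        "crr0": cfg.crr0,
        "mrr0": cfg.mrr0,
        "ff": cfg.ff,
        "q": cfg.q,
        "w": cfg.w,
        "seed": cfg.seed,
        "population_seed": pop_seed,
        "initial_elimination": cfg.initial_elimination,
        "best_fn_per_generation": [g.best_fn for g in ledger],
        "mean_fn_per_generation": [g.mean_fn for g in ledger],
        "crr_trajectory": [g.state_snapshot.crr for g in ledger],
        "mrr_trajectory": [g.state_snapshot.mrr for g in ledger],
    }
    return SelectionResult(
        selected_attributes=selected,
        final_population=Population(chromosomes=population, seed=pop_seed),
        attribute_ranks=ranks,
        ledger=ledger,
        best_record=best_record,
        initial_dropped=initial_dropped,
        final_dropped=final_dropped,
        final_counts=final_counts,
        manifest=manifest,
    )
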