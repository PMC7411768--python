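import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eagafs.ga_engine import (
    AdaptiveState,
    RunConfig,
    elitist_swap,
    one_bit_mutation,
    restrict_mutate,
    run,
    two_point_crossover,
    update_rates,
)
from eagafs.init_space import initial_population
from eagafs.wrapper_fitness import FitnessRecord, StubEvaluator, rank_population


_uid = iter(range(10_000))


def records(*fns):
    """Ranked records with globally distinct chromosomes."""
    out = []
    for fn in fns:
        u = next(_uid)
        bits = tuple(int(b) for b in format(u + 1, "014b"))
        out.append(FitnessRecord(bits, fn, 0, fn))
    return rank_population(out)


def landscape(seed, n_bits=6):
    """Deterministic wrapper-like fitness: a planted target subset is best."""
    rng = np.random.default_rng(seed)
    target = rng.integers(0, 2, size=n_bits)
    if not target.any():
        target[0] = 1

    def fn(mask):
        missing = sum(1 for t, m in zip(target, mask) if t and not m)
        extra = sum(1 for t, m in zip(target, mask) if m and not t)
        h = hash((seed,) + tuple(mask)) % 1000 / 1000
        return 0.1 + 0.07 * missing + 0.03 * extra + 0.005 * h

    return fn


class TestCrossover:
    def test_identical_parents_unchanged(self):
        p = np.array([1, 0, 1, 1, 0])
        o1, o2 = two_point_crossover(p, p, (1, 4))
        assert np.array_equal(o1, p) and np.array_equal(o2, p)

    def test_half_open_segment_exchange(self):
        o1, o2 = two_point_crossover([1] * 7, [0] * 7, (2, 5),
                                     np.random.default_rng(0))
        assert o1.tolist() == [1, 1, 0, 0, 0, 1, 1]
        assert o2.tolist() == [0, 0, 1, 1, 1, 0, 0]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            two_point_crossover([1, 0], [1, 0, 1], (0, 1))

    def test_all_zero_offspring_repaired(self):
        # swapping [0,2) turns p1 into all zeros pre-repair
        o1, o2 = two_point_crossover([1, 1], [0, 0], (0, 2),
                                     np.random.default_rng(3))
        assert o1.sum() >= 1 and o2.sum() >= 1

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10 ** 6), n=st.integers(2, 12))
    def test_positions_and_weight_conservation(self, seed, n):
        rng = np.random.default_rng(seed)
        p1 = rng.integers(0, 2, size=n)
        p2 = rng.integers(0, 2, size=n)
        c1, c2 = sorted(rng.choice(n + 1, size=2, replace=False))
        o1, o2 = two_point_crossover(p1, p2, (int(c1), int(c2)))  # no repair
        for j in range(n):
            inside = c1 <= j < c2
            assert o1[j] == (p2[j] if inside else p1[j])
            assert o2[j] == (p1[j] if inside else p2[j])
        assert o1.sum() + o2.sum() == p1.sum() + p2.sum()


class TestMutation:
    def test_forced_index_flip(self):
        out = one_bit_mutation([1, 0, 1, 0], np.random.default_rng(0), index=2)
        assert out.tolist() == [1, 0, 0, 0]

    def test_involution_at_same_index(self):
        rng = np.random.default_rng(0)
        c = np.array([1, 0, 1, 1])
        assert np.array_equal(one_bit_mutation(one_bit_mutation(c, rng, 1), rng, 1), c)

    def test_hamming_distance_is_one(self):
        rng = np.random.default_rng(5)
        c = np.array([1, 0, 1, 1, 0, 1])
        for _ in range(200):
            out = one_bit_mutation(c, rng)
            assert (out != c).sum() == 1

    def test_flip_index_uniform(self):
        rng = np.random.default_rng(9)
        counts = np.zeros(5)
        c = np.ones(5, dtype=np.int8)
        for _ in range(10_000):
            out = one_bit_mutation(c, rng)
            counts[np.flatnonzero(out != c)[0]] += 1
        sigma = np.sqrt(10_000 * 0.2 * 0.8)
        assert np.all(np.abs(counts - 2000) < 4 * sigma)


class TestElitistSwap:
    def test_best_of_union(self):
        merged = elitist_swap(records(0.18, 0.21, 0.29), records(0.25, 0.19, 0.17))
        assert [round(r.fn, 2) for r in merged] == [0.17, 0.18, 0.19]

    def test_identical_populations(self):
        pre = records(0.3, 0.2, 0.1)
        merged = elitist_swap(pre, pre)
        assert [r.fn for r in merged] == sorted(r.fn for r in pre)
        assert len(merged) == 3

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10 ** 6))
    def test_min_of_output_is_min_over_both(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 8))
        pre = [FitnessRecord(tuple(rng.integers(0, 2, 4)), 0, 0,
                             float(rng.random())) for _ in range(p)]
        post = [FitnessRecord(tuple(rng.integers(0, 2, 4)), 0, 0,
                              float(rng.random())) for _ in range(p)]
        merged = elitist_swap(pre, post)
        assert len(merged) == p
        assert merged[0].fn == min(r.fn for r in pre + post)
        # brute-force union sort oracle over distinct chromosomes
        best = {}
        for r in pre + post:
            if r.chromosome not in best or r.fn < best[r.chromosome].fn:
                best[r.chromosome] = r
        oracle = sorted(best.values(), key=lambda r: (r.fn, r.z, r.chromosome))[:p]
        assert [r.fn for r in merged[: len(oracle)]] == [r.fn for r in oracle]


class TestAdaptiveController:
    def test_crossover_favoured_case(self):
        s = AdaptiveState(crr=0.20, mrr=0.20, q=0.05, w=0.05,
                          cm_alpha=0.3, mm_alpha=0.1)
        out = update_rates(s)
        assert out.crr == pytest.approx(0.25)
        assert out.mrr == pytest.approx(0.15)

    def test_mutation_favoured_case(self):
        s = AdaptiveState(crr=0.20, mrr=0.20, cm_alpha=0.1, mm_alpha=0.3)
        out = update_rates(s)
        assert out.crr == pytest.approx(0.15)
        assert out.mrr == pytest.approx(0.25)

    def test_equal_means_leave_rates_unchanged(self):
        s = AdaptiveState(crr=0.4, mrr=0.3, cm_alpha=0.2, mm_alpha=0.2)
        out = update_rates(s)
        assert (out.crr, out.mrr) == (0.4, 0.3)

    def test_clamped_at_bounds(self):
        s = AdaptiveState(crr=0.93, mrr=0.06, q=0.05, w=0.05,
                          cm_alpha=1.0, mm_alpha=0.0)
        out = update_rates(s)
        assert out.crr == pytest.approx(0.95)
        assert out.mrr == pytest.approx(0.05)

    def test_event_accumulation_means(self):
        s = AdaptiveState()
        s.record_crossover(0.5, 0.4)
        s.record_crossover(0.1, 0.4)
        s.record_mutation(0.2, 0.2)
        s.close_generation()
        assert s.cm_alpha == pytest.approx(0.2)
        assert s.mm_alpha == pytest.approx(0.0)

    def test_empty_generation_means_zero(self):
        s = AdaptiveState()
        s.close_generation()
        assert (s.cm_alpha, s.mm_alpha) == (0.0, 0.0)

    def test_accumulator_matches_brute_force(self):
        rng = np.random.default_rng(2)
        s = AdaptiveState()
        events = rng.random((20, 2))
        for f1, f2 in events:
            s.record_crossover(f1, f2)
        s.close_generation()
        assert s.cm_alpha == pytest.approx(np.mean(np.abs(events[:, 0] - events[:, 1])))


class TestRestrictMutate:
    def test_good_solution_upturns_highest_order_zero(self):
        out = restrict_mutate([0, 1, 1, 1, 1, 1, 1], fn_value=0.1, threshold=0.5)
        assert out.tolist() == [1] * 7

    def test_poor_solution_upturns_lowest_order_zero(self):
        out = restrict_mutate([1, 1, 1, 1, 1, 1, 0], fn_value=0.9, threshold=0.5)
        assert out.tolist() == [1] * 7

    def test_all_ones_unchanged(self):
        out = restrict_mutate([1, 1, 1], fn_value=0.9, threshold=0.5)
        assert out.tolist() == [1, 1, 1]

    def test_changes_at_most_one_bit(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            c = rng.integers(0, 2, size=8)
            out = restrict_mutate(c, float(rng.random()), 0.5)
            assert (out != c).sum() <= 1
            assert out.sum() >= c.sum()


class TestDrivers:
    def test_noop_operators_preserve_population(self, worked_example_labelled):
        cfg = RunConfig(variant="GA", generations=1, pop_size=6, crr0=0.0,
                        mrr0=0.0, seed=3)
        res = run(worked_example_labelled, cfg)
        expected = initial_population(7, 6, res.manifest["population_seed"])
        assert np.array_equal(
            np.sort(res.final_population.chromosomes, axis=0),
            np.sort(expected.chromosomes, axis=0),
        )

    def test_run_is_reproducible(self, worked_example_labelled):
        cfg = RunConfig(variant="EAGA", generations=8, pop_size=8, seed=17)
        r1 = run(worked_example_labelled, cfg)
        r2 = run(worked_example_labelled, cfg)
        assert r1.selected_attributes == r2.selected_attributes
        assert r1.manifest == r2.manifest
        assert np.array_equal(r1.final_population.chromosomes,
                              r2.final_population.chromosomes)
        assert r1.attribute_ranks == r2.attribute_ranks

    def test_population_size_constant(self, worked_example_labelled):
        for variant in ("GA", "E-GA", "A-GA", "EAGA"):
            cfg = RunConfig(variant=variant, generations=5, pop_size=9, seed=2)
            res = run(worked_example_labelled, cfg)
            assert res.final_population.size == 9
            for g in res.ledger:
                assert len(g.pre_fitness) == 9
                assert len(g.post_fitness) == 9

    def test_elitist_best_fn_non_increasing(self):
        for seed in range(5):
            cfg = RunConfig(variant="EAGA", generations=30, pop_size=12,
                            seed=seed, initial_elimination=False)
            res = run(None, cfg, evaluator=StubEvaluator(landscape(seed, 8), 8))
            best = [g.best_fn for g in res.ledger]
            assert all(b <= a + 1e-12 for a, b in zip(best, best[1:]))

    def test_adaptive_rates_bounded_and_step_law(self):
        cfg = RunConfig(variant="A-GA", generations=40, pop_size=10, seed=5,
                        q=0.05, w=0.07, initial_elimination=False)
        res = run(None, cfg, evaluator=StubEvaluator(landscape(5, 7), 7))
        crr = [cfg.crr0] + res.manifest["crr_trajectory"]
        mrr = [cfg.mrr0] + res.manifest["mrr_trajectory"]
        lo, hi = cfg.rate_bounds
        for seq, step in ((crr, cfg.q), (mrr, cfg.w)):
            assert all(lo - 1e-12 <= v <= hi + 1e-12 for v in seq[1:])
            for a, b in zip(seq, seq[1:]):
                d = abs(b - a)
                assert d <= step + 1e-12
                # a partial step only ever happens at a clamp boundary
                if 1e-12 < d < step - 1e-12:
                    assert b in (lo, hi)
        # rates move in opposite directions whenever they move
        for a1, b1, a2, b2 in zip(crr, crr[1:], mrr, mrr[1:]):
            if abs(b1 - a1) > 1e-12 and abs(b2 - a2) > 1e-12:
                assert (b1 - a1) * (b2 - a2) < 0

    def test_eaga_drops_unique_minimum_count_attribute(self, worked_example_labelled):
        cfg = RunConfig(variant="EAGA", generations=12, pop_size=10, seed=21)
        res = run(worked_example_labelled, cfg)
        counts = res.final_counts
        assert counts[res.final_dropped] == min(counts.counts)
        assert res.final_dropped not in res.selected_attributes
        assert len(res.selected_attributes) == 6
        # rank 1 goes to a maximum-count survivor
        rank1 = next(nm for nm, r in res.attribute_ranks.items() if r == 1)
        assert counts[rank1] == max(counts[nm] for nm in res.selected_attributes)

    def test_initial_elimination_drops_min_count(self, worked_example_labelled):
        cfg = RunConfig(variant="GA", generations=1, pop_size=4, seed=0)
        res = run(worked_example_labelled, cfg)
        assert res.initial_dropped is not None
        assert res.initial_dropped not in res.final_counts.attribute_names
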