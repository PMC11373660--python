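"""Wright-Fisher engine: per-generation operations, determinism contracts,
cache transparency, and neutral-drift calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastevo as pv

from conftest import random_genotype


class _StubRng:
    """Feeds predetermined uniform draws to mutate()/recombine()."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        out = self.values.pop(0)
        return np.asarray(out) if size is not None else out

    def integers(self, low, high, size=None):
        return np.zeros(size, dtype=int)


class TestEnvironmentSchedule:
    @pytest.mark.parametrize("T,IT,start,expected", [
        (0, 100, "E1", "E1"),
        (99, 100, "E1", "E1"),
        (100, 100, "E1", "E2"),   # first switch at T = IT
        (250, 100, "E1", "E1"),   # epoch index 2 is even again
        (0, 1, "E2", "E2"),
        (1, 1, "E2", "E1"),
    ])
    def test_alternation(self, T, IT, start, expected):
        assert pv.environment_at(T, IT, start) == expected


class TestMutate:
    def test_zero_rates_identity(self, simp_params):
        p = simp_params.with_overrides(mu_g=0.0, mu_b=0.0, mu_c=0.0)
        gt = pv.Genotype.initial(p)
        out = pv.mutate(gt, p, np.random.default_rng(0))
        assert out == gt and out is not gt

    def test_clamps_g_at_upper_bound(self, simp_params):
        """A forced increment past 1/alpha clips to exactly 1/alpha."""
        p = simp_params.with_overrides(mu_g=1.0, gamma_g=0.1)
        gt = pv.Genotype(g=[4.98, 4.98], B=np.zeros((2, 2)), c=[0.0, 0.0])
        # trial draws (all hit), then effect draws: 2u-1 = 0.5 -> +0.05
        rng = _StubRng([
            np.zeros(2), np.full(2, 0.75),          # g trials, g effects
            np.ones((2, 2)), np.zeros((2, 2)),      # B: no hits
            np.ones(2), np.zeros(2),                # c: no hits
        ])
        out = pv.mutate(gt, p, rng)
        assert np.all(out.g == 5.0)

    def test_clamps_g_at_lower_bound(self, simp_params):
        p = simp_params.with_overrides(mu_g=1.0, gamma_g=0.1)
        gt = pv.Genotype(g=[0.02, 0.02], B=np.zeros((2, 2)), c=[0.0, 0.0])
        rng = _StubRng([
            np.zeros(2), np.full(2, 0.25),          # 2u-1 = -0.5 -> -0.05
            np.ones((2, 2)), np.zeros((2, 2)),
            np.ones(2), np.zeros(2),
        ])
        out = pv.mutate(gt, p, rng)
        assert np.all(out.g == 0.0)

    def test_mutation_count_matches_binomial_expectation(self, simp_params):
        """mu = 1e-3 over 1e5 element trials: count within 3 s.d. of 100."""
        p = simp_params.with_overrides(mu_g=1e-3, mu_b=0.0, mu_c=0.0)
        rng = np.random.default_rng(42)
        gt = pv.Genotype.initial(p)
        trials, hits = 0, 0
        for _ in range(50_000):
            out = pv.mutate(gt, p, rng)
            hits += int(np.sum(out.g != gt.g))
            trials += p.n
        mean = trials * 1e-3
        sd = math.sqrt(trials * 1e-3 * (1 - 1e-3))
        assert abs(hits - mean) < 3 * sd

    def test_row_mode_perturbs_single_element(self, simp_params):
        p = simp_params.with_overrides(mu_b=1.0, b_mutation="row")
        gt = pv.Genotype.initial(p)
        out = pv.mutate(gt, p, np.random.default_rng(3))
        # exactly one changed element per row of B
        assert np.all((out.B != gt.B).sum(axis=1) == 1)


class TestRecombine:
    def test_identical_parents(self, simp_params):
        gt = pv.make_fixture("bistable_diag").genotype
        child = pv.recombine(gt, gt, np.random.default_rng(0))
        assert child == gt

    def test_forced_single_parent(self):
        a = pv.Genotype(g=[1.0, 2.0], B=[[1, 2], [3, 4]], c=[5.0, 6.0])
        b = pv.Genotype(g=[0.0, 0.0], B=np.zeros((2, 2)), c=[0.0, 0.0])
        child = pv.recombine(a, b, _StubRng([np.zeros(8)]))
        assert child == a
        child = pv.recombine(a, b, _StubRng([np.ones(8)]))
        assert child == b

    def test_inheritance_is_balanced(self):
        rng = np.random.default_rng(9)
        a = pv.Genotype(g=[1.0, 1.0], B=np.ones((2, 2)), c=[1.0, 1.0])
        b = pv.Genotype(g=[0.0, 0.0], B=np.zeros((2, 2)), c=[0.0, 0.0])
        from_a = 0
        draws = 2000 * 8
        for _ in range(2000):
            from_a += int(pv.recombine(a, b, rng).to_vector().sum())
        sd = math.sqrt(draws * 0.25)
        assert abs(from_a - draws / 2) < 3 * sd

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_every_locus_comes_from_a_parent(self, seed):
        rng = np.random.default_rng(seed)
        a = random_genotype(rng, 3, 5.0)
        b = random_genotype(rng, 3, 5.0)
        child = pv.recombine(a, b, rng).to_vector()
        va, vb = a.to_vector(), b.to_vector()
        assert np.all((child == va) | (child == vb))


class TestSelectParentPairs:
    def test_single_survivor(self):
        pairs = pv.select_parent_pairs([1.0, 0.0, 0.0], 50,
                                       np.random.default_rng(0))
        assert np.all(pairs == 0)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            pv.select_parent_pairs([1.0, -0.1], 5, np.random.default_rng(0))

    def test_uniform_when_fitness_equal(self):
        rng = np.random.default_rng(7)
        pairs = pv.select_parent_pairs(np.ones(10), 50_000, rng)
        counts = np.bincount(pairs.ravel(), minlength=10)
        # chi-square goodness of fit, df=9; 27.88 = 0.999 quantile
        expected = pairs.size / 10
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 < 27.88

    def test_proportional_to_fitness(self):
        rng = np.random.default_rng(8)
        pairs = pv.select_parent_pairs([2.0, 1.0], 50_000, rng)
        draws = pairs.size
        freq0 = np.count_nonzero(pairs == 0)
        sd = math.sqrt(draws * (2 / 3) * (1 / 3))
        assert abs(freq0 - draws * 2 / 3) < 3 * sd

    def test_all_zero_falls_back_to_uniform(self):
        rng = np.random.default_rng(10)
        pairs = pv.select_parent_pairs(np.zeros(4), 20_000, rng)
        counts = np.bincount(pairs.ravel(), minlength=4)
        assert counts.min() > 0.2 * pairs.size / 4


class TestAdvanceGeneration:
    def test_monomorphic_no_mutation_is_invariant(self, simp_params):
        p = simp_params.with_overrides(mu_g=0.0, mu_b=0.0, mu_c=0.0)
        pop = pv.Population.initial(p)
        new, m1, m2 = pv.advance_generation(pop, p, np.random.default_rng(0))
        assert np.array_equal(new.rows, pop.rows)
        assert new.generation == 1

    def test_initial_means_are_exp_minus_one(self, full_params):
        pop = pv.Population.initial(full_params)
        _, m1, m2 = pv.advance_generation(pop, full_params,
                                          np.random.default_rng(0))
        assert m1 == pytest.approx(math.exp(-1), rel=1e-12)
        assert m2 == pytest.approx(math.exp(-1), rel=1e-12)

    def test_population_size_and_bounds_conserved(self, simp_params):
        p = simp_params.with_overrides(mu_g=0.5, mu_b=0.5, mu_c=0.5,
                                       gamma_g=2.0)
        pop = pv.Population.initial(p)
        rng = np.random.default_rng(4)
        for _ in range(20):
            pop, _, _ = pv.advance_generation(pop, p, rng)
            assert pop.size == p.N
            assert np.all(pop.rows[:, :p.n] >= 0.0)
            assert np.all(pop.rows[:, :p.n] <= p.x_max)


class TestRun:
    def test_tmax_zero_records_single_entry(self, full_params):
        rec = pv.run(full_params.with_overrides(T_max=0))
        assert len(rec.mean_w1) == 1
        assert rec.mean_w1[0] == pytest.approx(math.exp(-1), rel=1e-10)
        assert not rec.success

    def test_no_mutation_means_constant(self, simp_params):
        p = simp_params.with_overrides(mu_g=0.0, mu_b=0.0, mu_c=0.0,
                                       T_max=500)
        rec = pv.run(p)
        assert not rec.success
        assert np.unique(rec.mean_w1).size == 1
        assert np.unique(rec.mean_w2).size == 1

    def test_same_seed_identical_records(self, simp_params):
        p = simp_params.with_overrides(T_max=300, seed=123)
        a = pv.run(p, window=50)
        b = pv.run(p, window=50)
        assert np.array_equal(a.mean_w1, b.mean_w1)
        assert np.array_equal(a.mean_w2, b.mean_w2)
        assert np.array_equal(a.final_population.rows,
                              b.final_population.rows)

    def test_fast_and_reference_engines_agree_exactly(self, simp_params):
        p = simp_params.with_overrides(T_max=400, seed=5)
        fast = pv.run(p, window=50)
        ref = pv.run(p, window=50, engine="reference")
        assert np.array_equal(fast.mean_w1, ref.mean_w1)
        assert np.array_equal(fast.mean_w2, ref.mean_w2)
        assert np.array_equal(fast.final_population.rows,
                              ref.final_population.rows)

    def test_cache_transparency(self, simp_params):
        p = simp_params.with_overrides(T_max=300, seed=6)
        on = pv.run(p, window=50, engine="reference", use_cache=True)
        off = pv.run(p, window=50, engine="reference", use_cache=False)
        assert np.array_equal(on.mean_w1, off.mean_w1)
        assert np.array_equal(on.final_population.rows,
                              off.final_population.rows)

    def test_record_stride_thins_but_preserves_values(self, simp_params):
        p = simp_params.with_overrides(T_max=250, seed=8)
        full = pv.run(p, window=40)
        thinned = pv.run(p, window=40, record_stride=50)
        assert thinned.generations[-1] == full.generations[-1]
        for g, m1, m2 in zip(thinned.generations, thinned.mean_w1,
                             thinned.mean_w2):
            assert m1 == full.mean_w1[g] and m2 == full.mean_w2[g]

    def test_snapshots_align_with_schedule(self, simp_params):
        p = simp_params.with_overrides(T_max=200, seed=9)
        rec = pv.run(p, window=40, snapshot_every=64)
        gens = [g for g, _ in rec.snapshots]
        assert gens == [0, 64, 128, 192]
        for g, snap in rec.snapshots:
            assert snap.generation == g and snap.size == p.N

    def test_row_mutation_mode_runs_via_reference(self, simp_params):
        p = simp_params.with_overrides(T_max=50, seed=1, b_mutation="row")
        rec = pv.run(p, window=10)
        assert rec.final_generation == 50


def test_neutral_fixation_probability_is_one_over_N(neutral_fixation_count):
    """A selectively neutral tagged allele at initial frequency 1/N fixes
    with probability ~1/N under drift alone.
    Frozen 99% binomial band for 2000 replicates at p = 1/100: [9, 32]."""
    assert 9 <= neutral_fixation_count <= 32
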