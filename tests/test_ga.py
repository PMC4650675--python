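import numpy as np
import pytest
from scipy import stats

from soilspec.ga import (
    Chromosome,
    GAConfig,
    crossover,
    fitness,
    init_population,
    mutate,
    run_ga,
    toggle_mask,
)

SMALL = dict(population_size=12, max_generations=5, n_components=3, max_features=12)


class TestChromosome:
    def test_sorted_unique(self):
        ch = Chromosome([5, 1, 5, 3])
        assert ch.features == (1, 3, 5)
        assert ch.size == 3


class TestGAConfig:
    def test_min_features_is_components_plus_one(self):
        assert GAConfig(n_components=26).min_features == 27

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GAConfig(fitness_weights=(0.8, 0.8))

    def test_max_features_below_min_rejected(self):
        with pytest.raises(ValueError, match="max_features"):
            GAConfig(n_components=26, max_features=20)


class TestFitness:
    def test_weighted_combination_of_components(self, small_spectra):
        cfg = GAConfig(**SMALL, fitness_weights=(0.5, 0.5), seed=0)
        ch = Chromosome(range(10, 22))
        f, r_cal, r_loo = fitness(small_spectra, ch, cfg)
        assert f == pytest.approx(0.5 * r_cal + 0.5 * r_loo)
        assert 0.0 <= r_loo <= r_cal <= 1.0 or (0 <= r_cal <= 1 and 0 <= r_loo <= 1)
        # asymmetric weights move the fitness accordingly
        cfg2 = GAConfig(**SMALL, fitness_weights=(1.0, 0.0), seed=0)
        f2, _, _ = fitness(small_spectra, ch, cfg2)
        assert f2 == pytest.approx(r_cal)

    def test_separable_subset_reaches_maximum(self):
        # perfectly separable two-class data: r_cal = r_LOO = 1 -> fitness 1
        from soilspec.dataset import SpectraSet

        wn = np.linspace(5000.0, 4000.0, 4)
        X = np.tile([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]], (1, 4))
        s = SpectraSet(wn, X, [f"s{i}" for i in range(6)],
                       ["A"] * 3 + ["B"] * 3, ("A", "B"))
        cfg = GAConfig(population_size=4, max_generations=2, n_components=1,
                       max_features=3, fitness_weights=(0.3, 0.7))
        f, r_cal, r_loo = fitness(s, Chromosome([0, 2, 3]), cfg)
        assert f == 1.0 and r_cal == 1.0 and r_loo == 1.0

    def test_bound_violations_named(self, small_spectra):
        cfg = GAConfig(**SMALL)
        with pytest.raises(ValueError, match="minimum"):
            fitness(small_spectra, Chromosome([1, 2]), cfg)
        with pytest.raises(ValueError, match="maximum"):
            fitness(small_spectra, Chromosome(range(30)), cfg)


class TestOperators:
    def test_init_population_bounds_and_determinism(self):
        cfg = GAConfig(**SMALL)
        pop1 = init_population(cfg, 100, np.random.default_rng(4))
        pop2 = init_population(cfg, 100, np.random.default_rng(4))
        assert pop1 == pop2
        for ch in pop1:
            assert cfg.min_features <= ch.size <= cfg.max_features
            assert ch.features[-1] < 100

    def test_init_population_uniform_index_coverage(self):
        """Over many draws every grid index is sampled ~uniformly (chi-square)."""
        cfg = GAConfig(population_size=2000, max_generations=1, n_components=3,
                       max_features=12)
        rng = np.random.default_rng(8)
        counts = np.zeros(50)
        for ch in init_population(cfg, 50, rng):
            counts[list(ch.features)] += 1
        _, p_value = stats.chisquare(counts)
        assert p_value > 0.001

    def test_crossover_child_within_union_and_parent_sized(self):
        cfg = GAConfig(**SMALL)
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = Chromosome(rng.choice(60, size=rng.integers(4, 13), replace=False))
            b = Chromosome(rng.choice(60, size=rng.integers(4, 13), replace=False))
            child = crossover(a, b, cfg, rng)
            assert set(child.features) <= set(a.features) | set(b.features)
            assert cfg.min_features <= child.size <= cfg.max_features

    def test_crossover_identical_parents_identity(self):
        cfg = GAConfig(**SMALL)
        a = Chromosome(range(4, 12))
        child = crossover(a, a, cfg, np.random.default_rng(1))
        assert child == a

    def test_crossover_child_size_matches_a_parent(self):
        cfg = GAConfig(population_size=10, max_generations=1, n_components=2,
                       max_features=30)
        rng = np.random.default_rng(9)
        a = Chromosome(range(10))       # size 10
        b = Chromosome(range(40, 60))   # size 20
        sizes = [crossover(a, b, cfg, rng).size for _ in range(1000)]
        counts = np.bincount(sizes, minlength=21)
        assert set(np.flatnonzero(counts)) == {10, 20}
        # both parents chosen with p=1/2: two-sided binomial check
        assert stats.binomtest(int(counts[10]), 1000, 0.5).pvalue > 1e-3

    def test_mutate_zero_probability_is_identity(self):
        cfg = GAConfig(**SMALL, mutation_prob=0.0)
        ch = Chromosome(range(5, 13))
        assert mutate(ch, cfg, 100, np.random.default_rng(2)) == ch

    def test_mutate_always_repaired_to_bounds(self):
        cfg = GAConfig(**SMALL, mutation_prob=0.5)
        rng = np.random.default_rng(3)
        ch = Chromosome(range(4, 12))
        for _ in range(300):
            ch2 = mutate(ch, cfg, 60, rng)
            assert cfg.min_features <= ch2.size <= cfg.max_features
            assert ch2.features[-1] < 60

    def test_toggle_rate_binomial_calibration(self):
        """Pre-repair per-feature toggle frequency over 10,000 trials sits in
        the exact binomial 99% interval around 0.05."""
        p, prob, trials = 40, 0.05, 10_000
        rng = np.random.default_rng(12345)
        counts = np.zeros(p)
        for _ in range(trials):
            counts += toggle_mask(p, prob, rng)
        lo = stats.binom.ppf(0.005, trials, prob)
        hi = stats.binom.ppf(0.995, trials, prob)
        pooled = counts.sum()
        plo = stats.binom.ppf(0.005, trials * p, prob)
        phi = stats.binom.ppf(0.995, trials * p, prob)
        assert plo <= pooled <= phi
        # individual features at the wider 99.9% interval (40 simultaneous checks)
        lo3 = stats.binom.ppf(0.0005, trials, prob)
        hi3 = stats.binom.ppf(0.9995, trials, prob)
        assert np.all((counts >= lo3) & (counts <= hi3))
        assert (counts >= lo).mean() > 0.9 and (counts <= hi).mean() > 0.9


class TestRunGA:
    def test_deterministic_and_elitist_trajectory(self, small_spectra):
        cfg = GAConfig(population_size=8, max_generations=4, n_components=3,
                       max_features=10, seed=77, target_fitness=2.0)
        r1 = run_ga(small_spectra, cfg)
        r2 = run_ga(small_spectra, cfg)
        assert r1.best_subset == r2.best_subset
        assert r1.trajectory == r2.trajectory
        best = [b for b, _ in r1.trajectory]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))
        assert r1.generations_run <= cfg.max_generations
        w_cal, w_loo = cfg.fitness_weights
        assert r1.best_fitness == pytest.approx(
            w_cal * r1.fitness_components[0] + w_loo * r1.fitness_components[1]
        )

    def test_stops_early_at_target_fitness(self, small_spectra):
        cfg = GAConfig(population_size=10, max_generations=20, n_components=3,
                       max_features=12, seed=5, target_fitness=0.0)
        r = run_ga(small_spectra, cfg)
        assert r.generations_run == 0  # initial population already meets target
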