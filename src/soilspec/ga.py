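"""Genetic-algorithm wavelength selection for PLSDA.

A chromosome is an explicit set of feature (wavenumber) indices.  Fitness
of a subset is a weighted combination of PLSDA calibration accuracy and
leave-one-out cross-validation accuracy on the training set, both as
fractions in [0, 1]; the defaults weight them equally.  Evolution uses
tournament selection, union crossover, grid-wide per-feature toggle
mutation and elitism, stopping at a target fitness or a generation cap.

Subset sizes are bounded below by ``n_components + 1`` (one more feature
than latent variables, so the PLS fit is determined) and above by
``max_features`` (75 in the study configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import SpectraSet
from .plsda import PLSDAClassifier, loo_cv, overall_accuracy, train_confusion


@dataclass(frozen=True)
class Chromosome:
    """One candidate feature subset (sorted, unique grid indices)."""

    features: tuple[int, ...]

    def __init__(self, features: Sequence[int]):
        object.__setattr__(self, "features", tuple(sorted(set(int(i) for i in features))))

    @property
    def size(self) -> int:
        return len(self.features)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.features, dtype=int)


@dataclass
class GAConfig:
    """Hyperparameters of the wavelength-selection GA (study defaults)."""

    population_size: int = 50
    max_generations: int = 20
    mutation_prob: float = 0.05  # per grid feature, per generation
    max_features: int = 75
    n_components: int = 26
    fitness_weights: tuple[float, float] = (0.5, 0.5)  # (w_cal, w_loo)
    elitism: int = 1
    tournament_size: int = 2
    target_fitness: float = 1.0
    cv_folds: int | None = None  # None = exact LOO inside the fitness
    seed: int = 0

    @property
    def min_features(self) -> int:
        return self.n_components + 1

    def __post_init__(self) -> None:
        if min(self.population_size, self.max_generations, self.elitism + 1,
               self.tournament_size, self.n_components, self.max_features) < 1:
            raise ValueError("all GA counts must be positive")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        w = self.fitness_weights
        if min(w) < 0 or abs(sum(w) - 1.0) > 1e-12:
            raise ValueError("fitness_weights must be nonnegative and sum to 1")
        if self.max_features < self.min_features:
            raise ValueError(
                f"max_features={self.max_features} < min_features="
                f"{self.min_features} (n_components + 1)"
            )


@dataclass
class GAResult:
    """Outcome of one GA run."""

    best_subset: Chromosome
    best_fitness: float
    trajectory: list[tuple[float, float]]  # (best, mean) fitness per generation
    generations_run: int
    fitness_components: tuple[float, float]  # (r_calibration, r_LOO) of the best


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------
def _check_bounds(subset: Chromosome, cfg: GAConfig, p: int) -> None:
    if subset.size < cfg.min_features:
        raise ValueError(
            f"subset size {subset.size} < minimum {cfg.min_features} "
            f"(n_components + 1)"
        )
    if subset.size > cfg.max_features:
        raise ValueError(f"subset size {subset.size} > maximum {cfg.max_features}")
    if subset.features and (subset.features[0] < 0 or subset.features[-1] >= p):
        raise ValueError(f"subset indices outside grid 0..{p - 1}")


def _stratified_fold_accuracy(train: SpectraSet, n_components: int, k: int) -> float:
    """Deterministic stratified k-fold CV accuracy (fraction correct).

    Folds are assigned round-robin within each class (no randomness), so a
    given subset always maps to the same folds and fitness values can be
    cached safely.
    """
    labels = train.label_array()
    fold = np.empty(train.n_samples, dtype=int)
    for c in train.class_order:
        idx = np.flatnonzero(labels == c)
        fold[idx] = np.arange(idx.size) % k
    correct = 0
    for f in range(k):
        mask = fold != f
        if mask.sum() < n_components + 1 or (~mask).sum() == 0:
            continue
        clf = PLSDAClassifier(
            n_components=n_components, class_order=train.class_order
        ).fit(train.absorbance[mask], labels[mask])
        pred = clf.predict(train.absorbance[~mask])
        correct += int(np.sum(pred == labels[~mask]))
    return correct / train.n_samples


def fitness(
    train: SpectraSet, subset: Chromosome, cfg: GAConfig
) -> tuple[float, float, float]:
    """(fitness, r_calibration, r_LOO) of one feature subset.

    ``fitness = w_cal * r_calibration + w_loo * r_LOO`` with both
    accuracies as fractions.  The internal-validation term is exact LOO by
    default; ``cfg.cv_folds`` switches to stratified k-fold for large runs.
    """
    _check_bounds(subset, cfg, train.n_features)
    sub = train.select_features(subset.features)
    r_cal = overall_accuracy(train_confusion(sub, cfg.n_components)) / 100.0
    if cfg.cv_folds is None:
        r_loo = overall_accuracy(loo_cv(sub, cfg.n_components)) / 100.0
    else:
        r_loo = _stratified_fold_accuracy(sub, cfg.n_components, cfg.cv_folds)
    w_cal, w_loo = cfg.fitness_weights
    return w_cal * r_cal + w_loo * r_loo, r_cal, r_loo


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------
def init_population(cfg: GAConfig, p: int, rng: np.random.Generator) -> list[Chromosome]:
    """Random subsets with sizes uniform in [min_features, max_features]."""
    if p < cfg.min_features:
        raise ValueError(f"grid size {p} < minimum subset size {cfg.min_features}")
    hi = min(cfg.max_features, p)
    pop = []
    for _ in range(cfg.population_size):
        size = int(rng.integers(cfg.min_features, hi + 1))
        pop.append(Chromosome(rng.choice(p, size=size, replace=False)))
    return pop


def crossover(
    parent_a: Chromosome, parent_b: Chromosome, cfg: GAConfig, rng: np.random.Generator
) -> Chromosome:
    """Child drawn from the union of the parents, sized like one of them."""
    union = np.asarray(sorted(set(parent_a.features) | set(parent_b.features)))
    size = parent_a.size if rng.random() < 0.5 else parent_b.size
    size = int(np.clip(size, cfg.min_features, min(cfg.max_features, union.size)))
    return Chromosome(rng.choice(union, size=size, replace=False))


def toggle_mask(p: int, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of grid features to toggle this generation."""
    return rng.random(p) < prob


def mutate(
    subset: Chromosome, cfg: GAConfig, p: int, rng: np.random.Generator
) -> Chromosome:
    """Toggle each grid feature with ``mutation_prob``, then repair to bounds.

    Toggling adds absent features and removes present ones; the repaired
    result is clamped back into [min_features, max_features] by random
    removal/addition so every offspring stays feasible.
    """
    mask = toggle_mask(p, cfg.mutation_prob, rng)
    current = np.zeros(p, dtype=bool)
    current[subset.as_array()] = True
    current ^= mask
    chosen = np.flatnonzero(current)
    hi = min(cfg.max_features, p)
    if chosen.size > hi:
        chosen = rng.choice(chosen, size=hi, replace=False)
    elif chosen.size < cfg.min_features:
        absent = np.flatnonzero(~np.isin(np.arange(p), chosen))
        extra = rng.choice(absent, size=cfg.min_features - chosen.size, replace=False)
        chosen = np.concatenate([chosen, extra])
    return Chromosome(chosen)


def _tournament(
    scored: list[tuple[Chromosome, float]], k: int, rng: np.random.Generator
) -> Chromosome:
    idx = rng.integers(0, len(scored), size=k)
    best = max(idx, key=lambda i: scored[i][1])
    return scored[best][0]


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------
def run_ga(train: SpectraSet, cfg: GAConfig) -> GAResult:
    """Evolve feature subsets maximizing the calibration+LOO fitness.

    Deterministic for a fixed ``cfg.seed``.  The trajectory records the
    (best, mean) population fitness of the initial population and of each
    subsequent generation; with ``elitism >= 1`` the best is non-decreasing.
    """
    p = train.n_features
    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple[int, ...], tuple[float, float, float]] = {}

    def evaluate(ch: Chromosome) -> tuple[float, float, float]:
        key = ch.features
        if key not in cache:
            cache[key] = fitness(train, ch, cfg)
        return cache[key]

    population = init_population(cfg, p, rng)
    scored = [(ch, evaluate(ch)[0]) for ch in population]
    trajectory: list[tuple[float, float]] = []
    generations_run = 0

    def record() -> float:
        fits = [f for _, f in scored]
        trajectory.append((max(fits), float(np.mean(fits))))
        return max(fits)

    best = record()
    while generations_run < cfg.max_generations and best < cfg.target_fitness:
        ranked = sorted(scored, key=lambda t: -t[1])
        next_pop: list[Chromosome] = [ch for ch, _ in ranked[: cfg.elitism]]
        while len(next_pop) < cfg.population_size:
            pa = _tournament(scored, cfg.tournament_size, rng)
            pb = _tournament(scored, cfg.tournament_size, rng)
            child = mutate(crossover(pa, pb, cfg, rng), cfg, p, rng)
            _check_bounds(child, cfg, p)  # hard invariant of the loop
            next_pop.append(child)
        population = next_pop
        scored = [(ch, evaluate(ch)[0]) for ch in population]
        generations_run += 1
        best = record()

    best_ch, best_fit = max(scored, key=lambda t: t[1])
    _, r_cal, r_loo = evaluate(best_ch)
    return GAResult(
        best_subset=best_ch,
        best_fitness=best_fit,
        trajectory=trajectory,
        generations_run=generations_run,
        fitness_components=(r_cal, r_loo),
    )
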