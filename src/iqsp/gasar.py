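"""GA-SAR: genetic-algorithm wrapper feature selection with a usefulness profile.

The goal is a minimal subset of m informative property features (m in
[m_min, m_max]) that maximizes SVM cross-validation accuracy.  Each
chromosome carries a binary mask over the candidate features plus two integer
exponent genes encoding the SVM hyperparameters C = 2^c_exp and
gamma = 2^g_exp, both in [-8, 8], so model selection evolves jointly with
feature selection.

Before evolution starts, a self-assessment report (SAR) scores every feature
once: a good feature is highly correlated with the class labels but
uncorrelated with the other features.  Here

    usefulness_j = minmax( |corr(x_j, y)| - mean_{k != j} |corr(x_j, x_k)| )

scaled to [0, 1].  The profile biases mutation: deletions prefer low-usefulness
features (probability proportional to 1 - usefulness) and additions prefer
high-usefulness ones (proportional to usefulness), with a repair step keeping
the selected-feature count inside [m_min, m_max].

One fixed 10-fold partition (from the run seed) is used for every fitness
evaluation within a run so chromosomes are compared on identical folds, and
fitness values are memoized.  Elitism of one makes the best-fitness history
non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence
import warnings

import numpy as np
from sklearn.svm import SVC

from .featurize import FeatureMatrix
from .svm_model import _make_folds

__all__ = [
    "Chromosome",
    "SarProfile",
    "GasarConfig",
    "GasarResult",
    "compute_sar_profile",
    "evaluate_fitness",
    "tournament_select",
    "crossover_20pt",
    "sar_mutate",
    "run_gasar",
]

EXP_MIN, EXP_MAX = -8, 8


@dataclass(frozen=True)
class Chromosome:
    """One GA individual: feature mask + SVM hyperparameter exponent genes."""

    mask: np.ndarray  # boolean, one entry per candidate feature
    c_exp: int
    g_exp: int
    fitness: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if not (EXP_MIN <= self.c_exp <= EXP_MAX):
            raise ValueError(f"c_exp {self.c_exp} outside [{EXP_MIN}, {EXP_MAX}]")
        if not (EXP_MIN <= self.g_exp <= EXP_MAX):
            raise ValueError(f"g_exp {self.g_exp} outside [{EXP_MIN}, {EXP_MAX}]")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def key(self) -> tuple:
        return (self.mask.tobytes(), self.c_exp, self.g_exp)


@dataclass(frozen=True)
class SarProfile:
    """Per-feature usefulness in [0, 1] (the self-assessment report)."""

    usefulness: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.usefulness, dtype=float)
        if u.ndim != 1:
            raise ValueError("usefulness must be 1-D")
        if (u < 0).any() or (u > 1).any():
            raise ValueError("usefulness values must lie in [0, 1]")
        object.__setattr__(self, "usefulness", u)

    def __len__(self) -> int:
        return len(self.usefulness)


@dataclass(frozen=True)
class GasarConfig:
    """Evolution settings; defaults follow the published procedure."""

    population_size: int = 50
    generations: int = 50
    m_min: int = 5
    m_max: int = 20
    tournament_size: int = 2
    crossover_points: int = 20
    exponent_mut_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.m_min <= self.m_max):
            raise ValueError("need 1 <= m_min <= m_max")
        if self.tournament_size < 1 or self.population_size < 2:
            raise ValueError("tournament_size >= 1 and population_size >= 2")


@dataclass(frozen=True)
class GasarResult:
    """Best-ever chromosome plus per-generation (best, mean) fitness history."""

    best: Chromosome
    history: tuple[tuple[int, float, float], ...]  # (generation, best, mean)
    selected_names: tuple[str, ...]
    config: GasarConfig


def compute_sar_profile(matrix: FeatureMatrix, y: Sequence[int]) -> SarProfile:
    """Relevance-minus-redundancy usefulness, minmax-scaled to [0, 1].

    Constant features contribute zero to both correlation terms (with a
    warning) and end up at the bottom of the profile.
    """
    X = matrix.values
    yv = np.asarray(y, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); their correlations "
            "are treated as 0",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=0)
    sd_safe = np.where(constant, 1.0, sd)
    Z = Xc / sd_safe
    Z[:, constant] = 0.0
    n = X.shape[0]
    yc = yv - yv.mean()
    y_sd = yv.std()
    relevance = np.zeros(X.shape[1])
    if y_sd > 0:
        relevance = np.abs(Z.T @ yc) / (n * y_sd)
    # |corr| matrix via standardized columns; constant columns give 0 rows
    C = np.abs(Z.T @ Z) / n
    np.fill_diagonal(C, 0.0)
    p = X.shape[1]
    redundancy = C.sum(axis=1) / max(p - 1, 1)
    raw = relevance - redundancy
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        scaled = (raw - lo) / (hi - lo)
    else:
        scaled = np.full(p, 0.5)
    return SarProfile(scaled)


def evaluate_fitness(
    chrom: Chromosome,
    matrix: FeatureMatrix,
    y: Sequence[int],
    folds,
) -> float:
    """Mean 10-fold CV accuracy of the chromosome's SVM on its feature subset.

    *folds* is the fixed partition shared by all evaluations of one GA run;
    passing an integer builds the partition from that seed.
    """
    if chrom.n_selected == 0:
        raise ValueError("chromosome selects no features")
    X = matrix.values[:, chrom.mask]
    yv = np.asarray(y, dtype=int)
    if isinstance(folds, int):
        folds = _make_folds(yv, folds)
    C, gamma = 2.0**chrom.c_exp, 2.0**chrom.g_exp
    accs = []
    for tr, te in folds:
        svc = SVC(C=C, gamma=gamma, kernel="rbf")
        svc.fit(X[tr], yv[tr])
        accs.append(float(np.mean(svc.predict(X[te]) == yv[te])))
    return float(np.mean(accs))


def _better(a: Chromosome, b: Chromosome) -> bool:
    """True if *a* beats *b*: higher fitness, then fewer features, then lower C."""
    fa = -np.inf if a.fitness is None else a.fitness
    fb = -np.inf if b.fitness is None else b.fitness
    return (fa, -a.n_selected, -a.c_exp) > (fb, -b.n_selected, -b.c_exp)


def tournament_select(
    population: Sequence[Chromosome], k: int, rng: np.random.Generator
) -> Chromosome:
    """Best of *k* members sampled without replacement."""
    if not population:
        raise ValueError("empty population")
    k = min(k, len(population))
    idx = rng.choice(len(population), size=k, replace=False)
    best = population[idx[0]]
    for i in idx[1:]:
        if _better(population[i], best):
            best = population[i]
    return best


def crossover_20pt(
    parent_a: Chromosome,
    parent_b: Chromosome,
    rng: np.random.Generator,
    n_points: int = 20,
) -> tuple[Chromosome, Chromosome]:
    """Multi-point crossover on the mask; exponent genes inherited atomically.

    ``n_points`` distinct cut points are drawn over the mask (clamped to the
    mask length minus one for short masks); alternating segments are swapped.
    Each child inherits its (c_exp, g_exp) pair as a unit from one parent.
    """
    if parent_a.mask.shape != parent_b.mask.shape:
        raise ValueError("parent masks must have equal length")
    L = len(parent_a.mask)
    n_points = min(n_points, L - 1)
    cuts = np.sort(rng.choice(np.arange(1, L), size=n_points, replace=False))
    swap = np.zeros(L, dtype=bool)
    toggle = False
    prev = 0
    for cut in list(cuts) + [L]:
        if toggle:
            swap[prev:cut] = True
        toggle = not toggle
        prev = cut
    mask_a = np.where(swap, parent_b.mask, parent_a.mask)
    mask_b = np.where(swap, parent_a.mask, parent_b.mask)
    exps_a = parent_a if rng.random() < 0.5 else parent_b
    exps_b = parent_a if rng.random() < 0.5 else parent_b
    child_a = Chromosome(mask_a, exps_a.c_exp, exps_a.g_exp)
    child_b = Chromosome(mask_b, exps_b.c_exp, exps_b.g_exp)
    return child_a, child_b


def _weighted_pick(
    indices: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> int:
    total = weights.sum()
    if total <= 0:
        return int(rng.choice(indices))
    return int(rng.choice(indices, p=weights / total))


def sar_mutate(
    chrom: Chromosome,
    profile: SarProfile,
    config: GasarConfig,
    rng: np.random.Generator,
) -> Chromosome:
    """SAR-guided mutation: one usefulness-biased delete and add attempt,
    then repair of the selected-feature count into [m_min, m_max]; exponent
    genes are perturbed by +/-1 with probability ``exponent_mut_prob``.
    """
    if len(profile) != len(chrom.mask):
        raise ValueError("profile length must match the feature space")
    mask = chrom.mask.copy()
    u = profile.usefulness

    def delete_one() -> None:
        sel = np.flatnonzero(mask)
        if sel.size > 1:
            mask[_weighted_pick(sel, 1.0 - u[sel], rng)] = False

    def add_one() -> None:
        unsel = np.flatnonzero(~mask)
        if unsel.size:
            mask[_weighted_pick(unsel, u[unsel], rng)] = True

    delete_one()
    add_one()
    # repair into [m_min, m_max]
    while mask.sum() > config.m_max:
        delete_one()
    while mask.sum() < config.m_min:
        add_one()

    def perturb(exp: int) -> int:
        if rng.random() < config.exponent_mut_prob:
            exp += int(rng.choice([-1, 1]))
        return int(np.clip(exp, EXP_MIN, EXP_MAX))

    return Chromosome(mask, perturb(chrom.c_exp), perturb(chrom.g_exp))


def _random_chromosome(
    n_features: int, config: GasarConfig, rng: np.random.Generator
) -> Chromosome:
    m = int(rng.integers(config.m_min, min(config.m_max, n_features) + 1))
    mask = np.zeros(n_features, dtype=bool)
    mask[rng.choice(n_features, size=m, replace=False)] = True
    c_exp = int(rng.integers(EXP_MIN, EXP_MAX + 1))
    g_exp = int(rng.integers(EXP_MIN, EXP_MAX + 1))
    return Chromosome(mask, c_exp, g_exp)


def run_gasar(
    matrix: FeatureMatrix, y: Sequence[int], config: GasarConfig
) -> GasarResult:
    """Evolve feature subsets and SVM hyperparameters; fully seed-reproducible.

    Returns the best-ever chromosome (ties broken by fewer features, then
    smaller C) and the per-generation (best, mean) fitness history.
    """
    yv = np.asarray(y, dtype=int)
    if len(yv) < 20:
        raise ValueError("need at least 20 samples for 10-fold CV fitness")
    n_features = matrix.n_features
    rng = np.random.default_rng(config.seed)
    folds = _make_folds(yv, config.seed)
    profile = compute_sar_profile(matrix, yv)
    cache: dict[tuple, float] = {}

    def fitness_of(ch: Chromosome) -> Chromosome:
        if ch.fitness is not None:
            return ch
        key = ch.key()
        if key not in cache:
            cache[key] = evaluate_fitness(ch, matrix, yv, folds)
        return replace(ch, fitness=cache[key])

    population = [
        fitness_of(_random_chromosome(n_features, config, rng))
        for _ in range(config.population_size)
    ]
    best_ever = population[0]
    for ch in population[1:]:
        if _better(ch, best_ever):
            best_ever = ch
    history: list[tuple[int, float, float]] = []

    def record(gen: int) -> None:
        fits = np.array([c.fitness for c in population])
        history.append((gen, float(fits.max()), float(fits.mean())))

    record(0)
    for gen in range(1, config.generations + 1):
        next_pop = [best_ever]  # elitism of 1
        while len(next_pop) < config.population_size:
            pa = tournament_select(population, config.tournament_size, rng)
            pb = tournament_select(population, config.tournament_size, rng)
            ca, cb = crossover_20pt(pa, pb, rng, config.crossover_points)
            for child in (ca, cb):
                if len(next_pop) < config.population_size:
                    mutated = sar_mutate(child, profile, config, rng)
                    next_pop.append(fitness_of(mutated))
        population = next_pop
        for ch in population:
            if _better(ch, best_ever):
                best_ever = ch
        record(gen)
    selected = tuple(
        matrix.feature_names[j] for j in np.flatnonzero(best_ever.mask)
    )
    return GasarResult(best_ever, tuple(history), selected, config)
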