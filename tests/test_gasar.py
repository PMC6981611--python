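"""GA-SAR operators: profile, selection, crossover, mutation, evolution."""

import numpy as np
import pytest

from iqsp.featurize import FeatureMatrix, standardize
from iqsp.gasar import (
    Chromosome,
    GasarConfig,
    SarProfile,
    compute_sar_profile,
    crossover_20pt,
    evaluate_fitness,
    run_gasar,
    sar_mutate,
    tournament_select,
)
from iqsp.synthetic import PlantedDataSpec, generate_planted


def brute_force_usefulness(X, y):
    """Independent recomputation: |corr with y| minus mean |corr with others|."""
    p = X.shape[1]
    raw = np.empty(p)
    for j in range(p):
        rel = abs(np.corrcoef(X[:, j], y)[0, 1])
        red = np.mean(
            [abs(np.corrcoef(X[:, j], X[:, k])[0, 1]) for k in range(p) if k != j]
        )
        raw[j] = rel - red
    return (raw - raw.min()) / (raw.max() - raw.min())


def chrom(mask, c_exp=0, g_exp=0, fitness=None):
    return Chromosome(np.asarray(mask, dtype=bool), c_exp, g_exp, fitness)


class TestSarProfile:
    def test_label_copy_feature_scores_one_and_duplicate_scores_minimum(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.array([1, -1] * (n // 2))
        noise = rng.standard_normal((n, 3))
        dup = noise[:, 0] + 1e-9 * rng.standard_normal(n)
        X = np.column_stack([y.astype(float), noise, dup])
        fm = FeatureMatrix(tuple("abcde"), X)
        profile = compute_sar_profile(fm, y)
        assert profile.usefulness[0] == pytest.approx(1.0)
        assert profile.usefulness[4] == pytest.approx(
            profile.usefulness.min(), abs=1e-6
        )

    def test_matches_brute_force_oracle_on_planted_data(self):
        fm, y, _ = generate_planted(
            PlantedDataSpec(200, 20, tuple(range(6)), delta=2.0, seed=14)
        )
        profile = compute_sar_profile(fm, y)
        oracle = brute_force_usefulness(fm.values, y)
        assert profile.usefulness == pytest.approx(oracle, abs=1e-10)
        assert profile.usefulness[:6].mean() > profile.usefulness[6:].mean()

    def test_constant_feature_is_flagged_not_fatal(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        y = np.array([1, -1] * 10)
        with pytest.warns(UserWarning, match="constant"):
            profile = compute_sar_profile(FeatureMatrix(("c", "v"), X), y)
        assert len(profile) == 2

    def test_profile_bounds_are_enforced(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            SarProfile(np.array([0.5, 1.5]))


class TestFitness:
    def test_deterministic_for_fixed_fold_seed(self):
        fm, y, mask = generate_planted(
            PlantedDataSpec(30, 8, (0, 1), delta=2.0, seed=3)
        )
        c = chrom(mask)
        assert evaluate_fitness(c, fm, y, folds=7) == evaluate_fitness(
            c, fm, y, folds=7
        )

    def test_permuted_labels_score_near_chance(self):
        fm, y, mask = generate_planted(
            PlantedDataSpec(100, 8, (0, 1), delta=3.0, seed=4)
        )
        y_perm = np.random.default_rng(5).permutation(y)
        acc = evaluate_fitness(chrom(mask), fm, y_perm, folds=0)
        assert 0.4 <= acc <= 0.6

    def test_empty_mask_is_rejected(self):
        fm, y, _ = generate_planted(PlantedDataSpec(30, 4, (0,), seed=0))
        with pytest.raises(ValueError, match="no features"):
            evaluate_fitness(chrom([0, 0, 0, 0]), fm, y, folds=0)


class TestTournament:
    def setup_method(self):
        self.pop = [
            chrom([1, 0, 0, 0], fitness=0.6),
            chrom([1, 1, 0, 0], fitness=0.9),
            chrom([1, 1, 1, 0], fitness=0.8),
        ]

    def test_full_tournament_returns_global_best(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert tournament_select(self.pop, 3, rng).fitness == 0.9

    def test_k1_is_a_uniform_draw(self):
        rng = np.random.default_rng(1)
        picks = {tournament_select(self.pop, 1, rng).fitness for _ in range(60)}
        assert picks == {0.6, 0.8, 0.9}

    def test_pairwise_prefers_higher_fitness(self):
        rng = np.random.default_rng(2)
        two = self.pop[:2]
        assert tournament_select(two, 2, rng).fitness == 0.9

    def test_fitness_tie_breaks_by_fewer_features(self):
        tied = [chrom([1, 1, 1, 1], fitness=0.9), chrom([1, 0, 0, 0], fitness=0.9)]
        rng = np.random.default_rng(3)
        assert tournament_select(tied, 2, rng).n_selected == 1


class TestCrossover:
    def test_identical_parents_yield_identical_children(self):
        rng = np.random.default_rng(0)
        p = chrom([1, 0, 1, 0, 1, 1, 0, 0], c_exp=2, g_exp=-3)
        a, b = crossover_20pt(p, p, rng, n_points=3)
        assert np.array_equal(a.mask, p.mask) and np.array_equal(b.mask, p.mask)
        assert (a.c_exp, a.g_exp) == (2, -3)

    def test_per_position_bits_are_conserved(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            pa = chrom(rng.integers(0, 2, size=40))
            pb = chrom(rng.integers(0, 2, size=40))
            ca, cb = crossover_20pt(pa, pb, rng)
            parents = pa.mask.astype(int) + pb.mask.astype(int)
            children = ca.mask.astype(int) + cb.mask.astype(int)
            assert np.array_equal(parents, children)

    def test_complementary_masks_split_the_length(self):
        rng = np.random.default_rng(2)
        pa = chrom([1, 0] * 10)
        pb = chrom([0, 1] * 10)
        ca, cb = crossover_20pt(pa, pb, rng)
        assert ca.n_selected + cb.n_selected == 20

    def test_exponent_genes_are_inherited_atomically(self):
        rng = np.random.default_rng(3)
        pa = chrom([1] * 10, c_exp=5, g_exp=-5)
        pb = chrom([0] * 10, c_exp=-7, g_exp=7)
        for _ in range(20):
            for child in crossover_20pt(pa, pb, rng):
                assert (child.c_exp, child.g_exp) in {(5, -5), (-7, 7)}


class TestSarMutate:
    def setup_method(self):
        self.config = GasarConfig(m_min=5, m_max=20, seed=0)

    def test_overfull_mask_is_repaired_down(self):
        rng = np.random.default_rng(0)
        profile = SarProfile(np.linspace(0, 1, 30))
        c = chrom([1] * 25 + [0] * 5)
        assert sar_mutate(c, profile, self.config, rng).n_selected <= 20

    def test_underfull_mask_is_repaired_up(self):
        rng = np.random.default_rng(1)
        profile = SarProfile(np.linspace(0, 1, 30))
        c = chrom([1, 1, 1] + [0] * 27)
        assert sar_mutate(c, profile, self.config, rng).n_selected >= 5

    def test_degenerate_profile_forces_the_useful_feature_in(self):
        # all usefulness mass on one unselected feature; repair must add it
        u = np.zeros(10)
        u[7] = 1.0
        c = chrom([1, 1] + [0] * 8)
        config = GasarConfig(m_min=3, m_max=5, seed=0)
        out = sar_mutate(c, SarProfile(u), config, np.random.default_rng(2))
        assert out.mask[7]

    def test_exponents_stay_in_range(self):
        rng = np.random.default_rng(3)
        profile = SarProfile(np.full(10, 0.5))
        config = GasarConfig(m_min=2, m_max=8, exponent_mut_prob=1.0, seed=0)
        c = chrom([1] * 5 + [0] * 5, c_exp=8, g_exp=-8)
        for _ in range(20):
            out = sar_mutate(c, profile, config, rng)
            assert -8 <= out.c_exp <= 8 and -8 <= out.g_exp <= 8


@pytest.fixture(scope="module")
def tiny_run():
    fm, y, _ = generate_planted(
        PlantedDataSpec(25, 12, (0, 1), delta=4.0, seed=6)
    )
    z = standardize(fm)
    config = GasarConfig(
        population_size=8, generations=4, m_min=2, m_max=6, seed=42
    )
    return z, y, config, run_gasar(z, y, config)


class TestRunGasar:
    def test_history_best_fitness_is_non_decreasing(self, tiny_run):
        _, _, _, result = tiny_run
        best = [b for _, b, _ in result.history]
        assert best == sorted(best)
        assert len(result.history) == 5  # initial population + 4 generations

    def test_best_chromosome_respects_invariants(self, tiny_run):
        _, _, config, result = tiny_run
        assert config.m_min <= result.best.n_selected <= config.m_max
        assert -8 <= result.best.c_exp <= 8
        assert result.selected_names == tuple(
            name
            for name, bit in zip(
                ("SYNF%06d" % (j + 1) for j in range(12)), result.best.mask
            )
            if bit
        )

    def test_identical_seeds_reproduce_the_run(self, tiny_run):
        z, y, config, result = tiny_run
        again = run_gasar(z, y, config)
        assert again.history == result.history
        assert np.array_equal(again.best.mask, result.best.mask)

    def test_too_few_samples_for_cv_is_rejected(self):
        fm, y, _ = generate_planted(PlantedDataSpec(8, 6, (0,), seed=1))
        with pytest.raises(ValueError, match="20 samples"):
            run_gasar(fm, y, GasarConfig(m_min=2, m_max=4))
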