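"""Sparrow search: update-rule contracts, convergence, oracle equivalence."""
import numpy as np
import pytest

from lesionforge.exceptions import ValidationError
from lesionforge.fcedn import SearchSpace, TrainConfig, default_layout
from lesionforge.spasa import (ArchitectureObjective, FitnessContext,
                               OptimizerConfig, SparrowSearch, evaluate_fitness,
                               initialize_population, optimize, producer_update,
                               scout_update, scrounger_update)


@pytest.fixture(scope="module")
def arch_space():
    return SearchSpace.from_layout(default_layout())


@pytest.fixture
def box5():
    return SearchSpace(lower=np.full(5, -5.0), upper=np.full(5, 5.0),
                       integer=np.zeros(5, bool))


def sphere(x):
    return -float(np.sum(np.asarray(x) ** 2))


class TestInitialization:
    def test_population_shape_and_bounds(self, arch_space):
        cfg = OptimizerConfig(population_size=10, seed=0)
        pop = initialize_population(arch_space, cfg)
        assert pop.positions.shape == (10, 22)
        assert np.all(pop.positions >= arch_space.lower)
        assert np.all(pop.positions <= arch_space.upper)

    def test_same_seed_same_population(self, arch_space):
        cfg = OptimizerConfig(population_size=8, seed=3)
        a = initialize_population(arch_space, cfg)
        b = initialize_population(arch_space, cfg)
        assert np.array_equal(a.positions, b.positions)

    def test_pooled_kernel_size_genes_respect_bounds(self, arch_space):
        layout = default_layout()
        ks_cols = [i for i, g in enumerate(layout.genes) if g.name.endswith("_ks")]
        pooled = []
        for seed in range(100):   # 100 pops x 10 birds -> 1000+ genes pooled
            pop = initialize_population(arch_space,
                                        OptimizerConfig(population_size=10, seed=seed))
            pooled.append(pop.positions[:, ks_cols])
        pooled = np.concatenate(pooled).ravel()
        assert pooled.min() >= 3.0 and pooled.max() <= 5.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            OptimizerConfig(population_size=2).validate()
        with pytest.raises(ValidationError):
            OptimizerConfig(producer_fraction=1.5).validate()


class TestUpdateRules:
    def _evaluated_pop(self, space, cfg, objective=sphere):
        rng = np.random.default_rng(cfg.seed)
        pop = initialize_population(space, cfg, rng)
        pop.fitnesses = np.array([objective(x) for x in pop.positions])
        pop.record_best()
        return pop, rng

    def test_producer_update_respects_bounds(self, box5):
        cfg = OptimizerConfig(population_size=10, seed=1)
        pop, rng = self._evaluated_pop(box5, cfg)
        producer_update(pop, cfg, rng, box5)
        assert np.all(pop.positions >= box5.lower)
        assert np.all(pop.positions <= box5.upper)

    def test_updates_deterministic_in_seed(self, box5):
        cfg = OptimizerConfig(population_size=10, seed=2)
        results = []
        for _ in range(2):
            pop, rng = self._evaluated_pop(box5, cfg)
            producer_update(pop, cfg, rng, box5)
            scrounger_update(pop, cfg, rng, box5)
            scout_update(pop, cfg, rng, box5)
            results.append(pop.positions.copy())
        assert np.array_equal(results[0], results[1])

    def test_scroungers_fixed_when_population_identical(self, box5):
        cfg = OptimizerConfig(population_size=6, seed=0)
        pop, rng = self._evaluated_pop(box5, cfg)
        point = pop.positions[0].copy()
        pop.positions = np.tile(point, (6, 1))
        pop.fitnesses = np.full(6, sphere(point))
        pop.best_position, pop.best_fitness = point.copy(), sphere(point)
        scrounger_update(pop, cfg, rng, box5)
        assert np.array_equal(pop.positions, np.tile(point, (6, 1)))

    def test_scrounger_moves_flock_toward_best(self, box5):
        moved_closer = 0
        for seed in range(50):
            cfg = OptimizerConfig(population_size=10, seed=seed)
            pop, rng = self._evaluated_pop(box5, cfg)
            d0 = np.linalg.norm(pop.positions - pop.best_position, axis=1).mean()
            scrounger_update(pop, cfg, rng, box5)
            d1 = np.linalg.norm(pop.positions - pop.best_position, axis=1).mean()
            moved_closer += d1 < d0
        assert moved_closer > 25

    def test_zero_scout_fraction_leaves_population_unchanged(self, box5):
        cfg = OptimizerConfig(population_size=10, scout_fraction=0.0, seed=5)
        pop, rng = self._evaluated_pop(box5, cfg)
        before = pop.positions.copy()
        scout_update(pop, cfg, rng, box5)
        assert np.array_equal(before, pop.positions)


class TestOptimize:
    def test_sphere_optimum_found(self, box5):
        cfg = OptimizerConfig(population_size=30, iterations=100, seed=1)
        _, best, trace = optimize(box5, sphere, cfg)
        assert best >= -0.01
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_shifted_sphere_no_origin_freebie(self, box5):
        cfg = OptimizerConfig(population_size=30, iterations=100, seed=2)
        _, best, _ = optimize(box5, lambda x: -np.sum((x - 2.34) ** 2), cfg)
        assert best >= -0.01

    def test_matches_exhaustive_search_on_discrete_space(self):
        space = SearchSpace(lower=np.zeros(2), upper=np.full(2, 7.0),
                            integer=np.ones(2, bool))

        def objective(x):
            xi = np.round(np.asarray(x))
            return -((xi[0] - 5) ** 2 + (xi[1] - 2) ** 2) + 0.5 * np.sin(xi[0] * xi[1])

        brute = max(objective(np.array([i, j], float))
                    for i in range(8) for j in range(8))
        for seed in range(3):
            cfg = OptimizerConfig(population_size=20, iterations=60, seed=seed)
            _, best, _ = optimize(space, objective, cfg)
            assert best == pytest.approx(brute)

    def test_planted_architecture_recovery(self, arch_space):
        planted = arch_space.round_clip(
            arch_space.sample(1, np.random.default_rng(99))[0])
        successes = 0
        for seed in range(1, 6):
            cfg = OptimizerConfig(population_size=30, iterations=200, seed=seed)
            best, _, _ = optimize(arch_space,
                                  lambda x: -np.sum((x - planted) ** 2), cfg)
            rec = arch_space.round_clip(best)
            successes += np.all(rec[arch_space.integer] == planted[arch_space.integer])
        assert successes >= 4

    def test_non_finite_objective_recorded_as_minus_inf(self, box5):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            return np.nan if calls["n"] % 3 == 0 else sphere(x)

        cfg = OptimizerConfig(population_size=6, iterations=5, seed=0)
        _, best, trace = optimize(box5, flaky, cfg)
        assert np.isfinite(best)
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_feasibility_after_every_iteration(self, box5):
        seen = []

        def recording(x):
            seen.append(np.asarray(x).copy())
            return sphere(x)

        optimize(box5, recording, OptimizerConfig(population_size=6, iterations=10,
                                                  seed=0))
        stacked = np.vstack(seen)
        assert np.all(stacked >= box5.lower - 1e-12)
        assert np.all(stacked <= box5.upper + 1e-12)

    def test_sparrow_search_facade_summary(self, box5):
        res = SparrowSearch(box5, sphere,
                            OptimizerConfig(population_size=10, iterations=10,
                                            seed=0)).fit()
        assert "best fitness" in res.summary()
        assert res.trace[-1] == res.best_fitness


class TestFitness:
    def _context(self, images):
        return FitnessContext(train_images=images[:4], eval_images=images[4:6],
                              train_cfg=TrainConfig(epochs=1, batch_size=4, seed=0),
                              epsilon=1.0)

    def test_smoothed_jaccard_sum_matches_brute_force(self, small_dataset):
        from lesionforge.fcedn import FCEDN, decode
        layout = default_layout()
        space = SearchSpace.from_layout(layout)
        ctx = self._context(small_dataset)
        vec = space.sample(1, np.random.default_rng(0))[0]
        spec = decode(vec, space, layout)
        fit = evaluate_fitness(vec, ctx)
        # brute force: retrain identically, then per-pixel set counting
        model = FCEDN(spec, seed=0)
        model.fit(ctx.train_images, ctx.train_cfg)
        total = 0.0
        for img in ctx.eval_images:
            pred = model.predict_mask(img)
            inter = sum(int(p == 1 and t == 1)
                        for p, t in zip(pred.ravel(), img.mask.ravel()))
            total += (1.0 + inter) / (1.0 + int(pred.sum()) + int(img.mask.sum())
                                      - inter)
        assert fit == pytest.approx(total)
        assert 0 < fit <= len(ctx.eval_images)

    def test_perfect_and_empty_predictions_bracket_fitness(self):
        # direct check of the fitness formula end members
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        inter = float((mask & mask).sum())
        eps = 0.7
        perfect = (eps + inter) / (eps + 2 * mask.sum() - inter)
        assert perfect == pytest.approx(1.0)
        empty_pred = (1e-9 + 0.0) / (1e-9 + mask.sum())
        assert empty_pred == pytest.approx(0.0, abs=1e-8)

    def test_architecture_objective_caches_by_genome(self, small_dataset):
        layout = default_layout()
        space = SearchSpace.from_layout(layout)
        obj = ArchitectureObjective(self._context(small_dataset), space, layout)
        vec = space.sample(1, np.random.default_rng(1))[0]
        v1 = obj(vec)
        v2 = obj(vec + 1e-9)   # same rounded genome
        assert v1 == v2
        assert obj.n_trained <= 1
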