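"""Fitness function, scenario genomes and the genetic algorithm."""

import numpy as np
import pytest

from cpgwalk.controller import ControllerWeights
from cpgwalk.ga import (FitnessRecord, Genome, GAConfig, fitness,
                        make_scenario, run_ga, warm_start_utta,
                        evaluate_genome)


class TestFitness:
    def test_fall_short_of_gate(self):
        rec = FitnessRecord(distance=2.0, fell=True, cot=np.inf)
        assert fitness(rec) == pytest.approx(-1.0)

    def test_sustained_walk_includes_economy(self):
        rec = FitnessRecord(distance=5.0, fell=False, cot=10.0)
        assert fitness(rec) == pytest.approx(11.0)

    def test_lower_cost_is_better(self):
        hi = FitnessRecord(distance=5.0, fell=False, cot=10.0)
        lo = FitnessRecord(distance=5.0, fell=False, cot=5.0)
        assert fitness(lo) > fitness(hi)

    def test_no_penalty_without_fall(self):
        rec = FitnessRecord(distance=2.0, fell=False, cot=np.inf)
        assert fitness(rec) == pytest.approx(2.0)

    def test_non_faller_dominates_faller_at_equal_distance(self):
        for d in (0.5, 2.9, 3.0, 8.0):
            faller = FitnessRecord(distance=d, fell=True, cot=12.0)
            walker = FitnessRecord(distance=d, fell=False, cot=12.0)
            assert fitness(walker) > fitness(faller)

    def test_invalid_energetics_rejected(self):
        with pytest.raises(ValueError):
            fitness(FitnessRecord(distance=5.0, fell=False, cot=0.0))


class TestScenarios:
    @pytest.mark.parametrize("name,n", [("normal", 51),
                                        ("utta_symmetric", 17),
                                        ("utta_asymmetric", 33)])
    def test_genome_sizes(self, name, n):
        sc = make_scenario(name)
        assert sc.n_genes == n
        assert sc.bounds.shape == (n, 2)
        Genome(np.zeros(n), name)  # validates
        with pytest.raises(ValueError):
            Genome(np.zeros(n + 1), name)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            make_scenario("bipedal_sprint")

    def test_normal_decode_is_symmetric(self, rng):
        sc = make_scenario("normal")
        g = rng.uniform(sc.bounds[:, 0], sc.bounds[:, 1])
        w = sc.decode(g)
        assert np.array_equal(w.w_feed[0], w.w_feed[1])
        assert w.u0 == g[0]
        assert np.array_equal(w.w_cpg, g[17:28])
        assert np.array_equal(w.w_pos, g[28:51])

    def test_symmetric_utta_ties_legs_and_freezes_base(self, rng):
        base = make_scenario("normal").decode(
            rng.uniform(-1, 1, 51).clip(0, None))
        sc = make_scenario("utta_symmetric")
        g = rng.uniform(sc.bounds[:, 0], sc.bounds[:, 1])
        w = sc.decode(g, base)
        assert np.array_equal(w.w_feed[0], w.w_feed[1])
        assert np.array_equal(w.w_cpg, base.w_cpg)
        assert np.array_equal(w.w_pos, base.w_pos)

    def test_asymmetric_utta_frees_both_legs(self, rng):
        base = ControllerWeights()
        sc = make_scenario("utta_asymmetric")
        g = np.arange(33.0)
        w = sc.decode(g, base)
        assert np.array_equal(w.w_feed[0], g[1:17])
        assert np.array_equal(w.w_feed[1], g[17:33])

    def test_utta_decode_requires_base(self):
        sc = make_scenario("utta_symmetric")
        with pytest.raises(ValueError):
            sc.decode(np.zeros(17))

    def test_encode_decode_round_trip(self, rng):
        sc = make_scenario("normal")
        g = rng.uniform(sc.bounds[:, 0], sc.bounds[:, 1])
        w = sc.decode(g)
        assert np.allclose(sc.encode_from(w), g)


class TestWarmStart:
    def test_symmetric_keeps_nonscenario_genes_frozen(self, rng):
        normal = make_scenario("normal").decode(
            np.clip(rng.uniform(-1, 1, 51), 0, None))
        sc = make_scenario("utta_symmetric")
        pop = warm_start_utta(normal, sc, 8, rng)
        assert pop.shape == (8, 17)
        # first individual is the normal solution verbatim
        assert np.allclose(pop[0], sc.encode_from(normal))
        # decoded, every individual inherits the frozen blocks
        for g in pop:
            w = sc.decode(g, normal)
            assert np.array_equal(w.w_cpg, normal.w_cpg)
            assert np.array_equal(w.w_pos, normal.w_pos)

    def test_zero_noise_population_is_verbatim(self, rng):
        normal = ControllerWeights(u0=1.2)
        sc = make_scenario("utta_asymmetric")
        pop = warm_start_utta(normal, sc, 5, rng, noise_frac=0.0)
        assert np.allclose(pop, pop[0])
        assert pop.shape == (5, 33)

    def test_normal_scenario_rejected(self, rng):
        with pytest.raises(ValueError):
            warm_start_utta(ControllerWeights(), make_scenario("normal"),
                            4, rng)


def sphere_eval(genome):
    """Surrogate fitness: negative sphere function, optimum at 0.3."""
    d = np.asarray(genome) - 0.3
    rec = FitnessRecord(distance=0.0, fell=False, cot=np.inf)
    rec.fitness = -float(d @ d)
    return rec


SPHERE_BOUNDS = np.tile([[-1.0, 1.0]], (8, 1))


class TestGA:
    def test_elitism_makes_best_fitness_monotone(self):
        res = run_ga(sphere_eval, SPHERE_BOUNDS,
                     GAConfig(population=20, generations=40, seed=5))
        best = res.history["best_fitness"].to_numpy()
        assert np.all(np.diff(best) >= 0)

    def test_reproducible_per_seed(self):
        cfg = GAConfig(population=16, generations=15, seed=9)
        r1 = run_ga(sphere_eval, SPHERE_BOUNDS, cfg)
        r2 = run_ga(sphere_eval, SPHERE_BOUNDS, cfg)
        assert np.array_equal(r1.best_genome, r2.best_genome)
        assert r1.history.equals(r2.history)

    def test_different_seeds_differ(self):
        r1 = run_ga(sphere_eval, SPHERE_BOUNDS,
                    GAConfig(population=16, generations=5, seed=1))
        r2 = run_ga(sphere_eval, SPHERE_BOUNDS,
                    GAConfig(population=16, generations=5, seed=2))
        assert not np.array_equal(r1.best_genome, r2.best_genome)

    def test_bounds_respected_after_variation(self):
        bounds = np.tile([[0.0, 0.5]], (6, 1))

        def ev(g):
            assert np.all(g >= 0.0) and np.all(g <= 0.5)
            return sphere_eval(g)

        res = run_ga(ev, bounds, GAConfig(population=12, generations=20,
                                          seed=3))
        assert np.all(res.population >= 0.0)
        assert np.all(res.population <= 0.5)

    def test_sphere_convergence(self):
        res = run_ga(sphere_eval, SPHERE_BOUNDS,
                     GAConfig(population=32, generations=200, seed=1))
        assert -res.history["best_fitness"].iloc[-1] < 1e-2

    def test_pluggable_map(self):
        calls = []

        def recording_map(fn, xs):
            out = [fn(x) for x in xs]
            calls.append(len(out))
            return out

        run_ga(sphere_eval, SPHERE_BOUNDS,
               GAConfig(population=10, generations=3, seed=0),
               map_fn=recording_map)
        assert len(calls) == 3  # initial + 2 offspring generations

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population=1)
        with pytest.raises(ValueError):
            GAConfig(generations=0)


class TestEvaluateGenome:
    def test_all_zero_genome_falls_quickly(self):
        sc = make_scenario("normal")
        rec = evaluate_genome(np.zeros(51), sc, duration=2.0)
        assert rec.fell
        assert rec.distance < 1.0
        assert rec.fitness < 0.0

    def test_deterministic(self, rng):
        sc = make_scenario("normal")
        g = rng.uniform(sc.bounds[:, 0], sc.bounds[:, 1])
        r1 = evaluate_genome(g, sc, duration=1.0)
        r2 = evaluate_genome(g, sc, duration=1.0)
        assert (r1.distance, r1.fell, r1.cot, r1.fitness) == \
               (r2.distance, r2.fell, r2.cot, r2.fitness)

    def test_genome_mismatch_raises(self):
        sc = make_scenario("utta_symmetric")
        with pytest.raises(ValueError):
            evaluate_genome(np.zeros(17), sc, duration=1.0)  # no base
        with pytest.raises(ValueError):
            evaluate_genome(np.zeros(5), make_scenario("normal"))

    def test_crashed_trial_reported_as_fall(self, monkeypatch):
        import cpgwalk.ga as ga_mod

        def boom(**kw):
            raise FloatingPointError("blow-up")

        monkeypatch.setattr(ga_mod, "run_trial", boom)
        rec = evaluate_genome(np.zeros(51), make_scenario("normal"),
                              duration=1.0)
        assert rec.fell
        assert rec.distance == 0.0
        assert rec.fitness == pytest.approx(-3.0)
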