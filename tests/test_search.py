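"""Search operators, CEP mechanics, local search and the drivers."""

import math

import numpy as np
import pytest

from cepdock import (
    EvaluationContext,
    Individual,
    SearchConfig,
    cep_update,
    local_search,
    one_point_crossover,
    rank_select,
    real_mutation,
    run_cepga,
    run_ga,
)
from cepdock.search import (
    BoxSpace,
    ElitistRecord,
    PoseSpace,
    Problem,
    _rank_probabilities,
    identify_elites,
)
from cepdock.synthetic import make_landscape


def _members(energies):
    return [Individual(np.array([float(e)]), energy=float(e)) for e in energies]


class TestRankSelection:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.integers(min_value=2, max_value=200),
        s=st.floats(min_value=1.0, max_value=2.0),
    )
    def test_rank_probabilities_form_monotone_distribution(self, n, s):
        probs = _rank_probabilities(n, s)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs >= -1e-15)
        assert np.all(np.diff(probs) <= 1e-15)  # best rank first

    def test_two_member_probabilities(self):
        """Linear ranking with pressure 1.5 on P=2: best 0.75, worst 0.25."""
        probs = _rank_probabilities(2, 1.5)
        np.testing.assert_allclose(probs, [0.75, 0.25])

    def test_uniform_when_pressure_one(self):
        np.testing.assert_allclose(_rank_probabilities(5, 1.0), np.full(5, 0.2))

    def test_lower_energy_strictly_more_likely(self):
        probs = _rank_probabilities(50, 1.5)
        assert np.all(np.diff(probs) < 0)
        assert probs.sum() == pytest.approx(1.0)

    def test_empirical_frequency_matches_formula(self):
        """Monte-Carlo draw frequencies agree with the closed-form linear
        rank probability within 3 sigma."""
        members = _members(np.arange(50))
        rng = np.random.default_rng(0)
        n_draws = 100_000
        picks = rank_select(members, rng, pressure=1.5, size=n_draws)
        best_count = sum(1 for ind in picks if ind.energy == 0.0)
        p_best = _rank_probabilities(50, 1.5)[0]
        sigma = math.sqrt(n_draws * p_best * (1 - p_best))
        assert abs(best_count - n_draws * p_best) < 3 * sigma

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            rank_select([], np.random.default_rng(0))


class TestCrossover:
    def test_forced_cut_matches_definition(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([10.0, 20, 30, 40, 50])
        ca, cb = one_point_crossover(a, b, np.random.default_rng(0), cut=2)
        np.testing.assert_array_equal(ca, [1, 2, 30, 40, 50])
        np.testing.assert_array_equal(cb, [10, 20, 3, 4, 5])

    def test_identical_parents_fixed_point(self):
        a = np.arange(7.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            ca, cb = one_point_crossover(a, a.copy(), rng)
            np.testing.assert_array_equal(ca, a)
            np.testing.assert_array_equal(cb, a)

    def test_gene_multiset_conserved_over_all_cut_points(self):
        """Exhaustive over cut points on L=7: parents and children hold the
        same multiset of genes."""
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 7))
        for k in range(1, 7):
            ca, cb = one_point_crossover(a, b, rng, cut=k)
            np.testing.assert_array_equal(
                np.sort(np.concatenate([ca, cb])),
                np.sort(np.concatenate([a, b])),
            )

    def test_short_genomes_copied(self):
        a, b = np.array([1.0]), np.array([2.0])
        ca, cb = one_point_crossover(a, b, np.random.default_rng(0))
        assert ca == a and cb == b


class TestMutation:
    def _pose_space(self, n_torsions=4):
        from cepdock.synthetic import FixtureSpec, make_fixture

        fx = make_fixture(FixtureSpec(n_torsions=n_torsions, rng_seed=9),
                          quality_control=False)
        return PoseSpace(fx.topo, fx.receptor)

    def test_zero_rate_identity(self):
        space = self._pose_space()
        cfg = SearchConfig(mutation_rate=0.0)
        vec = space.random(np.random.default_rng(0))
        np.testing.assert_array_equal(
            real_mutation(vec, cfg, np.random.default_rng(1), space), vec
        )

    def test_vanishing_scale_limit(self):
        space = self._pose_space()
        cfg = SearchConfig(
            mutation_rate=1.0,
            sigma_translation=1e-12,
            sigma_rotation=1e-12,
            sigma_torsion=1e-12,
        )
        vec = space.random(np.random.default_rng(0))
        out = real_mutation(vec, cfg, np.random.default_rng(1), space)
        np.testing.assert_allclose(out, vec, atol=1e-9)

    def test_torsions_wrapped_and_displacement_matches_folded_normal(self):
        """All mutated torsions stay in (-pi, pi]; mean |step| agrees with
        the folded-normal expectation sigma*sqrt(2/pi) within 3 sigma."""
        space = BoxSpace([-np.pi] * 1, [np.pi] * 1)  # placeholder, unused
        pose = self._pose_space(n_torsions=10)
        cfg = SearchConfig(mutation_rate=1.0, sigma_torsion=0.35)
        rng = np.random.default_rng(3)
        vec = pose.random(rng)
        steps = []
        for _ in range(1000):
            out = real_mutation(vec, cfg, rng, pose)
            assert np.all(out[7:] > -np.pi) and np.all(out[7:] <= np.pi)
            d = np.abs(np.angle(np.exp(1j * (out[7:] - vec[7:]))))
            steps.extend(d)
        n = len(steps)
        expected = 0.35 * math.sqrt(2.0 / math.pi)
        sd = 0.35 * math.sqrt(1.0 - 2.0 / math.pi)
        assert abs(np.mean(steps) - expected) < 3 * sd / math.sqrt(n)

    def test_quaternion_stays_unit(self):
        pose = self._pose_space()
        cfg = SearchConfig(mutation_rate=1.0)
        rng = np.random.default_rng(4)
        vec = pose.random(rng)
        for _ in range(50):
            vec = real_mutation(vec, cfg, rng, pose)
            assert abs(np.linalg.norm(vec[3:7]) - 1.0) < 1e-9


class TestCepUpdate:
    def _generation(self):
        """Fig-style setup: six offspring, best one (2a) carries preserved
        parents 1a and 1b."""
        p1a = Individual(np.array([10.0]), energy=10.0)
        p1b = Individual(np.array([11.0]), energy=11.0)
        offspring = [
            Individual(np.array([float(i)]), energy=float(i),
                       parents=(p1a, p1b) if i == 0 else None)
            for i in range(6)
        ]
        return offspring, p1a, p1b

    def test_worked_replacement_example(self):
        """Elite 2a kept; preserved parents 1a, 1b replace chosen slots 2b
        and 2c, yielding {2a, 1a, 1b, 2d, 2e, 2f}."""
        offspring, p1a, p1b = self._generation()
        records = identify_elites(offspring, 1)
        assert records[0].elite is offspring[0]
        assert records[0].father is p1a and records[0].mother is p1b
        out = cep_update(offspring, records, np.random.default_rng(0), slots=[1, 2])
        assert out[0] is offspring[0]
        assert out[1] is p1a and out[2] is p1b
        assert out[3:] == offspring[3:]
        assert len(out) == 6

    def test_elite_slot_cannot_be_replaced(self):
        offspring, *_ = self._generation()
        records = identify_elites(offspring, 1)
        with pytest.raises(ValueError, match="elite"):
            cep_update(offspring, records, np.random.default_rng(0), slots=[0, 2])

    def test_self_parenting_generation_zero(self):
        members = _members([3.0, 1.0, 2.0])
        rec = identify_elites(members, 1)[0]
        assert rec.elite is members[1]
        assert rec.father is members[1] and rec.mother is members[1]

    def test_insufficient_slots_rejected(self):
        members = _members([1.0, 2.0, 3.0])
        records = [
            ElitistRecord(members[0], _members([9])[0], _members([9])[0]),
            ElitistRecord(members[1], _members([9])[0], _members([9])[0]),
        ]
        with pytest.raises(ValueError, match="non-elite"):
            cep_update(members, records, np.random.default_rng(0))

    def test_elites_never_displaced_and_size_conserved(self):
        """Randomized generations: elites always survive, every preserved
        parent is present, population size is constant."""
        rng = np.random.default_rng(12)
        for _ in range(300):
            p = int(rng.integers(6, 30))
            n_elites = int(rng.integers(1, p // 3 + 1))
            parents = _members(rng.normal(size=2 * n_elites) + 100)
            offspring = [
                Individual(np.array([float(i)]), energy=float(rng.normal()))
                for i in range(p)
            ]
            ranked = sorted(offspring, key=lambda m: m.energy)[:n_elites]
            records = [
                ElitistRecord(e, parents[2 * k], parents[2 * k + 1])
                for k, e in enumerate(ranked)
            ]
            out = cep_update(offspring, records, rng)
            assert len(out) == p
            for rec in records:
                assert any(m is rec.elite for m in out)
                assert any(m is rec.father for m in out)
                assert any(m is rec.mother for m in out)


class TestLocalSearch:
    def _bowl_problem(self, dims=1):
        space = BoxSpace([-5.0] * dims, [5.0] * dims)
        return space, EvaluationContext(lambda x: float(np.sum(x * x)))

    def test_never_worsens(self):
        space, ctx = self._bowl_problem(3)
        cfg = SearchConfig(ls_max_iter=40)
        rng = np.random.default_rng(0)
        ind = Individual(space.random(rng))
        ind.energy = ctx.evaluate(ind.genome)
        out = local_search(ind, cfg, ctx, space, rng)
        assert out.energy <= ind.energy

    def test_quadratic_contraction(self):
        """Solis-Wets walk from x=1 on f(x)=x^2 reaches |x| < 0.1 within
        100 iterations."""
        space, ctx = self._bowl_problem(1)
        cfg = SearchConfig(ls_max_iter=100)
        ind = Individual(np.array([1.0]), energy=1.0)
        out = local_search(ind, cfg, ctx, space, np.random.default_rng(5))
        assert abs(out.genome[0]) < 0.1

    def test_zero_iterations_is_noop(self):
        space, ctx = self._bowl_problem(1)
        cfg = SearchConfig(ls_max_iter=0)
        ind = Individual(np.array([1.0]), energy=1.0)
        out = local_search(ind, cfg, ctx, space, np.random.default_rng(0))
        assert out is ind
        assert ctx.count == 0

    def test_budget_exhaustion_returns_best_so_far(self):
        space, ctx = self._bowl_problem(1)
        ctx.max_evaluations = 5
        cfg = SearchConfig(ls_max_iter=100)
        ind = Individual(np.array([2.0]), energy=4.0)
        out = local_search(ind, cfg, ctx, space, np.random.default_rng(1))
        assert ctx.count == 5
        assert out.energy <= 4.0


class TestConfig:
    def test_theta_range_enforced(self):
        with pytest.raises(ValueError, match="theta"):
            SearchConfig(theta=0.2)

    def test_elite_counts_by_ceiling(self):
        assert SearchConfig(pop_size=50, theta=0.1).n_elites == 5
        assert SearchConfig(pop_size=50, theta=0.01).n_elites == 1
        assert SearchConfig(pop_size=50, theta=0.05).n_elites == 3

    def test_infeasible_cep_rejected(self):
        # P=2: one elite plus two preserved parents cannot fit
        with pytest.raises(ValueError, match="infeasible"):
            SearchConfig(pop_size=2, theta=0.05)

    def test_single_member_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            SearchConfig(pop_size=1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SearchConfig(pop_size=20, max_generations=100, theta=0.1)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SearchConfig.from_yaml(path) == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("pop_size: 10\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            SearchConfig.from_yaml(path)


class TestDrivers:
    def _bowl(self, dims=2):
        return make_landscape("bowl", dims).problem()

    def test_zero_generations_returns_best_of_initial_population(self):
        cfg = SearchConfig(pop_size=20, max_generations=0)
        s = run_cepga(self._bowl(), cfg, seed=0)
        assert s.n_evaluations == 20
        assert s.best_energy >= 0.0

    def test_bowl_convergence_close_to_analytic_minimum(self):
        cfg = SearchConfig(pop_size=20, max_generations=50, max_evaluations=50_000)
        s = run_cepga(self._bowl(), cfg, seed=1)
        assert s.best_energy < 1e-2

    def test_trace_strictly_monotone(self, fixture_t2):
        cfg = SearchConfig(max_generations=20, max_evaluations=10_000)
        s = run_cepga(fixture_t2.problem(), cfg, seed=2)
        es = [e for _, e in s.trace]
        ns = [n for n, _ in s.trace]
        assert all(b < a for a, b in zip(es, es[1:]))
        assert all(b > a for a, b in zip(ns, ns[1:]))
        assert s.best_energy == es[-1]

    def test_seeded_determinism_bitwise(self, fixture_t2):
        cfg = SearchConfig(max_generations=10, max_evaluations=6_000)
        a = run_cepga(fixture_t2.problem(), cfg, seed=3)
        b = run_cepga(fixture_t2.problem(), cfg, seed=3)
        assert a.trace == b.trace
        assert a.best_energy == b.best_energy
        np.testing.assert_array_equal(a.best_genome, b.best_genome)

    def test_budget_respected(self, fixture_t2):
        cfg = SearchConfig(max_generations=1000, max_evaluations=2_000)
        s = run_cepga(fixture_t2.problem(), cfg, seed=4)
        assert s.n_evaluations <= 2_000

    def test_ga_shares_operators_but_skips_cep_and_ls(self):
        cfg = SearchConfig(pop_size=20, max_generations=30, max_evaluations=50_000)
        ga = run_ga(self._bowl(), cfg, seed=5)
        assert ga.algorithm == "ga"
        assert ga.best_energy < 1.0  # converges, if less sharply than CEPGA

    def test_ablation_shares_trace_until_first_cep_or_ls_event(self):
        """Same seed, CEP/LS disabled: the GA's trace matches CEPGA's up to
        the initial population (the first point where the arms diverge)."""
        prob = self._bowl()
        cfg = SearchConfig(pop_size=20, max_generations=5, max_evaluations=10_000)
        a = run_cepga(prob, cfg, seed=9)
        b = run_ga(prob, cfg, seed=9)
        prefix_a = [t for t in a.trace if t[0] <= cfg.pop_size]
        prefix_b = [t for t in b.trace if t[0] <= cfg.pop_size]
        assert prefix_a == prefix_b
        assert a.trace != b.trace  # CEP/LS change the search afterwards

    def test_cepga_beats_or_matches_ga_on_bowl_medians(self):
        cfg = SearchConfig(pop_size=20, max_generations=30, max_evaluations=50_000)
        prob = self._bowl()
        cep = np.median([run_cepga(prob, cfg, seed=s).best_energy for s in range(7)])
        ga = np.median([run_ga(prob, cfg, seed=s).best_energy for s in range(7)])
        assert cep <= ga

    def test_lattice_never_below_exhaustive_minimum(self):
        land = make_landscape("lattice", 3)
        cfg = SearchConfig(pop_size=20, max_generations=40, max_evaluations=50_000)
        s = run_cepga(land.problem(), cfg, seed=6)
        assert s.best_energy >= land.global_minimum - 1e-12
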