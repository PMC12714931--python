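"""GA operators and full runs: selection law, operator invariants, convergence."""

import math

import numpy as np
import pytest

import nanovax as nv
from nanovax.ga_opt import crossover, init_population, mutate, tournament_select
from nanovax.lnp_space import BOUNDS


def _candidate(size=90.0, charge=0.0, peg=0.3, targeting=1.0, fitness=None):
    return nv.Candidate(np.array([size, charge, peg, targeting]), fitness)


def _in_bounds(genome):
    return (
        BOUNDS["size_nm"][0] <= genome[0] <= BOUNDS["size_nm"][1]
        and BOUNDS["charge_mV"][0] <= genome[1] <= BOUNDS["charge_mV"][1]
        and BOUNDS["peg_molpct"][0] <= genome[2] <= BOUNDS["peg_molpct"][1]
        and genome[3] in (0.0, 1.0)
    )


class TestInit:
    def test_population_size_and_bounds(self):
        pop = init_population(nv.GAConfig(pop_size=50, seed=0))
        assert len(pop) == 50
        assert all(_in_bounds(c.genome) for c in pop)

    def test_same_seed_identical_population(self):
        a = init_population(nv.GAConfig(seed=1))
        b = init_population(nv.GAConfig(seed=1))
        assert all(np.array_equal(x.genome, y.genome) for x, y in zip(a, b))

    def test_genes_spread_across_the_box(self):
        pop = init_population(nv.GAConfig(pop_size=200, seed=2))
        genomes = np.stack([c.genome for c in pop])
        assert genomes[:, 0].min() < 60 and genomes[:, 0].max() > 140
        assert genomes[:, 1].min() < -8 and genomes[:, 1].max() > 8
        assert set(genomes[:, 3]) == {0.0, 1.0}


class TestTournament:
    def test_full_tournament_returns_global_best(self):
        pop = [_candidate(fitness=f) for f in (0.1, 0.9, 0.4)]
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert tournament_select(pop, k=3, rng=rng).fitness == 0.9

    def test_k1_is_uniform_pick(self):
        pop = [_candidate(fitness=float(i)) for i in range(4)]
        rng = np.random.default_rng(0)
        picks = [tournament_select(pop, k=1, rng=rng).fitness for _ in range(4000)]
        counts = np.bincount(np.array(picks, dtype=int), minlength=4)
        assert (np.abs(counts / 4000 - 0.25) < 0.05).all()

    def test_selection_law_matches_hypergeometric_enumeration(self):
        """n=5, k=3 without replacement: P(rank-r individual wins) =
        C(n-r, k-1)/C(n, k); checked against 10,000 trials."""
        n, k, trials = 5, 3, 10_000
        pop = [_candidate(fitness=float(n - i)) for i in range(n)]  # rank i+1
        rng = np.random.default_rng(0)
        wins = np.zeros(n)
        for _ in range(trials):
            winner = tournament_select(pop, k=k, rng=rng)
            wins[n - int(winner.fitness)] += 1
        for r in range(1, n + 1):
            p_exact = math.comb(n - r, k - 1) / math.comb(n, k)
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / trials)
            assert abs(wins[r - 1] / trials - p_exact) < 4 * se + 1e-9

    def test_oversized_tournament_rejected(self):
        pop = [_candidate(fitness=1.0)]
        with pytest.raises(ValueError):
            tournament_select(pop, k=2, rng=np.random.default_rng(0))


class TestCrossover:
    def test_p_zero_copies_parents(self):
        a, b = _candidate(60, -5, 0.2, 0), _candidate(140, 5, 0.4, 1)
        c1, c2 = crossover(a, b, p=0.0, rng=np.random.default_rng(0))
        assert np.array_equal(c1.genome, a.genome)
        assert np.array_equal(c2.genome, b.genome)

    def test_identical_parents_fixed_point(self):
        a = _candidate(100, 2, 0.25, 1)
        c1, c2 = crossover(a, a, p=1.0, rng=np.random.default_rng(0))
        assert np.allclose(c1.genome, a.genome)
        assert np.allclose(c2.genome, a.genome)

    def test_children_within_parent_intervals(self):
        rng = np.random.default_rng(5)
        a, b = _candidate(60, -5, 0.2, 0), _candidate(140, 5, 0.4, 1)
        for _ in range(50):
            for child in crossover(a, b, p=1.0, rng=rng):
                for g in range(3):
                    lo = min(a.genome[g], b.genome[g])
                    hi = max(a.genome[g], b.genome[g])
                    assert lo - 1e-12 <= child.genome[g] <= hi + 1e-12
                assert child.genome[3] in (0.0, 1.0)


class TestMutation:
    def test_p_zero_is_identity(self):
        c = _candidate(100, 2, 0.25, 1)
        out = mutate(c, p=0.0, rng=np.random.default_rng(0))
        assert np.array_equal(out.genome, c.genome)

    def test_output_always_in_bounds(self):
        rng = np.random.default_rng(1)
        c = _candidate(150, 10, 0.5, 1)  # at the corner, noise must clip
        for _ in range(200):
            assert _in_bounds(mutate(c, p=1.0, rng=rng).genome)

    def test_mean_absolute_size_step_matches_half_normal(self):
        """Unclipped size steps are N(0, (0.05*100)^2); mean |step| must be
        within 5% of sigma*sqrt(2/pi) over 10,000 mutations."""
        rng = np.random.default_rng(2)
        c = _candidate(100.0, 0.0, 0.3, 0)  # far from size bounds: no clipping
        steps = [abs(mutate(c, p=1.0, rng=rng).genome[0] - 100.0) for _ in range(10_000)]
        expected = 5.0 * np.sqrt(2 / np.pi)
        assert abs(np.mean(steps) - expected) / expected < 0.05


class TestRuns:
    def test_analytic_fitness_reaches_grid_optimum(self):
        """With the noiseless objective as fitness the GA lands within 0.02
        of the grid-search optimum 1.75 after 100 generations."""
        result = nv.run_ga(nv.score_frame, nv.GAConfig(seed=0))
        assert result.top_k["predicted_delta_auc"].iloc[0] >= 1.75 - 0.02

    def test_analytic_fitness_converges_for_ten_seeds(self):
        for seed in range(10):
            result = nv.run_ga(nv.score_frame, nv.GAConfig(seed=seed))
            assert result.top_k["predicted_delta_auc"].iloc[0] >= 1.70

    def test_surrogate_run_selects_targeted_candidates(self, ga_result):
        assert (ga_result.top_k["targeting"] == 1).all()

    def test_best_so_far_trace_non_decreasing(self, ga_result):
        assert (np.diff(ga_result.trace["best_so_far"]) >= 0).all()

    def test_topk_deduplicated(self, ga_result):
        keys = {
            (round(r.size_nm, 1), round(r.charge_mV, 1), round(r.peg_molpct, 2), r.targeting)
            for r in ga_result.top_k.itertuples()
        }
        assert len(keys) == len(ga_result.top_k)

    def test_topk_sorted_descending(self, ga_result):
        fits = ga_result.top_k["predicted_delta_auc"].to_numpy()
        assert (np.diff(fits) <= 1e-12).all()

    def test_run_is_reproducible(self):
        cfg = nv.GAConfig(pop_size=20, generations=10, seed=7)
        a = nv.run_ga(nv.score_frame, cfg)
        b = nv.run_ga(nv.score_frame, cfg)
        assert a.top_k.equals(b.top_k)
        assert a.trace.equals(b.trace)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            nv.GAConfig(pop_size=2, tournament_size=5).validate()
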