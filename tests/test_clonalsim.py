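"""Moran clonal-expansion engine: exact kernel, drift and advantage."""

import itertools
import math

import numpy as np
import pytest

from mitofibre import clonalsim as cs


def two_species(n_small, n_large, small_kb=8.0, large_kb=12.0):
    return (
        cs.SpeciesSpec("small", small_kb, n_small),
        cs.SpeciesSpec("large", large_kb, n_large),
    )


def exact_kernel(state, weights):
    """Exact one-step Moran transition probabilities (oracle)."""
    state = np.asarray(state, dtype=float)
    n = state.sum()
    birth_w = state * weights
    birth_p = birth_w / birth_w.sum()
    death_p = state / n
    probs = {}
    for i, j in itertools.product(range(len(state)), repeat=2):
        new = state.copy()
        new[i] -= 1
        new[j] += 1
        key = tuple(int(x) for x in new)
        probs[key] = probs.get(key, 0.0) + death_p[i] * birth_p[j]
    return probs


class TestMoranStep:
    def test_copy_number_conserved_along_trajectory(self):
        cfg = cs.SimConfig(
            species=two_species(5, 5), alpha=1.0, n_steps=200, seed=1,
            record_times=tuple(range(0, 201, 10)),
        )
        traj = cs.simulate_cell(cfg)
        assert (traj[["small", "large"]].sum(axis=1) == 10).all()

    def test_neutral_weights_are_uniform(self):
        cfg = cs.SimConfig(species=two_species(3, 7), alpha=0.0, seed=0)
        assert np.allclose(cfg.weights(), 1.0)

    def test_strong_advantage_always_replicates_smallest(self):
        rng = np.random.default_rng(0)
        state = np.array([5, 5])
        weights = (16.6 / np.array([8.0, 12.0])) ** 200  # alpha -> infinity
        weights /= weights.max()
        births = []
        for _ in range(200):
            new = cs.moran_step(state, weights, rng)
            diff = new - state
            if (diff != 0).any():
                births.append(int(np.argmax(diff)))
        assert set(births) <= {0}

    def test_empirical_kernel_matches_exact_probabilities(self):
        # N = 4, two species, 1e5 draws against the enumerated kernel
        state = np.array([3, 1])
        weights = (16.6 / np.array([8.0, 12.0])) ** 1.0
        exact = exact_kernel(state, weights)
        rng = np.random.default_rng(99)
        n_draws = 100_000
        seen: dict = {}
        for _ in range(n_draws):
            new = tuple(int(x) for x in cs.moran_step(state, weights, rng))
            seen[new] = seen.get(new, 0) + 1
        for key, p in exact.items():
            if p == 0:
                continue
            se = math.sqrt(p * (1 - p) / n_draws)
            assert abs(seen.get(key, 0) / n_draws - p) < 3 * se + 1e-9

    def test_vectorised_engine_matches_exact_kernel(self):
        # one event applied to 1e5 parallel cells reproduces the kernel
        cfg = cs.SimConfig(
            species=two_species(3, 1), alpha=1.0, n_steps=1, n_cells=100_000,
            seed=7,
        )
        summary = cs.simulate_cohort(cfg)
        counts = summary.final_states.value_counts().to_dict()
        exact = exact_kernel([3, 1], cfg.weights())
        for key, p in exact.items():
            if p == 0:
                continue
            se = math.sqrt(p * (1 - p) / cfg.n_cells)
            assert abs(counts.get(key, 0) / cfg.n_cells - p) < 3 * se + 1e-9

    def test_single_molecule_population_rejected(self):
        with pytest.raises(cs.SimError):
            cs.moran_step(np.array([1, 0]), np.ones(2), np.random.default_rng(0))


class TestSimulateCell:
    def test_zero_steps_returns_initial_state(self):
        cfg = cs.SimConfig(species=two_species(4, 6), n_steps=0, seed=5,
                           record_times=(0,))
        traj = cs.simulate_cell(cfg)
        assert traj.iloc[-1]["small"] == 4 and traj.iloc[-1]["large"] == 6

    def test_same_seed_reproduces_trajectory(self):
        cfg = cs.SimConfig(species=two_species(10, 10), alpha=0.7,
                           n_steps=300, seed=123, record_times=(100, 200, 300))
        assert cs.simulate_cell(cfg).equals(cs.simulate_cell(cfg))


class TestCohort:
    def test_neutral_symmetry_of_prevalence(self):
        # equal starts, alpha = 0: by exchangeability the smallest genome is
        # most prevalent in half of the unresolved cells
        cfg = cs.SimConfig(species=two_species(50, 50), alpha=0.0,
                           n_steps=500, n_cells=2000, seed=11)
        s = cs.simulate_cohort(cfg)
        frac = s.smallest_most_prevalent_fraction
        se = math.sqrt(0.25 / s.n_multi_species_cells)
        assert abs(frac - 0.5) < 3 * se

    def test_neutral_mean_heteroplasmy_constant(self):
        cfg = cs.SimConfig(species=two_species(30, 70), alpha=0.0,
                           n_steps=500, n_cells=2000, seed=19)
        s = cs.simulate_cohort(cfg)
        h = s.final_states["small"] / 100
        assert abs(h.mean() - 0.3) < 3 * h.std(ddof=1) / math.sqrt(len(h))

    def test_neutral_fixation_probability_equals_initial_frequency(self):
        n, f = 20, 0.3
        cfg = cs.SimConfig(species=two_species(int(n * f), int(n * (1 - f))),
                           alpha=0.0, n_steps=4000, n_cells=1000, seed=23)
        s = cs.simulate_cohort(cfg)
        absorbed = s.fixation_counts["small"] + s.fixation_counts["large"]
        assert absorbed > 950  # nearly all runs resolved at this horizon
        fix_frac = s.fixation_counts["small"] / absorbed
        se = math.sqrt(f * (1 - f) / absorbed)
        assert abs(fix_frac - f) < 3 * se

    def test_prevalence_monotone_in_alpha(self):
        fracs = []
        for alpha in (0.0, 0.5, 1.0, 2.0):
            cfg = cs.SimConfig(species=two_species(50, 50), alpha=alpha,
                               n_steps=500, n_cells=1000, seed=31)
            fracs.append(
                cs.simulate_cohort(cfg).smallest_most_prevalent_fraction
            )
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]

    def test_wild_type_excluded_from_comparison_by_default(self):
        species = (
            cs.SpeciesSpec("wt", 16.6, 90),
            cs.SpeciesSpec("del1", 10.0, 5),
            cs.SpeciesSpec("del2", 8.0, 5),
        )
        cfg = cs.SimConfig(species=species, alpha=0.0, n_steps=50,
                           n_cells=200, seed=41)
        s = cs.simulate_cohort(cfg)
        # wild type dominates every cell; the statistic still compares only
        # the deleted species, so it is not degenerate at 0
        assert s.n_multi_species_cells > 0


class TestObservedComparison:
    def test_two_sided_exact_binomial(self):
        assert cs.compare_to_observed(0.5, 4, 10) == pytest.approx(0.7539, abs=1e-4)
        assert cs.compare_to_observed(0.5, 0, 10) == pytest.approx(
            2 * 0.5**10, rel=1e-9
        )

    def test_observation_at_expectation_hits_p_one(self):
        assert cs.compare_to_observed(0.5, 5, 10) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(cs.SimError):
            cs.compare_to_observed(0.5, 11, 10)
        with pytest.raises(cs.SimError):
            cs.compare_to_observed(0.5, 1, 0)
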