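from collections import Counter
from dataclasses import replace
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxadapt import (
    AdaptationConfig,
    AdaptationState,
    FluxVector,
    SamplerConfig,
    advance_step,
    default_delta_t,
    enumerate_candidates,
    enumerate_chain_exact,
    make_random_network,
    run_ensemble,
    run_trajectory,
    selection_probabilities,
    solve_pfba,
    trajectories_to_frame,
)
from fluxadapt.analysis import flux_correlation
from fluxadapt.engine import Candidate, CandidateSet


def state_at(net, values):
    return AdaptationState(
        k=0,
        flux=FluxVector.from_values(net, np.asarray(values, dtype=float)),
        constraints=net.constraints(),
    )


def make_candidates(growths):
    entries = [Candidate("stay", None, None, growths[0])] + [
        Candidate("silence", i, None, g) for i, g in enumerate(growths[1:])
    ]
    return CandidateSet(entries=tuple(entries))


class TestCandidateEnumeration:
    def test_toy_at_pfba_point(self, toy):
        cands = enumerate_candidates(
            state_at(toy, [10, 10, 0]), AdaptationConfig(delta_t=1.0)
        )
        by_action = {(c.action, c.reaction): c for c in cands.entries}
        assert cands.n_k == 2  # waste reaction inactive, hence not a candidate
        assert by_action[("stay", None)].growth == pytest.approx(10.0)
        assert by_action[("silence", 0)].growth == pytest.approx(0.0, abs=1e-6)
        assert by_action[("silence", 1)].growth == pytest.approx(0.0, abs=1e-6)

    def test_toy_at_interior_point(self, toy):
        cands = enumerate_candidates(
            state_at(toy, [10, 5, 5]), AdaptationConfig(delta_t=1.0)
        )
        growths = {c.reaction: c.growth for c in cands.entries[1:]}
        assert cands.entries[0].growth == pytest.approx(5.0)
        assert growths[0] == pytest.approx(0.0, abs=1e-6)
        assert growths[1] == pytest.approx(0.0, abs=1e-6)
        assert growths[2] == pytest.approx(7.5, abs=1e-6)
        flux_r3 = next(c.flux for c in cands.entries if c.reaction == 2)
        np.testing.assert_allclose(flux_r3.values, [7.5, 7.5, 0.0], atol=1e-6)

    def test_zero_flux_state_has_stay_only(self, toy):
        cands = enumerate_candidates(
            state_at(toy, [0, 0, 0]), AdaptationConfig(delta_t=1.0)
        )
        assert cands.n_k == 0

    def test_infeasible_candidates_dropped(self):
        from fluxadapt.network import MetabolicNetwork

        # R2 has forced throughput (positive lower bound), so silencing R1
        # empties the polytope and that candidate is dropped; silencing R2
        # itself pins both bounds to zero and stays feasible at zero growth
        net = MetabolicNetwork(
            reaction_ids=("R1", "R2"),
            metabolite_ids=("A",),
            S=np.array([[1.0, -1.0]]),
            lower_bounds=np.array([0.0, 1.0]),
            upper_bounds=np.array([10.0, 10.0]),
            biomass_coeffs=np.array([0.0, 1.0]),
        )
        cands = enumerate_candidates(
            state_at(net, [5, 5]), AdaptationConfig(delta_t=1.0)
        )
        assert cands.n_k == 1
        assert cands.n_infeasible_dropped == 1
        assert cands.entries[1].reaction == 1
        assert cands.entries[1].growth == pytest.approx(0.0, abs=1e-8)

    def test_internal_only_scope_excludes_exchanges(self, ecoli_core):
        cfg_all = AdaptationConfig(delta_t=1.0, candidate_scope="all_active")
        cfg_int = AdaptationConfig(delta_t=1.0, candidate_scope="internal_only")
        from fluxadapt import sample_interior_points

        v0 = sample_interior_points(
            ecoli_core.constraints(),
            SamplerConfig(n_samples=1, seed=0, burn_in=100, thinning=1),
        )[0]
        st_core = state_at(ecoli_core, v0.values)
        all_c = enumerate_candidates(st_core, cfg_all)
        int_c = enumerate_candidates(st_core, cfg_int)
        assert int_c.n_k < all_c.n_k
        ex = set(np.flatnonzero(ecoli_core.is_exchange))
        assert all(c.reaction not in ex for c in int_c.entries[1:])


class TestSelectionProbabilities:
    def test_two_candidate_closed_form(self, toy):
        dist = selection_probabilities(
            make_candidates([0.0, 1.0]),
            state_at(toy, [10, 10, 0]),
            AdaptationConfig(delta_t=float(np.log(2.0))),
        )
        np.testing.assert_allclose(dist.probabilities, [1 / 3, 2 / 3], atol=1e-12)
        assert dist.partition_value == pytest.approx(3.0)

    def test_vanishing_interval_gives_uniform_prior(self, toy):
        dist = selection_probabilities(
            make_candidates([0.3, 1.0, 0.7]),
            state_at(toy, [10, 10, 0]),
            AdaptationConfig(delta_t=1e-14),
        )
        np.testing.assert_allclose(dist.probabilities, np.full(3, 1 / 3), atol=1e-9)

    def test_dominant_exponent_limit(self, toy):
        dist = selection_probabilities(
            make_candidates([2.0, 1.0, 0.0]),
            state_at(toy, [10, 10, 0]),
            AdaptationConfig(delta_t=100.0),
        )
        np.testing.assert_allclose(dist.probabilities, [1, 0, 0], atol=1e-6)

    def test_overflow_safe_and_normalised(self, toy):
        dist = selection_probabilities(
            make_candidates([900.0, 850.0, 0.0]),
            state_at(toy, [10, 10, 0]),
            AdaptationConfig(delta_t=5.0),
        )
        assert np.isfinite(dist.probabilities).all()
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.log_partition == pytest.approx(4500.0, rel=1e-9)

    def test_accumulated_prior_sharpens_with_beta(self, toy):
        cands = make_candidates([0.0, 1.0])
        cfg = AdaptationConfig(delta_t=1.0, prior_mode="accumulated", beta0=0.0)
        st0 = state_at(toy, [10, 10, 0])
        cold = selection_probabilities(cands, st0, cfg)
        warm = selection_probabilities(cands, replace(st0, beta=3.0), cfg)
        assert warm.probabilities[1] > cold.probabilities[1]

    def test_average_fitness_is_expected_growth(self, toy):
        cands = make_candidates([1.0, 3.0])
        dist = selection_probabilities(
            cands, state_at(toy, [10, 10, 0]), AdaptationConfig(delta_t=1e-14)
        )
        assert dist.average_fitness(cands) == pytest.approx(2.0, abs=1e-9)


class TestAdvanceStep:
    def test_single_candidate_means_deterministic_stay(self, toy):
        st0 = state_at(toy, [0, 0, 0])
        new, chosen = advance_step(
            st0, AdaptationConfig(delta_t=1.0), np.random.default_rng(0)
        )
        assert chosen.action == "stay"
        assert new.k == 1 and new.stall_count == 1
        assert new.constraints.silenced == frozenset()

    def test_growth_improving_silencing_dominates(self, toy):
        # from (10,5,5) only silencing the waste reaction improves growth
        st0 = state_at(toy, [10, 5, 5])
        for seed in range(10):
            new, chosen = advance_step(
                st0, AdaptationConfig(delta_t=50.0), np.random.default_rng(seed)
            )
            assert chosen.action == "silence" and chosen.reaction == 2
            assert new.constraints.silenced == {2}
            assert new.stall_count == 0

    def test_accumulated_beta_bookkeeping(self, toy):
        cfg = AdaptationConfig(delta_t=2.0, prior_mode="accumulated", beta0=0.5)
        st0 = replace(state_at(toy, [0, 0, 0]), beta=0.5)
        st1, _ = advance_step(st0, cfg, np.random.default_rng(0))
        assert st1.beta == pytest.approx(2.5)  # stay: beta += delta_t
        st_int = replace(state_at(toy, [10, 5, 5]), beta=7.0)
        st2, chosen = advance_step(st_int, cfg, np.random.default_rng(1))
        if chosen.action == "silence":
            assert st2.beta == pytest.approx(0.5)  # reset to beta0


class TestTrajectories:
    def test_start_at_attractor_absorbs_without_silencing(self, toy):
        tr = run_trajectory(
            toy,
            FluxVector.from_values(toy, [10, 10, 0]),
            AdaptationConfig(delta_t=50.0, seed=0),
        )
        assert tr.absorbed
        assert tr.length == 0
        assert tr.absorption_step == 0
        assert tr.steps[-1].growth == pytest.approx(10.0)

    def test_two_step_adaptation_to_reduced_attractor(self, toy):
        tr = run_trajectory(
            toy,
            FluxVector.from_values(toy, [10, 5, 5]),
            AdaptationConfig(delta_t=50.0, seed=1),
        )
        assert tr.absorbed
        assert tr.length == 1
        np.testing.assert_allclose(
            tr.final_state.flux.values, [7.5, 7.5, 0.0], atol=1e-6
        )
        pfba = solve_pfba(toy.constraints()).flux
        assert flux_correlation(tr.final_state.flux, pfba) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_zero_step_cap_returns_initial_state_only(self, toy):
        tr = run_trajectory(
            toy,
            FluxVector.from_values(toy, [10, 5, 5]),
            AdaptationConfig(delta_t=1.0, max_steps=0),
        )
        assert len(tr.steps) == 1 and not tr.absorbed

    def test_infeasible_start_rejected(self, toy):
        with pytest.raises(ValueError, match="not feasible"):
            run_trajectory(
                toy,
                FluxVector.from_values(toy, [10, 3, 3]),
                AdaptationConfig(delta_t=1.0),
            )

    def test_absorbed_tail_is_constant(self, toy):
        tr = run_trajectory(
            toy,
            FluxVector.from_values(toy, [10, 5, 5]),
            AdaptationConfig(delta_t=50.0, seed=3),
        )
        tail = tr.steps[tr.absorption_step:]
        growths = {round(s.growth, 9) for s in tail}
        assert len(growths) == 1

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), dt=st.floats(0.01, 30.0))
    def test_silenced_sets_monotone_along_any_trajectory(self, seed, dt):
        net = make_random_network(n_reactions=5, seed=3)
        from fluxadapt import sample_interior_points

        v0 = sample_interior_points(
            net.constraints(),
            SamplerConfig(n_samples=1, seed=seed, burn_in=50, thinning=1),
        )[0]
        tr = run_trajectory(
            net, v0, AdaptationConfig(delta_t=dt, seed=seed, retain_fluxes=True)
        )
        silenced = set()
        for s in tr.steps[1:]:
            if s.action == "silence":
                i = net.index(s.silenced_reaction)
                assert i not in silenced
                silenced.add(i)
        assert tr.length == len(silenced)
        assert tr.final_state.constraints.silenced == silenced


class TestEnsembles:
    def test_empty_ensemble(self, toy):
        assert run_ensemble(
            toy, 0, SamplerConfig(n_samples=1, seed=0), AdaptationConfig(delta_t=1.0)
        ) == []

    def test_seeded_reproducibility(self, toy):
        kw = dict(
            sampler_config=SamplerConfig(n_samples=1, seed=5, burn_in=100,
                                         thinning=5),
            adaptation_config=AdaptationConfig(delta_t=5.0, seed=9),
        )
        a = trajectories_to_frame(run_ensemble(toy, 20, **kw), g_fba=10.0)
        b = trajectories_to_frame(run_ensemble(toy, 20, **kw), g_fba=10.0)
        assert a.equals(b)

    def test_strong_selection_funnels_toy_to_pfba(self, toy):
        trajs = run_ensemble(
            toy,
            200,
            SamplerConfig(n_samples=1, seed=2, burn_in=100, thinning=5),
            AdaptationConfig(delta_t=50.0, seed=4),
        )
        pfba = solve_pfba(toy.constraints()).flux
        corr = np.array(
            [flux_correlation(t.final_state.flux, pfba) for t in trajs]
        )
        assert np.all(corr >= 0.99)


class TestExactEnumeration:
    def test_probability_conservation_and_triangularity(self, toy):
        res = enumerate_chain_exact(
            toy,
            FluxVector.from_values(toy, [10, 5, 5]),
            AdaptationConfig(delta_t=5.0),
        )
        assert res.total_mass == pytest.approx(1.0, abs=1e-9)
        assert res.triangular

    def test_uniform_limit_matches_hand_counted_orders(self, toy):
        """At dt -> 0 every candidate is equiprobable and the end-state masses
        reduce to counting silencing orders (with the stall-absorption factor
        (1/(n+1))**5 per visited state); hand-computed for the toy pathway."""
        res = enumerate_chain_exact(
            toy,
            FluxVector.from_values(toy, [10, 5, 5]),
            AdaptationConfig(delta_t=1e-12, stall_steps=5),
        )
        q4 = Fraction(1, 4) ** 5    # absorb at root (3 candidates + stay)
        q3 = Fraction(1, 3) ** 5    # absorb at a 2-candidate state
        e4 = 1 - q4
        e3 = 1 - q3
        expected = {
            frozenset(): q4,
            frozenset({0}): e4 / 3,                      # dead end: flux 0
            frozenset({1}): e4 / 3 * q3,
            frozenset({2}): e4 / 3 * q3,
            frozenset({0, 1}): e4 / 3 * e3 / 2,
            frozenset({0, 2}): e4 / 3 * e3 / 2,
            frozenset({1, 2}): e4 / 3 * e3,              # reached two ways
        }
        assert set(res.probabilities) == set(expected)
        for key, p in expected.items():
            assert res.probabilities[key] == pytest.approx(float(p), abs=1e-9)

    def test_mode_and_size_guards(self, toy):
        v0 = FluxVector.from_values(toy, [10, 5, 5])
        with pytest.raises(ValueError, match="uniform"):
            enumerate_chain_exact(
                toy, v0, AdaptationConfig(delta_t=1.0, prior_mode="accumulated")
            )
        big = make_random_network(n_reactions=14, seed=0)
        with pytest.raises(ValueError, match="r <= 12"):
            enumerate_chain_exact(
                big,
                FluxVector.from_values(big, np.zeros(14)),
                AdaptationConfig(delta_t=1.0),
            )

    def test_monte_carlo_matches_exact_distribution(self, toy):
        """Trajectory frequencies agree with the exact tree expansion."""
        cfg = AdaptationConfig(delta_t=0.4)
        v0 = FluxVector.from_values(toy, [10, 5, 5])
        exact = enumerate_chain_exact(toy, v0, cfg)
        n = 5000
        counts = Counter()
        for s in range(n):
            tr = run_trajectory(toy, v0, replace(cfg, seed=s))
            counts[frozenset(tr.final_state.constraints.silenced)] += 1
        for key, p in exact.probabilities.items():
            if p < 1e-4:
                continue
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) <= 3 * sigma + 1e-9, key
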