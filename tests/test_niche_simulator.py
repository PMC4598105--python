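import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichelumps._rng import substream_rng
from nichelumps.niche_simulator import (
    CommunityState,
    SimulationParams,
    competition_coefficient,
    evolution_step,
    integrate_dynamics,
    lump_summary,
    lv_derivatives,
    run_simulation,
)


def two_species_equilibrium(d: float, sigma: float, K: float):
    """Closed-form symmetric two-species coexistence: N* = K / (1 + alpha)."""
    alpha = np.exp(-(d**2) / (2 * sigma**2))
    return K / (1 + alpha)


class TestCompetitionCoefficient:
    def test_zero_distance_is_one(self):
        assert competition_coefficient(0.5, 0.5, 0.123) == 1.0

    def test_one_kernel_width_is_exp_minus_half(self):
        assert competition_coefficient(0.0, 0.05, 0.05) == pytest.approx(
            np.exp(-0.5), abs=1e-12
        )

    @given(
        a=st.floats(0, 1), b=st.floats(0, 1),
        sigma=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetry(self, a, b, sigma):
        assert competition_coefficient(a, b, sigma) == competition_coefficient(
            b, a, sigma
        )

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="sigma_alpha"):
            competition_coefficient(0.0, 1.0, 0.0)


class TestLvDerivatives:
    def test_single_species_at_K_is_stationary(self):
        params = SimulationParams(n_species=1)
        state = CommunityState(x=np.array([0.5]), N=np.array([params.K0]))
        assert lv_derivatives(state, params) == pytest.approx([0.0], abs=1e-12)

    def test_extinct_species_stays_extinct(self):
        params = SimulationParams(n_species=1)
        state = CommunityState(x=np.array([0.5]), N=np.array([0.0]))
        assert lv_derivatives(state, params) == pytest.approx([0.0], abs=1e-15)

    def test_two_species_closed_form_equilibrium(self):
        """dN/dt vanishes to 1e-10 at the analytic N* = K/(1+alpha) for
        random distance/width/capacity triples."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = rng.uniform(0.01, 0.5)
            sigma = rng.uniform(0.02, 0.3)
            K = rng.uniform(10.0, 1000.0)
            params = SimulationParams(n_species=2, K0=K, sigma_alpha=sigma)
            nstar = two_species_equilibrium(d, sigma, K)
            state = CommunityState(
                x=np.array([0.3, 0.3 + d]), N=np.array([nstar, nstar])
            )
            deriv = lv_derivatives(state, params)
            assert np.all(np.abs(deriv) < 1e-10)


class TestIntegrateDynamics:
    def test_zero_duration_is_identity(self):
        params = SimulationParams(n_species=2)
        state = CommunityState(
            x=np.array([0.2, 0.8]), N=np.array([1.0, 2.0]), t=3.0
        )
        assert integrate_dynamics(state, params, 0.0) is state

    def test_logistic_closed_form(self):
        """A lone species follows N(t) = K / (1 + ((K-N0)/N0) e^{-rt});
        the RK4 state at t = 20/r is within 1% of it (and of K)."""
        params = SimulationParams(
            n_species=1, r=1.0, K0=100.0, dt=0.1, extinction_threshold=0.0
        )
        N0 = 0.01 * params.K0
        state = CommunityState(x=np.array([0.5]), N=np.array([N0]))
        out = integrate_dynamics(state, params, 20.0)
        expected = params.K0 / (1 + (params.K0 - N0) / N0 * np.exp(-20.0))
        assert out.N[0] == pytest.approx(expected, rel=1e-6)
        assert out.N[0] == pytest.approx(params.K0, rel=0.01)

    def test_colocated_species_stay_equal_and_sum_to_K(self):
        params = SimulationParams(
            n_species=2, r=1.0, K0=50.0, extinction_threshold=0.0
        )
        state = CommunityState(
            x=np.array([0.4, 0.4]), N=np.array([1.0, 1.0])
        )
        out = integrate_dynamics(state, params, 30.0)
        assert out.N[0] == out.N[1]
        assert out.N.sum() == pytest.approx(params.K0, rel=1e-3)

    def test_extinction_pruning_removes_species(self):
        params = SimulationParams(
            n_species=2, sigma_alpha=0.5, extinction_threshold=1.0
        )
        # second species starts far below threshold and is outcompeted
        state = CommunityState(
            x=np.array([0.5, 0.501]), N=np.array([100.0, 1e-8])
        )
        out = integrate_dynamics(state, params, 5.0)
        assert out.n_species == 1

    def test_empty_community_still_advances_time(self):
        params = SimulationParams(n_species=1)
        state = CommunityState(x=np.empty(0), N=np.empty(0), t=1.0)
        out = integrate_dynamics(state, params, 4.0)
        assert out.t == 5.0 and out.n_species == 0


class TestEvolutionStep:
    def _params(self, **kw):
        defaults = dict(n_species=2, sigma_alpha=0.05, evolution_step_sd=0.01)
        defaults.update(kw)
        return SimulationParams(**defaults)

    def test_zero_step_is_identity(self):
        params = self._params(evolution_step_sd=0.0)
        state = CommunityState(x=np.array([0.2, 0.6]), N=np.array([5.0, 5.0]))
        out = evolution_step(state, params, substream_rng(0, "t"))
        assert np.array_equal(out.x, state.x)

    def test_single_species_flat_landscape_does_not_move(self):
        params = self._params(n_species=1)
        state = CommunityState(x=np.array([0.5]), N=np.array([5.0]))
        out = evolution_step(state, params, substream_rng(0, "t"))
        assert out.x[0] == 0.5

    def test_close_pair_moves_apart_under_hill_climb(self):
        """Species half a kernel width apart each gain fitness by
        separating, so one hill-climb step strictly increases distance."""
        params = self._params()
        d0 = 0.5 * params.sigma_alpha
        state = CommunityState(
            x=np.array([0.5, 0.5 + d0]), N=np.array([40.0, 40.0])
        )
        out = evolution_step(state, params, substream_rng(0, "t"))
        assert out.x[1] - out.x[0] > d0

    def test_mutation_mode_preserves_abundances_and_count(self):
        params = self._params(evolution_mode="mutation_selection")
        state = CommunityState(
            x=np.array([0.2, 0.6]), N=np.array([3.0, 7.0])
        )
        out = evolution_step(state, params, substream_rng(1, "t"))
        assert out.n_species == 2
        assert np.array_equal(out.N, state.N)
        assert not np.array_equal(out.x, state.x)

    def test_positions_stay_within_axis(self):
        params = self._params(evolution_mode="mutation_selection",
                              evolution_step_sd=0.05)
        state = CommunityState(
            x=np.array([0.001, 0.999]), N=np.array([1.0, 1.0])
        )
        rng = substream_rng(2, "t")
        for _ in range(50):
            state = evolution_step(state, params, rng)
            assert np.all((state.x >= 0.0) & (state.x <= 1.0))

    def test_mode_none_instructs_caller_to_skip(self):
        params = self._params(evolution_mode="none")
        state = CommunityState(x=np.array([0.5]), N=np.array([1.0]))
        with pytest.raises(ValueError, match="skip"):
            evolution_step(state, params, substream_rng(0, "t"))


class TestRunSimulation:
    def test_seeded_determinism(self):
        params = SimulationParams(n_species=30, t_max=50.0, seed=11)
        a = run_simulation(params)
        b = run_simulation(params)
        assert np.array_equal(a.final_state.x, b.final_state.x)
        assert np.array_equal(a.final_state.N, b.final_state.N)

    def test_wide_kernel_behaves_as_single_niche(self):
        """With the kernel much wider than the axis every species competes
        with every other at full strength, so total abundance approaches the
        single-niche carrying capacity K0."""
        params = SimulationParams(
            n_species=50, sigma_alpha=10.0, evolution_mode="none",
            t_max=200.0, dt=0.1, extinction_threshold=0.0, seed=4,
        )
        res = run_simulation(params)
        assert res.final_state.N.sum() == pytest.approx(params.K0, rel=0.01)

    def test_abundances_never_negative_along_trajectory(self):
        params = SimulationParams(
            n_species=50, t_max=200.0, record_interval=20.0, seed=6
        )
        res = run_simulation(params)
        assert len(res.trajectory) >= 5
        for t, x, N in res.trajectory:
            assert np.all(N >= 0)
        times = [t for t, _, _ in res.trajectory]
        assert times == sorted(times)

    def test_lumpy_pattern_emerges_at_two_seeds(self):
        """Short Fig-1-style runs break the symmetric start into several
        distinct position clusters (the implementation as its own oracle at
        two seeds)."""
        for seed in (11, 12):
            params = SimulationParams(
                n_species=100, sigma_alpha=0.05, t_max=4000.0, seed=seed
            )
            res = run_simulation(params)
            lumps = lump_summary(
                res.final_state, gap_threshold=0.5 * params.sigma_alpha
            )
            assert len(lumps) >= 2


class TestLumpSummary:
    def test_two_clusters_by_gap(self):
        state = CommunityState(
            x=np.array([0.10, 0.11, 0.50]), N=np.array([1.0, 1.0, 2.0])
        )
        lumps = lump_summary(state, gap_threshold=0.05)
        assert [m for _, _, m in lumps] == [2, 1]

    def test_identical_positions_form_one_lump(self):
        state = CommunityState(
            x=np.array([0.3, 0.3, 0.3]), N=np.array([1.0, 2.0, 3.0])
        )
        lumps = lump_summary(state, gap_threshold=0.01)
        assert len(lumps) == 1
        assert lumps[0][0] == pytest.approx(0.3)

    def test_lump_abundances_conserve_total(self):
        rng = np.random.default_rng(3)
        state = CommunityState(x=rng.uniform(0, 1, 40), N=rng.uniform(0, 5, 40))
        lumps = lump_summary(state, gap_threshold=0.02)
        assert sum(a for _, a, _ in lumps) == pytest.approx(state.N.sum())
        assert sum(m for _, _, m in lumps) == 40

    def test_empty_community_gives_empty_list(self):
        state = CommunityState(x=np.empty(0), N=np.empty(0))
        assert lump_summary(state, gap_threshold=0.1) == []
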