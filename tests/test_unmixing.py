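"""Two- and n-pair unmixing: exact solves, fixed-point iteration, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcfret import (
    FretAcquisition,
    PairSimSpec,
    PcfretError,
    UnresolvablePairsError,
    fret_efficiency,
    iterative_unmix,
    power_law_pair_model,
    simulate_acquisition,
    solve_n_component,
    solve_two_component,
    unmix_timeseries,
)
from conftest import THETA_RANGE, forward_oracle_grid


class TestTwoComponentSolve:
    def test_hand_value(self):
        (dd1, dd2), _ = solve_two_component(
            2000, 1300, 0, 0, rho_d1=0.3, rho_d2=1.0, rho_a1=0.3, rho_a2=1.0
        )
        assert dd1 == pytest.approx(1000.0)
        assert dd2 == pytest.approx(1000.0)

    def test_single_species_limit(self):
        (dd1, dd2), _ = solve_two_component(
            500, 150, 0, 0, rho_d1=0.3, rho_d2=1.0, rho_a1=0.3, rho_a2=1.0
        )
        assert dd1 == pytest.approx(500.0)
        assert dd2 == pytest.approx(0.0, abs=1e-12)

    def test_singular_ratios_rejected(self):
        with pytest.raises(UnresolvablePairsError, match="donor"):
            solve_two_component(100, 50, 100, 50, 0.5, 0.5, 0.2, 0.9)
        with pytest.raises(UnresolvablePairsError, match="acceptor"):
            solve_two_component(100, 50, 100, 50, 0.2, 0.9, 0.5, 0.51)

    @given(
        s1=st.floats(0, 1e5), s2=st.floats(0, 1e5),
        a1=st.floats(0, 1e5), a2=st.floats(0, 1e5),
        r1=st.floats(0.05, 0.45), r2=st.floats(0.55, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_conservation_and_exactness(self, s1, s2, a1, a2, r1, r2):
        # forward-mix known components, invert, check recovery + sums
        dd_on, dd_off = s1 + s2, r1 * s1 + r2 * s2
        da_on, da_off = a1 + a2, r1 * a1 + r2 * a2
        (o1, o2), (p1, p2) = solve_two_component(
            dd_on, dd_off, da_on, da_off, r1, r2, r1, r2
        )
        assert o1 + o2 == pytest.approx(dd_on, rel=1e-9, abs=1e-9)
        assert p1 + p2 == pytest.approx(da_on, rel=1e-9, abs=1e-9)
        assert o1 == pytest.approx(s1, rel=1e-7, abs=1e-6)
        assert p1 == pytest.approx(a1, rel=1e-7, abs=1e-6)


class TestNComponentSolve:
    def test_reduces_to_two_component(self):
        rho = np.array([[1.0, 0.3], [1.0, 0.9]])
        truth = np.array([700.0, 1300.0])
        signals = rho.T @ truth
        comp, cond = solve_n_component(signals, rho)
        ref, _ = solve_two_component(
            signals[0], signals[1], 0, 0, 0.3, 0.9, 0.3, 0.9
        )
        assert comp == pytest.approx(truth)
        assert comp == pytest.approx(np.array(ref))
        assert cond > 1

    def test_three_pair_exact_recovery(self):
        rho = np.array([
            [1.0, 0.5, 0.25],
            [1.0, 0.9, 0.81],
            [1.0, 1.0, 1.0],
        ])
        truth = np.array([100.0, 250.0, 400.0])
        signals = rho.T @ truth
        comp, _ = solve_n_component(signals, rho)
        assert comp == pytest.approx(truth, rel=1e-10)

    def test_rank_deficient_rejected(self):
        rho = np.array([[1.0, 0.5, 0.25], [1.0, 0.5, 0.25], [1.0, 1.0, 1.0]])
        with pytest.raises(UnresolvablePairsError, match="condition"):
            solve_n_component(np.ones(3), rho, channel="donor")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(PcfretError):
            solve_n_component(np.ones(3), np.ones((2, 3)))


class TestIterativeUnmix:
    def test_noiseless_recovery(self, sim_specs, pair_models):
        on, off = simulate_acquisition(sim_specs, [0.35, 0.10], noise=False)
        res = iterative_unmix(on, off, pair_models)
        assert res.converged and res.iterations <= 20
        assert res.theta == pytest.approx([0.35, 0.10], abs=1e-6)

    def test_matches_brute_force_oracle(self, sim_specs, pair_models):
        grid = np.linspace(*THETA_RANGE, 31)
        for t1, t2 in [(0.0, 0.6), (0.2, 0.2), (0.52, 0.08)]:
            on, off = simulate_acquisition(sim_specs, [t1, t2], noise=False)
            res = iterative_unmix(on, off, pair_models)
            o1, o2 = forward_oracle_grid(on, off, sim_specs, grid)
            cell = grid[1] - grid[0]
            assert abs(res.theta[0] - o1) <= cell
            assert abs(res.theta[1] - o2) <= cell

    def test_photostatic_pairs_unresolvable(self, sim_specs):
        static = PairSimSpec(4000.0, 1.0)
        models = (power_law_pair_model("a", static, THETA_RANGE),
                  power_law_pair_model("b", static, THETA_RANGE))
        on, off = simulate_acquisition((static, static), [0.3, 0.1], noise=False)
        with pytest.raises(UnresolvablePairsError):
            iterative_unmix(on, off, models)

    def test_pure_pair_consistent_with_single_sensor_analysis(self, pair_models):
        spec = PairSimSpec(4000.0, 0.3)
        on, off = simulate_acquisition(
            (spec, PairSimSpec(0.0, 1.0)), [0.4, 0.0], noise=False
        )
        res = iterative_unmix(on, off, pair_models)
        assert res.s_dd_on[1] == pytest.approx(0.0, abs=1e-9)
        assert res.s_da_on[1] == pytest.approx(0.0, abs=1e-9)
        # with alpha = delta = 0, F_c = S_DA: same theta as single-sensor path
        single = fret_efficiency(on.s_da, on.s_dd, gamma=1.0)
        assert res.theta[0] == pytest.approx(single, abs=1e-9)

    def test_pair_swap_symmetry(self, sim_specs, pair_models):
        on, off = simulate_acquisition(sim_specs, [0.45, 0.15], noise=False)
        res = iterative_unmix(on, off, pair_models)
        swapped = iterative_unmix(on, off, (pair_models[1], pair_models[0]))
        assert swapped.theta == pytest.approx(res.theta[::-1], abs=1e-9)
        assert swapped.s_dd_on == pytest.approx(res.s_dd_on[::-1], abs=1e-6)

    def test_fixed_point_independent_of_start(self, sim_specs, pair_models):
        on, off = simulate_acquisition(sim_specs, [0.30, 0.50], noise=False)
        ref = iterative_unmix(on, off, pair_models).theta
        starts = np.linspace(0.0, 0.6, 5)
        for a in starts:
            for b in starts:
                res = iterative_unmix(on, off, pair_models, metric_init=(a, b))
                assert res.converged
                assert res.theta == pytest.approx(ref, abs=1e-5)

    def test_conservation_under_noise(self, sim_specs, pair_models):
        rng = np.random.default_rng(11)
        for _ in range(20):
            thetas = rng.uniform(*THETA_RANGE, size=2)
            on, off = simulate_acquisition(sim_specs, thetas, rng=rng)
            res = iterative_unmix(on, off, pair_models)
            assert np.sum(res.s_dd_on) == pytest.approx(on.s_dd, rel=1e-9)
            assert np.sum(res.s_da_on) == pytest.approx(on.s_da, rel=1e-9)

    def test_dark_acceptor_pair_contributes_zero(self, sim_specs, pair_models):
        import dataclasses

        dark = dataclasses.replace(pair_models[1], dark_acceptor=True)
        spec_dark = PairSimSpec(4000.0, 1.0, gamma=1.0)
        # pair 2 quenches its donor via FRET but emits nothing in S_DA
        on_dd = 4000 * (1 - 0.4) + 4000 * (1 - 0.2)
        on_da = 4000 * 0.4  # pair 1 only
        r1 = 0.3 ** (1 - 0.4)
        off_dd = r1 * 4000 * (1 - 0.4) + 1.0 * 4000 * (1 - 0.2)
        off_da = r1 * on_da
        on = FretAcquisition(s_dd=on_dd, s_da=on_da, state="on")
        off = FretAcquisition(s_dd=off_dd, s_da=off_da, state="off")
        res = iterative_unmix(on, off, (pair_models[0], dark))
        assert res.s_da_on[1] == 0.0
        assert np.isnan(res.theta[1])
        assert res.theta[0] == pytest.approx(0.4, abs=1e-6)
        assert res.s_dd_on == pytest.approx([2400.0, 3200.0], rel=1e-6)


class TestTimeseries:
    def test_constant_signal_constant_theta(self, sim_specs, pair_models):
        on, off = simulate_acquisition(sim_specs, [0.25, 0.45], noise=False)
        trace = [(on, off)] * 5
        results = unmix_timeseries(trace, pair_models)
        for res in results:
            assert res.theta == pytest.approx([0.25, 0.45], abs=1e-6)

    def test_step_in_pair1_leaves_pair2_flat(self, sim_specs, pair_models):
        thetas = [(0.1, 0.3)] * 4 + [(0.5, 0.3)] * 4
        trace = [simulate_acquisition(sim_specs, th, noise=False)
                 for th in thetas]
        results = unmix_timeseries(trace, pair_models)
        t1 = np.array([r.theta[0] for r in results])
        t2 = np.array([r.theta[1] for r in results])
        assert t1[:4] == pytest.approx(0.1, abs=1e-6)
        assert t1[4:] == pytest.approx(0.5, abs=1e-6)
        assert t2 == pytest.approx(0.3, abs=1e-6)

    def test_empty_trace(self, pair_models):
        assert unmix_timeseries([], pair_models) == []
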