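"""Simulation, attractor classification and peak-sequence extraction."""

import numpy as np
import pytest

from ctln.digraph import base_graph, build_from_name
from ctln.dynamics import (
    AttractorRecord,
    ClassifyOptions,
    SimOptions,
    Trajectory,
    battery,
    classify_trajectory,
    extract_sequence,
    orbit_distance,
    rhs,
    same_attractor,
    sequence_string,
    simulate,
    simulate_batch,
)
from ctln.network import CTLNParams, build_W, enumerate_FP, fixed_point_value


def _perturbed_fp(G, support, std, seed=0, eta=0.05):
    rng = np.random.default_rng(seed)
    x = np.array([float(v) for v in fixed_point_value(G, support, std)])
    return np.maximum(x + eta * rng.standard_normal(G.n), 0.0)


def _attractor(G, std, x0, T=400.0):
    W = build_W(G, std)
    t, X = simulate_batch(W, float(std.theta), np.asarray(x0)[None, :], T, 0.01,
                          record_from=T - 200)
    return classify_trajectory(Trajectory(t, X[:, 0, :], float(std.theta)))


class TestRHS:
    def test_zero_at_fixed_point(self, fig3_graph, std):
        W = build_W(fig3_graph, std)
        x = np.array([float(v) for v in fixed_point_value(fig3_graph, {1, 2, 3}, std)])
        assert np.allclose(rhs(x, W, 1.0), 0, atol=1e-12)

    def test_at_origin(self, std):
        W = build_W(base_graph("3cyc"), std)
        assert np.allclose(rhs(np.zeros(3), W, 1.0), 1.0)

    def test_instability_seed(self, std):
        W = build_W(base_graph("3cyc"), std)
        x = np.full(3, 4 / 13) + np.array([1e-3, 0, 0])
        assert np.linalg.norm(rhs(x, W, 1.0)) > 0


class TestSimulate:
    def test_nonnegative_and_shape(self, std):
        traj = simulate(base_graph("3cyc"), std, [0.2, 0.1, 0.0], T=50)
        assert np.all(traj.x >= 0)
        assert traj.x.shape == (len(traj.t), 3)

    def test_adaptive_matches_rk4(self, std):
        x0 = [0.2, 0.1, 0.0]
        a = simulate(base_graph("3cyc"), std, x0, T=30)
        b = simulate(
            base_graph("3cyc"), std, x0, T=30,
            opts=SimOptions(method="RK45", rtol=1e-10, atol=1e-13),
        )
        assert np.max(np.abs(a.x - b.x)) < 1e-6

    def test_rejects_negative_x0(self, std):
        with pytest.raises(ValueError):
            simulate(base_graph("3cyc"), std, [-0.1, 0, 0], T=10)


class TestBattery:
    def test_counts_with_three_fps(self, fig3_graph, std):
        fps = enumerate_FP(fig3_graph, std)
        ics = battery(fig3_graph, fps, n_random=10)
        # 3 fps x (2*4 coordinate + 10 random) + 16 corners
        assert len(ics) == 3 * 18 + 16

    def test_corners_only_without_fps(self, std):
        ics = battery(base_graph("3cyc"), None)
        assert len(ics) == 8
        assert all(lbl.startswith("corner:") for lbl, _ in ics)

    def test_reproducible(self, fig3_graph, std):
        fps = enumerate_FP(fig3_graph, std)
        a = battery(fig3_graph, fps, seed=7)
        b = battery(fig3_graph, fps, seed=7)
        assert all(np.array_equal(x, y) for (_, x), (_, y) in zip(a, b))


class TestClassification:
    def test_three_cycle_limit_cycle(self, std):
        rec = _attractor(base_graph("3cyc"), std, [0.2, 0.1, 0.0])
        assert rec.kind == "limit_cycle"
        assert rec.sequence_str == "123"
        assert rec.high_set == frozenset({1, 2, 3})
        assert rec.period == pytest.approx(11.24, abs=0.05)

    def test_fig3_static_attractor(self, fig3_graph, std):
        rec = _attractor(fig3_graph, std, _perturbed_fp(fig3_graph, {4}, std))
        assert rec.kind == "stable_fp"
        assert rec.high_set == frozenset({4})

    def test_fig3_dynamic_attractor(self, fig3_graph, std):
        rec = _attractor(fig3_graph, std, _perturbed_fp(fig3_graph, {1, 2, 3}, std))
        assert rec.kind == "limit_cycle"
        assert rec.high_set == frozenset({1, 2, 3})
        assert rec.low_set == frozenset({4})

    def test_d_attractor_low_firing_node4(self, std):
        G = base_graph("D")
        rec = _attractor(G, std, _perturbed_fp(G, {1, 2, 3}, std))
        assert rec.sequence_str == "1234"
        assert rec.low_set == frozenset({4})

    def test_synchronous_sequence_att21(self, std):
        # S1[3] has a (2,5) exchange symmetry: nodes 2 and 5 peak together
        G = build_from_name("S1[3]")
        rec = _attractor(G, std, _perturbed_fp(G, {1, 2, 3, 4}, std), T=600)
        assert rec.kind == "limit_cycle"
        assert rec.sequence_str == "1(25)34"

    def test_perturbation_returns_to_stable_fp(self, fig3_graph, std):
        rec = _attractor(fig3_graph, std, _perturbed_fp(fig3_graph, {4}, std, seed=3))
        x_final = rec.orbit[-1]
        assert np.allclose(x_final, [0, 0, 0, 1], atol=1e-5)


class TestSequenceExtraction:
    def _synthetic_orbit(self, peaks, m=256, width=0.02):
        """Gaussian bumps at given phase positions (neuron -> list of
        (phase, height))."""
        n = max(peaks) if peaks else 0
        orbit = np.zeros((m, n))
        ph = np.arange(m) / m
        for neuron, events in peaks.items():
            for center, height in events:
                d = np.minimum(np.abs(ph - center), 1 - np.abs(ph - center))
                orbit[:, neuron - 1] += height * np.exp(-(d**2) / width**2)
        return orbit

    def test_simple_order(self):
        orbit = self._synthetic_orbit({1: [(0.1, 1.0)], 2: [(0.4, 1.0)], 3: [(0.7, 1.0)]})
        seq, high, low = extract_sequence(orbit, period=10.0)
        assert sequence_string(seq) == "123"
        assert high == {1, 2, 3} and not low

    def test_low_firing_marked(self):
        orbit = self._synthetic_orbit(
            {1: [(0.1, 1.0)], 2: [(0.4, 1.0)], 3: [(0.7, 0.2)]}
        )
        seq, high, low = extract_sequence(orbit, period=10.0)
        assert low == {3} and high == {1, 2}
        assert sequence_string(seq) == "123"

    def test_synchrony_grouped(self):
        orbit = self._synthetic_orbit(
            {1: [(0.1, 1.0)], 2: [(0.5, 1.0)], 3: [(0.502, 1.0)]}
        )
        seq, _, _ = extract_sequence(orbit, period=10.0)
        assert sequence_string(seq) == "1(23)"

    def test_repeated_word_collapses(self):
        orbit = self._synthetic_orbit(
            {1: [(0.1, 1.0), (0.6, 0.9)], 2: [(0.3, 1.0), (0.8, 0.9)]}
        )
        seq, _, _ = extract_sequence(orbit, period=20.0)
        assert sequence_string(seq) == "12"

    def test_starts_at_lowest_high_neuron(self):
        orbit = self._synthetic_orbit({2: [(0.1, 1.0)], 1: [(0.5, 1.0)]})
        seq, _, _ = extract_sequence(orbit, period=10.0)
        assert sequence_string(seq) == "12"

    def test_silent_neurons_excluded(self):
        orbit = self._synthetic_orbit({1: [(0.1, 1.0)], 2: [(0.5, 1.0)], 3: [(0.9, 0.001)]})
        seq, high, low = extract_sequence(orbit, period=10.0)
        assert sequence_string(seq) == "12"
        assert 3 not in high | low


class TestSameAttractor:
    def test_identity(self, std):
        rec = _attractor(base_graph("3cyc"), std, [0.2, 0.1, 0.0])
        assert same_attractor(rec, rec)

    def test_d_and_e_attractors_match(self, std):
        a = _attractor(base_graph("D"), std, _perturbed_fp(base_graph("D"), {1, 2, 3}, std))
        b = _attractor(base_graph("E"), std, _perturbed_fp(base_graph("E"), {1, 2, 3}, std))
        assert same_attractor(a, b)

    def test_d_and_t_attractors_differ(self, std, fig3_graph):
        a = _attractor(base_graph("D"), std, _perturbed_fp(base_graph("D"), {1, 2, 3}, std))
        b = _attractor(fig3_graph, std, _perturbed_fp(fig3_graph, {1, 2, 3}, std))
        assert not same_attractor(a, b)

    def test_relabel_roundtrip(self, std):
        rec = _attractor(base_graph("3cyc"), std, [0.2, 0.1, 0.0])
        perm = {1: 2, 2: 3, 3: 1}
        back = {2: 1, 3: 2, 1: 3}
        assert same_attractor(rec.relabel(perm).relabel(back), rec)

    def test_orbit_distance_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random((256, 5))
        assert orbit_distance(a, np.roll(a, 37, axis=0)) < 1e-12


class TestNonNegativity:
    def test_battery_trajectories_stay_nonnegative(self, fig3_graph, std):
        fps = enumerate_FP(fig3_graph, std)
        ics = battery(fig3_graph, fps, n_random=3)
        W = build_W(fig3_graph, std)
        X0 = np.stack([x for _, x in ics])
        _, X = simulate_batch(W, 1.0, X0, 60.0, 0.01)
        assert np.all(X >= 0)
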