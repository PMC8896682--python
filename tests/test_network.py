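"""CTLN weight matrices and exact fixed-point theory."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctln.digraph import Digraph, base_graph, build_from_name
from ctln.network import (
    CTLNParams,
    DegeneracyError,
    IllegalParameterError,
    STANDARD_GRID,
    build_W,
    check_parameter_independence,
    enumerate_FP,
    fixed_point_value,
    is_fixed_point_support,
    stability,
)


class TestParams:
    def test_standard_values(self, std):
        assert (std.eps, std.delta, std.theta) == (Fraction(1, 4), Fraction(1, 2), 1)
        assert std.is_legal and std.is_exact

    def test_high_inhibition_legal(self):
        assert CTLNParams.high_inhibition().is_legal

    @pytest.mark.parametrize(
        "eps,delta,theta",
        [("0.5", "0.5", "1"),   # eps >= delta/(delta+1)
         ("0.25", "0", "1"),    # delta = 0
         ("0.25", "0.5", "0"),  # theta = 0
         ("0", "0.5", "1")],    # eps = 0
    )
    def test_illegal(self, eps, delta, theta):
        p = CTLNParams(eps, delta, theta)
        assert not p.is_legal
        with pytest.raises(IllegalParameterError):
            build_W(base_graph("3cyc"), p)

    def test_decimal_strings_stay_exact(self):
        assert CTLNParams("0.25", "0.5", "1").is_exact


class TestWeightMatrix:
    def test_three_cycle_entries(self, std):
        W = build_W(base_graph("3cyc"), std)
        assert np.allclose(np.diag(W), 0)
        # edge j -> i gives W[i, j] = -0.75; non-edges -1.5
        assert W[1, 0] == pytest.approx(-0.75)
        assert W[0, 1] == pytest.approx(-1.5)

    def test_empty_and_complete(self, std):
        n = 3
        empty = build_W(Digraph(n), std)
        off = ~np.eye(n, dtype=bool)
        assert np.all(empty[off] == pytest.approx(-1.5))
        full = Digraph(n, frozenset((i, j) for i in (1, 2, 3) for j in (1, 2, 3) if i != j))
        assert np.all(build_W(full, std)[off] == pytest.approx(-0.75))


class TestFixedPointValue:
    def test_singleton_is_theta(self, fig3_graph, std):
        x = fixed_point_value(fig3_graph, {4}, std)
        assert x == [0, 0, 0, 1]

    def test_three_cycle_symmetric_value(self, std):
        # symmetry forces x_i = theta / (3 - eps + delta) = 4/13
        x = fixed_point_value(base_graph("3cyc"), {1, 2, 3}, std)
        assert x == [Fraction(4, 13)] * 3

    def test_two_clique(self, std):
        G = Digraph(2, frozenset({(1, 2), (2, 1)}))
        # direct 2x2 solve: x_i = theta / (2 - eps)
        assert fixed_point_value(G, {1, 2}, std) == [Fraction(4, 7)] * 2

    def test_theta_scaling(self, fig3_graph, std):
        doubled = CTLNParams(std.eps, std.delta, 2)
        x1 = fixed_point_value(fig3_graph, {1, 2, 3}, std)
        x2 = fixed_point_value(fig3_graph, {1, 2, 3}, doubled)
        assert x2 == [2 * v for v in x1]


class TestMembership:
    def test_fig3_supports(self, fig3_graph, std):
        assert is_fixed_point_support(fig3_graph, {1, 2, 3}, std)
        assert not is_fixed_point_support(fig3_graph, {1, 4}, std)
        assert not is_fixed_point_support(fig3_graph, {3, 4}, std)

    def test_fig3_fpset(self, fig3_graph, std):
        assert enumerate_FP(fig3_graph, std).support_strings() == ("4", "123", "1234")

    def test_three_cycle_core(self, std):
        assert enumerate_FP(base_graph("3cyc"), std).support_strings() == ("123",)

    def test_f_graph_three_supports(self, std):
        assert enumerate_FP(base_graph("F"), std).support_strings() == ("123", "234", "1234")

    def test_exact_and_float_agree(self, std, census_graphs_n5):
        for G in census_graphs_n5[::19]:
            exact = set(enumerate_FP(G, std, exact=True, with_values=False).supports)
            approx = set(enumerate_FP(G, std, exact=False, with_values=False).supports)
            assert exact == approx


class TestStability:
    def test_sink_stable(self, fig3_graph, std):
        assert stability(fig3_graph, {4}, std) == "stable"

    def test_cycle_fixed_point_unstable(self, std):
        assert stability(base_graph("3cyc"), {1, 2, 3}, std) == "unstable"


class TestDegeneracy:
    def test_singular_matrix_raises(self):
        # at (eps, delta) = (2/5, 1) this oriented graph's full-support
        # matrix I - W_sigma is exactly singular
        G = Digraph(4, frozenset({(1, 2), (1, 3), (1, 4), (2, 3), (3, 4), (4, 2)}))
        p = CTLNParams(Fraction(2, 5), Fraction(1), 2)
        with pytest.raises(DegeneracyError):
            is_fixed_point_support(G, {1, 2, 3, 4}, p)


class TestParameterIndependence:
    def test_fig3_graph(self, fig3_graph):
        ok, witness = check_parameter_independence(fig3_graph)
        assert ok and witness is None

    def test_single_point_grid(self, fig3_graph, std):
        assert check_parameter_independence(fig3_graph, [std])[0]

    def test_grid_is_legal(self):
        assert all(p.is_legal for p in STANDARD_GRID)


class TestParity:
    def test_fp_count_is_odd(self, census_graphs_n5, std):
        for G in census_graphs_n5[::7]:
            assert len(enumerate_FP(G, std, with_values=False)) % 2 == 1


class TestRestriction:
    def test_supports_restrict(self, std, census_graphs_n5):
        from ctln.digraph import induced_subgraph

        for G in census_graphs_n5[::13]:
            for sigma in enumerate_FP(G, std, with_values=False).supports:
                H = induced_subgraph(G, sigma)
                full = frozenset(H.vertices)
                assert full in enumerate_FP(H, std, with_values=False).supports
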