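"""Graph structure, isomorphism, enumeration and the construction notation."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctln.digraph import (
    BASE_IDS,
    Digraph,
    GraphName,
    MasterPattern,
    automorphisms,
    base_graph,
    build_from_name,
    canonical_form,
    constructed_nosource_graphs,
    enumerate_oriented_nosink,
    expand_master,
    induced_subgraph,
    is_isomorphic,
    name_graph,
    source_extensions,
    three_cycle_double_source_graphs,
    uniform_in_degree,
    vertex_roles,
)


def digraphs(max_n=5):
    """Hypothesis strategy for small digraphs."""

    @st.composite
    def build(draw):
        n = draw(st.integers(2, max_n))
        pairs = [(i, j) for i in range(1, n + 1) for j in range(1, n + 1) if i != j]
        edges = draw(st.sets(st.sampled_from(pairs)))
        return Digraph(n, frozenset(edges))

    return build()


class TestDigraphBasics:
    def test_no_self_loops(self):
        with pytest.raises(ValueError):
            Digraph(3, frozenset({(1, 1)}))

    def test_oriented_predicate(self):
        assert base_graph("3cyc").is_oriented()
        assert not Digraph(2, frozenset({(1, 2), (2, 1)})).is_oriented()

    def test_text_roundtrip(self):
        G = build_from_name("D1[2,3]")
        assert Digraph.from_text(G.to_text()) == G

    def test_adjacency_roundtrip(self):
        G = base_graph("F")
        assert Digraph.from_adjacency(G.adjacency_matrix()) == G


class TestInducedSubgraph:
    def test_fig3_three_cycle(self, fig3_graph):
        H = induced_subgraph(fig3_graph, {1, 2, 3})
        assert is_isomorphic(H, base_graph("3cyc"))

    def test_identity_and_singleton(self, fig3_graph):
        assert induced_subgraph(fig3_graph, {1, 2, 3, 4}) == fig3_graph
        single = induced_subgraph(fig3_graph, {2})
        assert single.n == 1 and not single.edges

    def test_bad_sigma(self, fig3_graph):
        with pytest.raises(ValueError):
            induced_subgraph(fig3_graph, set())
        with pytest.raises(ValueError):
            induced_subgraph(fig3_graph, {1, 9})

    @settings(max_examples=50, deadline=None)
    @given(digraphs())
    def test_induced_edges_are_internal(self, G):
        sigma = set(list(G.vertices)[:: 2]) or {1}
        H, mapping = induced_subgraph(G, sigma, return_mapping=True)
        inv = {v: k for k, v in mapping.items()}
        lifted = {(inv[i], inv[j]) for i, j in H.edges}
        assert lifted == {(i, j) for i, j in G.edges if i in sigma and j in sigma}


class TestVertexRoles:
    def test_fig3_sink(self, fig3_graph):
        roles = vertex_roles(fig3_graph)
        assert roles[4].is_sink and not roles[4].is_source
        assert not any(roles[v].is_proper_source for v in (1, 2, 3))

    def test_isolated_vertex(self):
        G = Digraph(2, frozenset({(1, 2)}))  # hmm: 2 is a sink, 1 a proper source
        roles = vertex_roles(G)
        assert roles[1].is_proper_source and roles[2].is_sink
        iso = vertex_roles(Digraph(1))[1]
        assert iso.is_source and iso.is_sink and not iso.is_proper_source

    def test_three_cycle_no_sources_or_sinks(self):
        roles = vertex_roles(base_graph("3cyc"))
        assert not any(r.is_source or r.is_sink for r in roles.values())


class TestUniformInDegree:
    def test_cycle_clique_independent(self):
        assert uniform_in_degree(base_graph("3cyc")) == 1
        clique = Digraph(3, frozenset((i, j) for i in (1, 2, 3) for j in (1, 2, 3) if i != j))
        assert uniform_in_degree(clique) == 2
        assert uniform_in_degree(Digraph(3)) == 0

    def test_non_uniform(self):
        # F graph: vertex 2 has in-degree 2, the rest in-degree 1
        assert uniform_in_degree(base_graph("F")) is None


class TestIsomorphism:
    def test_published_aliases(self):
        assert is_isomorphic(build_from_name("D1[2,3]"), build_from_name("E2[3]"))
        assert is_isomorphic(build_from_name("D3[1,2]"), build_from_name("E3[1]"))

    def test_non_isomorphic(self):
        path = Digraph(3, frozenset({(1, 2), (2, 3)}))
        assert not is_isomorphic(base_graph("3cyc"), path)

    @settings(max_examples=40, deadline=None)
    @given(digraphs(), st.randoms(use_true_random=False))
    def test_canonical_form_is_relabeling_invariant(self, G, rnd):
        perm = list(G.vertices)
        rnd.shuffle(perm)
        H = G.relabel(dict(zip(G.vertices, perm)))
        assert canonical_form(G) == canonical_form(H)

    @settings(max_examples=40, deadline=None)
    @given(digraphs(max_n=4), digraphs(max_n=4))
    def test_agrees_with_networkx(self, G1, G2):
        nx1 = nx.DiGraph(list(G1.edges))
        nx1.add_nodes_from(G1.vertices)
        nx2 = nx.DiGraph(list(G2.edges))
        nx2.add_nodes_from(G2.vertices)
        expected = G1.n == G2.n and nx.is_isomorphic(nx1, nx2)
        assert is_isomorphic(G1, G2) == expected


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 7)])
    def test_small_counts(self, n, count):
        graphs = enumerate_oriented_nosink(n)
        assert len(graphs) == count
        for G in graphs:
            assert G.is_oriented() and not G.sinks()

    def test_n5_census_counts(self, census_graphs_n5):
        assert len(census_graphs_n5) == 152
        with_src = [G for G in census_graphs_n5 if G.proper_sources()]
        assert len(with_src) == 76
        assert len(census_graphs_n5) - len(with_src) == 76

    def test_pairwise_non_isomorphic(self, census_graphs_n5):
        forms = {canonical_form(G) for G in census_graphs_n5}
        assert len(forms) == 152


class TestBaseGraphs:
    def test_ids(self):
        for bid in BASE_IDS:
            assert base_graph(bid).n in (3, 4, 5)
        with pytest.raises(KeyError):
            base_graph("Q")

    def test_t_is_fig3(self, fig3_graph):
        assert base_graph("T") == fig3_graph

    def test_s_is_4cycle(self):
        assert base_graph("S").edges == frozenset({(1, 2), (2, 3), (3, 4), (4, 1)})

    def test_f_has_two_3cycles_and_an_automorphism(self):
        F = base_graph("F")
        assert len(automorphisms(F)) == 2
        c3 = base_graph("3cyc")
        cycles = [
            s for s in itertools.combinations(F.vertices, 3)
            if is_isomorphic(induced_subgraph(F, s), c3)
        ]
        assert sorted(cycles) == [(1, 2, 3), (2, 3, 4)]

    def test_d_e_trivial_automorphisms(self):
        assert len(automorphisms(base_graph("D"))) == 1
        assert len(automorphisms(base_graph("E"))) == 1

    def test_swap_de_swaps(self):
        assert base_graph("D", swap_de=True) == base_graph("E")


class TestSourceExtensionCounts:
    """Fig-6 family counts: 30 + 15 + 15 + 11 + 5 source-group graphs."""

    def test_three_cycle_two_sources(self):
        assert len(three_cycle_double_source_graphs()) == 30

    @pytest.mark.parametrize("base,count", [("D", 15), ("E", 15), ("F", 11), ("S", 5)])
    def test_single_source_extensions(self, base, count):
        assert len(source_extensions(base_graph(base))) == count

    def test_constructed_nosource(self):
        assert len(constructed_nosource_graphs()) == 75


class TestNames:
    def test_build_d1_23(self):
        G = build_from_name("D1[2,3]")
        assert G.n == 5
        assert {(1, 5), (5, 2), (5, 3)} <= G.edges
        assert base_graph("D").edges <= G.edges

    def test_build_s_13_24(self):
        G = build_from_name("S[1,3][2,4]")
        assert {(1, 5), (3, 5), (5, 2), (5, 4)} <= G.edges

    def test_source_name(self):
        G = build_from_name("F0[1]")
        assert G.in_degree(5) == 0 and G.out_neighbors(5) == frozenset({1})

    def test_invalid_names(self):
        with pytest.raises(ValueError):
            GraphName("D", frozenset({1}), frozenset({1}))  # overlap
        with pytest.raises(ValueError):
            GraphName("D", frozenset(), frozenset())  # sink

    def test_parse_roundtrip(self):
        for s in ("D1[2,3]", "S[1,3][2,4]", "F0[1]", "E2[4]"):
            assert str(GraphName.parse(s)) == s


class TestMasterPatterns:
    def test_d2_pattern(self):
        names = {str(n) for n in expand_master("D2[~3,4,*]")}
        assert names == {"D2[4]", "D2[1,4]"}

    def test_tilde_unicode_accepted(self):
        assert expand_master("D2[∼3,4,*]") == expand_master("D2[~3,4,*]")

    def test_s0_star_dedup(self):
        assert len(expand_master("S0[*]", dedupe_isomorphic=True)) == 5

    def test_no_wildcard(self):
        assert [str(n) for n in expand_master("F3[2]")] == ["F3[2]"]

    def test_contradictory(self):
        with pytest.raises(ValueError):
            MasterPattern("D", frozenset({2}), frozenset({3}), frozenset({3}), True)


class TestNameGraph:
    def test_five_cycle_has_no_name(self):
        with pytest.raises(ValueError):
            name_graph(base_graph("5cyc"))

    def test_d1_23_names_include_an_e_name(self):
        names = {str(n) for n in name_graph(build_from_name("D1[2,3]"))}
        assert "D1[2,3]" in names
        assert any(n.startswith("E") for n in names)

    def test_s_13_24_only_s_names(self):
        names = name_graph(build_from_name("S[1,3][2,4]"))
        assert names and all(n.base == "S" for n in names)

    def test_roundtrip_all_nosource(self):
        for nm, G in constructed_nosource_graphs():
            names = name_graph(G)
            assert any(is_isomorphic(build_from_name(n2), G) for n2 in names)
            assert str(nm) in {str(n2) for n2 in names}
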