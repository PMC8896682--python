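"""The taxonomy of oriented graphs with no sinks.

Every 5-vertex oriented graph without sources or sinks -- except the
5-cycle -- can be built from a 4-vertex base graph (D, E, F, T or S) by
adding node 5 with at least one incoming and one outgoing edge; graphs
with sources come from adding source nodes to a base.  Names like
``D1[2,3]`` record the construction; master patterns like ``D2[~3,4,*]``
describe whole families (~ forbidden, * optional edges).
"""

from ctln import build_from_name, enumerate_oriented_nosink, expand_master, is_isomorphic, name_graph

for n in (3, 4, 5):
    graphs = enumerate_oriented_nosink(n)
    n_src = sum(1 for G in graphs if G.proper_sources())
    print(f"n = {n}: {len(graphs)} oriented no-sink graphs "
          f"({n_src} with a proper source, {len(graphs) - n_src} without)")

G = build_from_name("D1[2,3]")
print("\nD1[2,3] edges:", sorted(G.edges))
print("its construction names:", [str(nm) for nm in name_graph(G)])
print("D1[2,3] isomorphic to E2[3]:", is_isomorphic(G, build_from_name("E2[3]")))

print("\nmaster pattern D2[~3,4,*] expands to:",
      [str(nm) for nm in expand_master("D2[~3,4,*]")])
print("master pattern S0[*] up to isomorphism:",
      len(expand_master("S0[*]", dedupe_isomorphic=True)), "graphs")
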