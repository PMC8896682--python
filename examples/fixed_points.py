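"""Exact fixed-point analysis of a small CTLN.

The example graph is a 3-cycle 1 -> 2 -> 3 -> 1 feeding a sink node 4.
Its fixed-point supports can be derived by hand with the graph rules,
and the exact rational values follow from x_sigma = theta (I - W_sigma)^{-1} 1.
"""

from ctln import CTLNParams, base_graph, enumerate_FP
from ctln.graph_rules import decide_by_rules

G = base_graph("T")  # 3-cycle plus sink: edges 12, 23, 31, 34
params = CTLNParams.standard()  # eps = 1/4, delta = 1/2, theta = 1

print("graph edges:", sorted(G.edges))
print("\nGraph-rule derivation (support, verdict, deciding rule):")
for support, d in sorted(decide_by_rules(G).items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    if d.verdict == "in":
        print("  %-5s in   (%s)" % ("".join(map(str, sorted(support))), d.rule))

fps = enumerate_FP(G, params)
print("\nNumerical enumeration, FP(G) =", fps.support_strings())
for fp in fps.fixed_points:
    sup = "".join(map(str, sorted(fp.support)))
    print(f"  {sup:5s} {'stable' if fp.stable else 'unstable':8s} x* = {[str(v) for v in fp.value]}")

# The sink {4} is the static attractor; the 3-cycle fixed point seeds a
# limit cycle; the full support 1234 is an unstable "tipping point"
# between the two basins.
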