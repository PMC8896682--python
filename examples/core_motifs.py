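"""Core motifs and core fixed points.

A core motif is a graph whose CTLN has exactly one fixed-point support
(the full vertex set); core fixed points of a larger network are the
surviving fixed points whose support induces a core motif.  They predict
the network's attractors.
"""

from ctln import CTLNParams, base_graph, build_from_name, core_fixed_points, enumerate_core_motifs, is_core_motif

params = CTLNParams.standard()

for n in (1, 2, 3, 4):
    motifs = enumerate_core_motifs(n)
    print(f"core motifs on n = {n} vertices: {len(motifs)} isomorphism classes")

print("\n3-cycle is a core motif:", is_core_motif(base_graph("3cyc")))
print("F graph is a core motif:", is_core_motif(base_graph("F")),
      " (it has three fixed points: 123, 234, 1234)")

for lbl in ("T4[1]", "F1[3]", "S[1,3][2,4]"):
    cores = core_fixed_points(build_from_name(lbl), params)
    print(f"core fixed points of {lbl}:",
          sorted("".join(map(str, sorted(s))) for s in cores))
# F1[3] predicts three attractors; at standard parameters only two are
# realized -- the 135 prediction is a "ghost" until inhibition is raised.
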