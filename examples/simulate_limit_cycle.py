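"""Simulate the 3-cycle CTLN and extract its attractor.

Activity follows the arrows of the graph: the limit cycle peaks in the
cyclic order 1, 2, 3.  The printed period and peak sequence describe the
detected attractor.
"""

import numpy as np

from ctln import CTLNParams, base_graph, classify_trajectory, simulate

G = base_graph("3cyc")
params = CTLNParams.standard()

traj = simulate(G, params, x0=[0.2, 0.1, 0.0], T=400)
print("simulated", len(traj.t), "samples; final state:", np.round(traj.x[-1], 4))

rec = classify_trajectory(traj)
print("attractor type :", rec.kind)
print("peak sequence  :", rec.sequence_str)   # cyclic order of firing-rate peaks
print("period         :", round(rec.period, 3), "time units")
print("high-firing    :", sorted(rec.high_set))

# The same machinery annotates low-firing participants and synchronous
# peaks; e.g. the graph D2[4] yields the sequence 12(35)4, with nodes 3
# and 5 peaking together.
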