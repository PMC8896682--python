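# ctln — combinatorial threshold-linear networks

Tools for studying how the *architecture* of a recurrent network shapes
its dynamics, in the one model family where the question is tractable:
combinatorial threshold-linear networks (CTLNs).  A CTLN is the
firing-rate system

```
dx_i/dt = -x_i + [ Σ_j W_ij x_j + θ ]₊ ,
```

whose weights are read off a directed graph G: `W_ij = -1+ε` when
`j → i` is an edge, `-1-δ` when it is not, `0` on the diagonal, with
δ > 0, θ > 0 and 0 < ε < δ/(δ+1).  Every interaction is inhibitory, but
edges inhibit less than non-edges, so activity follows the arrows of the
graph — and the network's fixed points, limit cycles and stranger
attractors become functions of graph combinatorics.

The package is for computational neuroscientists and applied
dynamicists who want to

* enumerate the fixed-point supports FP(G) **exactly** (rational
  arithmetic; a sign condition never flips through rounding), or decide
  them symbolically with the parameter-free graph rules (sources, sinks,
  uniform in-degree, parity);
* find **core motifs** — subgraphs whose CTLN has a unique fixed-point
  support — and the core fixed points that predict a network's
  attractors;
* simulate the dynamics, detect and classify attractors, and extract
  annotated **peak sequences** such as `1(25)34` (parentheses =
  synchronous peaks, separately reported low-firing participants);
* reproduce the exhaustive **attractor census** of all 152 oriented
  5-vertex graphs with no sinks: 191 core fixed points, 185 realized
  attractors, 6 ghosts, 0 spurious, 25 attractor classes, and the
  high-inhibition rescue of every ghost.

## Worked example

The classic four-neuron example: a 3-cycle feeding a sink
(edges 1→2, 2→3, 3→1, 3→4).

```python
>>> from ctln import CTLNParams, base_graph, enumerate_FP
>>> G = base_graph("T")                 # the 3-cycle + sink graph
>>> fps = enumerate_FP(G, CTLNParams.standard())
>>> fps.support_strings()
('4', '123', '1234')
```

Running `python examples/fixed_points.py` prints the full analysis:

```
Numerical enumeration, FP(G) = ('4', '123', '1234')
  4     stable   x* = ['0', '0', '0', '1']
  123   unstable x* = ['4/13', '4/13', '4/13', '0']
  1234  unstable x* = ['4/19', '4/19', '4/19', '4/19']
```

Three fixed points: the sink `{4}` is a stable (static) attractor; the
unstable `123` fixed point seeds a limit cycle whose high-firing neurons
peak in the cyclic order 1, 2, 3; the full-support fixed point is a
"tipping point" on the boundary of the two basins.  The values are exact
rationals — e.g. x* = θ/(3−ε+δ) = 4/13 on the 3-cycle.

Attractor prediction on a five-neuron graph, including a *ghost*
(`python examples/attractor_prediction.py`):

```
D2[4] at standard (delta = 0.5):
  core 1245   realized: limit_cycle, sequence 12(35)4
  core 123    GHOST (no corresponding attractor)
  spurious attractors: 0

D2[4] at high inhibition (delta = 1.25):
  core 123    realized: limit_cycle, sequence 12534
  core 1245   realized: limit_cycle, sequence 12354
  spurious attractors: 0
```

The graph `D2[4]` predicts two attractors from its two core fixed
points; at the standard parameters only `1245` is realized (nodes 3 and
5 fire synchronously, written `12(35)4`), while `123` is a ghost that
appears once the inhibition δ is raised to 1.25.

More narrative scripts live in `examples/`: graph taxonomy and
construction names (`taxonomy.py`), core motifs (`core_motifs.py`),
simulation and sequence extraction (`simulate_limit_cycle.py`).

## Command line

A thin CLI mirrors the library:

```bash
ctln enumerate --n 5 --no-source        # 76 graphs, edge-list format
ctln fp --name "D1[2,3]"                # exact FP(G) with stability
ctln rules --name "F0[1]"               # symbolic membership per support
ctln core --name "F1[3]"                # core-motif report (JSON)
ctln simulate --name "T4[1]" --x0 0.2,0.1,0,0,0 --t 200 --out traj.csv
ctln attractors --name "D2[4]"          # battery + ghost/spurious report
ctln census --out report.json --classify --rescue   # the full experiment
```

Graphs are accepted as construction names (`D1[2,3]`, `S[1,3][2,4]`),
edge-list text files (`n 5` header, one `i j` line per edge) or 0/1
adjacency CSV.

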