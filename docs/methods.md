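# Methods

## The model

A combinatorial threshold-linear network (CTLN) is the firing-rate system

    dx_i/dt = -x_i + [ Σ_j W_ij x_j + θ ]_+ ,   i = 1..n,

with `[u]_+ = max(0, u)` and a weight matrix read off a simple directed
graph `G`:

    W_ij = 0        if i = j,
    W_ij = -1 + ε   if j -> i is an edge of G,
    W_ij = -1 - δ   if j -> i is not an edge (i ≠ j).

The parameters are constrained to the legal range δ > 0, θ > 0,
0 < ε < δ/(δ+1), which makes the network inhibition-dominated: every
interaction is net-inhibitory, but edges inhibit *less* than non-edges,
so activity flows along the arrows of the graph.  Defaults are the
standard parameters (ε, δ, θ) = (1/4, 1/2, 1); the high-inhibition regime
(1/4, 5/4, 1) is used to rescue ghost attractors.  All three parameters
are kept as exact rationals whenever they are given as int, `Fraction`
or decimal string.

## Fixed points

A fixed point is labeled by its support σ (the set of strictly positive
coordinates).  On the support it solves `x_σ = θ (I - W_σ)^{-1} 1`; off
the support each neuron must receive strictly negative net input.
Membership of σ in FP(G) is therefore a finite set of strict sign
conditions, which we evaluate with exact rational Gaussian elimination —
a sign can then never flip through rounding.  A floating-point backend
(strictness tolerance 1e-9) exists for irrational parameters; on the full
n = 5 census the two backends agree support-for-support.

Degeneracy (a singular `I - W_σ`, a zero on-support value, or zero net
input to an off-support neuron) raises an error instead of deciding.
The theory assumes nondegeneracy; genericity makes this rare, but exact
parameter choices can trip it — e.g. (ε, δ) = (2/5, 1) makes `I - W_σ`
exactly singular for some 5-vertex supports, which is why the default
parameter-independence grid uses (7/20, 9/10, 2) as its fourth point.

Stability is decided by the eigenvalues of `-I + W_σ` (the off-support
conditions are strict by nondegeneracy); eigenvalues within 1e-9 of the
imaginary axis raise an indeterminate-stability error.

The parameter-free graph rules (sources, sinks, uniform in-degree,
parity) are implemented purely combinatorially and used as an
independent second route to FP(G); parity is applied only when exactly
one support remains undecided.  The rules are sound but incomplete; the
numeric enumerator fills the gaps.

## The graph taxonomy

The census universe is the set of oriented (no bidirectional edges)
graphs with no sinks on five vertices: 152 isomorphism classes, split
76/76 by the presence of a proper source.  Enumeration generates all
3^10 labeled oriented graphs and buckets by a canonical form (the
minimal flattened adjacency matrix over all vertex permutations — brute
force is exact and instant at this scale).

Graphs are held in *taxonomy coordinates*: a base graph (3-cycle, D, E,
F, T or S) on vertices 1..4 plus an added node.  The D and E labelings
are pinned jointly by the published isomorphisms `D1[2,3] ≅ E2[3]` and
`D3[1,2] ≅ E3[1]` and by the requirement that the D/E attractor sequence
is 1234 with node 4 (fed by node 3) peaking last:

    D = 3-cycle + {3->4, 4->1},    E = 3-cycle + {3->4, 4->1, 4->2}.

A `swap_de` flag exchanges the letters; it renames families and changes
no count.  Construction names (`D1[2,3]`), master patterns
(`D2[~3,4,*]`) and the reverse lookup (`name_graph`) follow the
bracket notation; one isomorphism class can carry several names (e.g.
`D2[4] ≅ S1[3,4]`), and the set of all name presentations of a graph
supplies the vertex alignments used when comparing attractors across
graphs.

## Core fixed points

σ is a *core* fixed point when σ ∈ FP(G) and FP(G|_σ) = {σ}; its induced
subgraph is then a *core motif*.  Core-ness is decided with the exact
backend at the standard parameters (a grid option re-checks at other
legal points).  Core supports form an antichain (they are minimal in
FP(G)), a fact the attractor-matching step relies on.  Across the census
there are 191 core fixed points: 87 in the source group, 104 in the
no-source group.

## Simulation and attractor detection

Two integration paths exist: adaptive `solve_ivp` for single
trajectories, and a vectorized fixed-step RK4 scheme (step 0.01 time
units) that advances a whole battery of initial conditions per graph at
once — the census needs ~15,000 trajectories, and batching them makes
the full run a matter of minutes on one core.  The state stays
non-negative up to clipping of O(dt^5) undershoots.  Halving the step
changes no census verdict (tested on the ghost graphs and the hardest
classification cases).

The initial-condition battery per graph: for *every* fixed point, the 2n
coordinate perturbations ±0.05 eᵢ and 10 seeded random perturbations of
norm 0.05, plus the 2^n corners of the unit cube.  Per-graph random
seeds are derived from a master seed and the canonical form, so the
census is reproducible and order-independent.

Classification looks at the final 150 time units of a 500-unit run
(unresolved trajectories are re-run to 1500, then 5000):

* fluctuation below 1e-6 → stable fixed point;
* otherwise peak times of the widest-swinging neuron give period
  candidates (median m-step intervals, m = 1..6, since the true period
  may span several passes); a candidate is accepted when the
  interpolated recurrence residual over the last period is below 1e-3
  (relative) → limit cycle;
* otherwise aperiodic.

Detected cycles get an annotated *peak sequence*: sub-sample-refined
peak times of every participating neuron over one period (participation
threshold 0.01·θ; secondary peaks need prominence above 5% of the orbit
amplitude), synchronous peaks within 1% of the period grouped in
parentheses, participants whose peak stays below 0.58 of the maximum
marked low-firing, the word rotated to start at the lowest-numbered
high-firing neuron, and an exact k-fold repetition collapsed to its
primitive word (a period-doubled orbit peaks in the same cyclic order
twice).  The 0.58 high/low split and the other thresholds are
calibrated so the published sequences of the n = 5 census (123, 1234
with low 4, 1(25)34, 12(35)4, …) are reproduced; the model itself fixes
none of them.

Many census attractors are genuinely period-multiplied: the F-graph
attractor has period ≈ 19.9 with two structurally identical but
quantitatively different passes, and several five-vertex orbits quadruple.
One graph (`F2[1,4]`) has four coexisting aperiodic attractors, one per
core fixed point, stable over at least 8000 time units.

A classified cycle is accepted as an *attractor* only if it is
dynamically stable.  The fast test is the Floquet monodromy along the
orbit (piecewise-constant Jacobian `-I + diag(a) W`, a = active set);
because the linearization is unreliable for orbits with grazing
switching events, a claimed instability is confirmed empirically by
integrating a perturbed twin for 24 periods.  Stable-fixed-point records
are checked by the eigenvalue test.  This filter removes trajectories
that ride invariant synchrony subspaces (symmetric corners of the cube)
onto unstable fixed points or cycles.

## The census and the correspondence test

A core fixed point σ is *realized* by an observed attractor A when

1. some battery trajectory started as a small perturbation of σ's fixed
   point converges to A,
2. high(A) ⊆ σ ⊆ participating(A) — the high-firing neurons lie in the
   support, and any extra participants are low-firing (typically a node
   dynamically synchronized with a support neuron, as in the `D2[4]`
   attractor where nodes 3 and 5 fire identically although only 5 is in
   the support), and
3. A is not already booked to another core fixed point (the
   correspondence is injective, which is what makes
   attractors + ghosts = core fixed points an identity).

Injectivity matters exactly once: `S1[3]`'s (2,5) exchange symmetry
fixes a single synchronous attractor serving both of its cores, so the
partner core 1345 is an unrealized (ghost) prediction.  At the standard
parameters the census yields 185 realized predictions, 6 ghosts — on six
distinct no-source graphs — and no spurious attractors.  Re-running the
ghost graphs at δ = 5/4 realizes every ghost prediction (the symmetric
partner through the shared synchronous attractor) with no new spurious
attractors.

## Attractor classes

Realized attractors are grouped by single linkage under *class
identity*: same type, same high/low firing sets, and mean L2 distance
below 0.05 between the phase-resampled orbits (256 phase points,
minimized over cyclic shifts), evaluated across every taxonomy-name
alignment of the two graphs.  Sequences are reported as annotations but
are not a grouping key — they are derived from the orbits and overly
sensitive to period-multiplying fine structure.  Ghost predictions are
attached to classes by comparing their high-inhibition (rescue-regime)
attractors with those of class representatives re-run in the same
regime; ghost groups matching no realized class stand as ghost-only
classes.  At the standard parameters this produces 24 realized classes
plus one ghost-only class — 25 in total — including classes of 44, 30
and 29 attractors built on the 3-cycle-with-appendage motifs and the
5-member 4-cycle-plus-source class whose rate curves are identical to
within 0.02 mean L2.

Two caveats are recorded rather than engineered away.  First, a handful
of closely related small classes (the "15234"-type attractors built on
differently embedded 3-cycles) can be split or merged differently by any
uniform metric rule: with fully converged orbits we measure one
published-together pair at aligned distance 0.164 while
published-apart pairs sit at 0.030–0.156, so the composition of these
small classes is a convention, and ours is the metric one.  Second, the
synchronous class around `S1[3]`/`D2[4]` would split into isomorphic
cycle pairs at inhibition levels above the rescue regime, so rescue
comparisons are made only between orbits computed at matched parameters.

Master patterns summarizing a class's graph family are derived by
grouping member names over a shared (base, in-set) presentation,
requiring common out-edges, and widening the optional set as far as it
goes without pulling in non-member graphs.

## Synthetic inputs and scope

All inputs are enumerable graphs; there is no biological data anywhere
in the pipeline, and nothing here validates the model against recordings
— the package reproduces the mathematical census.  Problem sizes are the
ones the theory targets (n ≤ 5 exhaustively, machinery usable to n = 6);
the brute-force isomorphism and 2^n-support scans are exact by
construction at these sizes and are not meant to scale beyond n ≈ 7.

## Known limitations

* Quasiperiodic and chaotic orbits share one "aperiodic" label.
* The high/low-firing split is an amplitude threshold; the underlying
  notion in the literature is informal, and dynamically synchronized
  off-support nodes make any amplitude rule imperfect (handled instead
  by the support-sandwich criterion above).
* Floquet multipliers are unreliable near grazing orbits; the empirical
  persistence test is the authority there.
* Class composition for the near-degenerate small families is
  metric-convention-dependent (see above), although the class count and
  the large-class memberships are robust.
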