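"""Minimal supports, core fixed points, and core motifs.

A fixed point is *minimal* when its support contains no other support in
FP(G).  A *core* fixed point is one whose support sigma satisfies
FP(G|_sigma) = {sigma}: it is minimal both in the full network and in its
own subnetwork.  The induced subgraph of a core support is a *core motif*
— a graph whose only fixed-point support is the full vertex set.  Core
fixed points are the attractor predictions: each is expected to mark one
static or dynamic attractor of the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .digraph import Digraph, canonical_form, induced_subgraph
from .network import CTLNParams, FPSet, enumerate_FP

__all__ = [
    "minimal_supports",
    "is_core_motif",
    "core_fixed_points",
    "enumerate_core_motifs",
    "CoreReport",
    "core_report",
]


def minimal_supports(supports: Iterable[Iterable[int]] | FPSet) -> set[frozenset[int]]:
    """Supports containing no other member of the set (minimal under inclusion)."""
    if isinstance(supports, FPSet):
        supports = supports.supports
    sups = {frozenset(s) for s in supports}
    return {s for s in sups if not any(t < s for t in sups)}


def is_core_motif(
    G: Digraph,
    params: CTLNParams | None = None,
    grid: Sequence[CTLNParams] | None = None,
) -> bool:
    """Is FP(G) = {full vertex set}?

    Decided at ``params`` (standard parameters by default); passing a
    ``grid`` re-checks at every point and raises on any discrepancy.
    """
    full = frozenset(G.vertices)
    points = tuple(grid) if grid else (params or CTLNParams.standard(),)
    verdicts = {
        frozenset(enumerate_FP(G, p, with_values=False).supports) == {full}
        for p in points
    }
    if len(verdicts) > 1:
        raise ValueError(
            f"core-motif status of {G!r} differs across the parameter grid"
        )
    return verdicts.pop()


def core_fixed_points(
    G: Digraph, params: CTLNParams | None = None
) -> set[frozenset[int]]:
    """Supports sigma in FP(G) with FP(G|_sigma) = {sigma}."""
    params = params or CTLNParams.standard()
    fps = enumerate_FP(G, params, with_values=False)
    out = set()
    for sigma in fps.supports:
        H = induced_subgraph(G, sigma)
        if is_core_motif(H, params):
            out.add(frozenset(sigma))
    return out


def enumerate_core_motifs(
    n: int, oriented_only: bool = False, params: CTLNParams | None = None
) -> list[Digraph]:
    """All isomorphism classes of n-vertex core motifs.

    Scans every digraph on n vertices (every labeled graph for n <= 4;
    for n = 5 only the oriented ones are tractable by brute force, so
    ``oriented_only`` is required there).
    """
    if n > 5 or (n == 5 and not oriented_only):
        raise ValueError("brute-force core-motif enumeration: n <= 4, or n = 5 oriented")
    params = params or CTLNParams.standard()
    pair_states = (0, 1, 2) if oriented_only else (0, 1, 2, 3)
    pairs = list(itertools.combinations(range(1, n + 1), 2))
    seen: set[str] = set()
    motifs = []
    for states in itertools.product(pair_states, repeat=len(pairs)):
        edges = set()
        for (i, j), s in zip(pairs, states):
            if s in (1, 3):
                edges.add((i, j))
            if s in (2, 3):
                edges.add((j, i))
        G = Digraph(n, frozenset(edges))
        key = canonical_form(G)
        if key in seen:
            continue
        seen.add(key)
        if is_core_motif(G, params):
            motifs.append(G)
    return motifs


@dataclass(frozen=True)
class CoreReport:
    """Fixed-point structure of one graph: FP supports down to core motifs."""

    graph: Digraph
    params: CTLNParams
    fp_supports: tuple[frozenset[int], ...]
    minimal: frozenset[frozenset[int]]
    core: frozenset[frozenset[int]]
    core_motif_classes: dict[frozenset[int], str]  # core support -> canonical form

    def to_dict(self) -> dict:
        fmt = lambda s: "".join(map(str, sorted(s)))
        return {
            "n": self.graph.n,
            "edges": sorted(self.graph.edges),
            "fp_supports": [fmt(s) for s in sorted(self.fp_supports, key=lambda s: (len(s), sorted(s)))],
            "minimal_supports": sorted(fmt(s) for s in self.minimal),
            "core_supports": sorted(fmt(s) for s in self.core),
            "core_motif_classes": {fmt(s): c for s, c in self.core_motif_classes.items()},
        }


def core_report(G: Digraph, params: CTLNParams | None = None) -> CoreReport:
    """Full core analysis of one graph.

    Also asserts the equivalence between the two characterizations of a
    core fixed point (minimal in G and in G|_sigma  <=>  FP(G|_sigma) =
    {sigma} and sigma survives).
    """
    params = params or CTLNParams.standard()
    fps = enumerate_FP(G, params, with_values=False)
    mins = minimal_supports(fps)
    core = core_fixed_points(G, params)
    for sigma in core:
        H = induced_subgraph(G, sigma)
        sub_min = minimal_supports(enumerate_FP(H, params, with_values=False))
        assert sigma in mins and sub_min == {frozenset(range(1, len(sigma) + 1))}
    classes = {
        sigma: canonical_form(induced_subgraph(G, sigma)) for sigma in core
    }
    return CoreReport(G, params, tuple(fps.supports), frozenset(mins), frozenset(core), classes)
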