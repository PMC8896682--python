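"""Directed graphs, isomorphism, and the n = 5 oriented no-sink taxonomy.

Vertices are labeled 1..n throughout, matching the construction notation
used for the graph families (``D1[2,3]``, ``S[1,3][2,4]``, ...).  Graphs
are small (n <= 7), so isomorphism is decided by exhaustive permutation
with a lexicographically minimal adjacency canonical form.
"""

from __future__ import annotations

import csv
import io
import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Digraph",
    "GraphName",
    "MasterPattern",
    "VertexRole",
    "induced_subgraph",
    "vertex_roles",
    "uniform_in_degree",
    "canonical_form",
    "is_isomorphic",
    "isomorphisms",
    "automorphisms",
    "enumerate_oriented_nosink",
    "base_graph",
    "BASE_IDS",
    "build_from_name",
    "expand_master",
    "name_graph",
    "source_extensions",
    "three_cycle_double_source_graphs",
    "constructed_nosource_graphs",
]


@dataclass(frozen=True)
class Digraph:
    """A simple directed graph on vertices 1..n with no self-loops."""

    n: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("graph must have at least one vertex")
        if not isinstance(self.edges, frozenset):
            object.__setattr__(self, "edges", frozenset(self.edges))
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on vertex {i}")
            if not (1 <= i <= self.n and 1 <= j <= self.n):
                raise ValueError(f"edge ({i}, {j}) outside vertex range 1..{self.n}")

    # -- basic accessors -------------------------------------------------
    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(range(1, self.n + 1))

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self.edges

    def in_neighbors(self, v: int) -> frozenset[int]:
        return frozenset(i for i, j in self.edges if j == v)

    def out_neighbors(self, v: int) -> frozenset[int]:
        return frozenset(j for i, j in self.edges if i == v)

    def in_degree(self, v: int) -> int:
        return len(self.in_neighbors(v))

    def out_degree(self, v: int) -> int:
        return len(self.out_neighbors(v))

    def is_oriented(self) -> bool:
        """True when the graph has no bidirectional pair i <-> j."""
        return not any((j, i) in self.edges for i, j in self.edges)

    def sources(self) -> frozenset[int]:
        return frozenset(v for v in self.vertices if self.in_degree(v) == 0)

    def proper_sources(self) -> frozenset[int]:
        return frozenset(v for v in self.sources() if self.out_degree(v) > 0)

    def sinks(self) -> frozenset[int]:
        return frozenset(v for v in self.vertices if self.out_degree(v) == 0)

    def relabel(self, perm: dict[int, int], n: int | None = None) -> "Digraph":
        """Relabel vertices: vertex v becomes perm[v]."""
        return Digraph(n or self.n, frozenset((perm[i], perm[j]) for i, j in self.edges))

    def add_vertex_with_edges(
        self, in_set: Iterable[int], out_set: Iterable[int]
    ) -> "Digraph":
        """Return a graph with one extra vertex (label n+1) wired as given."""
        v = self.n + 1
        extra = {(u, v) for u in in_set} | {(v, u) for u in out_set}
        return Digraph(v, self.edges | extra)

    # -- matrix / text I/O ----------------------------------------------
    def adjacency_matrix(self) -> list[list[int]]:
        """0/1 matrix, row = source vertex, column = target vertex."""
        A = [[0] * self.n for _ in range(self.n)]
        for i, j in self.edges:
            A[i - 1][j - 1] = 1
        return A

    @classmethod
    def from_adjacency(cls, A: Sequence[Sequence[int]]) -> "Digraph":
        n = len(A)
        edges = {
            (i + 1, j + 1) for i in range(n) for j in range(n) if int(A[i][j])
        }
        return cls(n, frozenset(edges))

    def to_text(self) -> str:
        lines = [f"n {self.n}"]
        lines += [f"{i} {j}" for i, j in sorted(self.edges)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Digraph":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("n "):
            raise ValueError('graph text must start with a header line "n <count>"')
        n = int(lines[0].split()[1])
        edges = set()
        for ln in lines[1:]:
            i, j = map(int, ln.split())
            edges.add((i, j))
        return cls(n, frozenset(edges))

    @classmethod
    def from_adjacency_csv(cls, text: str) -> "Digraph":
        rows = [r for r in csv.reader(io.StringIO(text)) if r]
        return cls.from_adjacency([[int(float(x)) for x in r] for r in rows])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        es = ",".join(f"{i}{j}" if self.n < 10 else f"{i}->{j}" for i, j in sorted(self.edges))
        return f"Digraph(n={self.n}, edges={{{es}}})"


# ---------------------------------------------------------------------------
# Subgraphs and vertex predicates
# ---------------------------------------------------------------------------

def induced_subgraph(
    G: Digraph, sigma: Iterable[int], return_mapping: bool = False
):
    """Induced subgraph on sigma, relabeled to 1..|sigma| preserving order.

    Returns the subgraph, or ``(subgraph, mapping)`` where mapping sends the
    old labels to the new ones.
    """
    sig = sorted(set(sigma))
    if not sig:
        raise ValueError("induced subgraph on an empty vertex set")
    if not set(sig) <= set(G.vertices):
        raise ValueError(f"sigma {sig} is not a subset of the vertices of G")
    mapping = {v: k + 1 for k, v in enumerate(sig)}
    edges = frozenset(
        (mapping[i], mapping[j]) for i, j in G.edges if i in mapping and j in mapping
    )
    H = Digraph(len(sig), edges)
    return (H, mapping) if return_mapping else H


@dataclass(frozen=True)
class VertexRole:
    in_degree: int
    out_degree: int
    is_source: bool
    is_proper_source: bool
    is_sink: bool


def vertex_roles(G: Digraph) -> dict[int, VertexRole]:
    """Per-vertex source/sink classification.

    A source has no incoming edges; a *proper* source additionally has at
    least one outgoing edge; a sink has no outgoing edges.
    """
    roles = {}
    for v in G.vertices:
        indeg, outdeg = G.in_degree(v), G.out_degree(v)
        roles[v] = VertexRole(
            in_degree=indeg,
            out_degree=outdeg,
            is_source=indeg == 0,
            is_proper_source=indeg == 0 and outdeg > 0,
            is_sink=outdeg == 0,
        )
    return roles


def uniform_in_degree(G: Digraph) -> int | None:
    """The common in-degree d when all vertices share it, else None."""
    degs = {G.in_degree(v) for v in G.vertices}
    return degs.pop() if len(degs) == 1 else None


# ---------------------------------------------------------------------------
# Isomorphism by exhaustive permutation (fine for n <= 7)
# ---------------------------------------------------------------------------

def _bits(G: Digraph) -> int:
    """Flattened adjacency as an n*n bit integer (row-major)."""
    b = 0
    for i, j in G.edges:
        b |= 1 << ((i - 1) * G.n + (j - 1))
    return b


@lru_cache(maxsize=8)
def _perm_tables(n: int) -> list[list[int]]:
    """For every permutation of 0..n-1, the source bit position feeding each
    target bit position of the permuted adjacency integer."""
    tables = []
    for p in itertools.permutations(range(n)):
        # new adjacency bit (a, b) comes from old bit (p[a], p[b])
        tables.append([p[a] * n + p[b] for a in range(n) for b in range(n)])
    return tables


def _permuted_bits(bits: int, table: list[int]) -> int:
    out = 0
    for dst, src in enumerate(table):
        if bits >> src & 1:
            out |= 1 << dst
    return out


def canonical_form(G: Digraph) -> str:
    """Canonical label: minimal flattened adjacency over all relabelings.

    Two graphs have equal canonical forms iff they are isomorphic.
    """
    bits = _bits(G)
    best = min(_permuted_bits(bits, t) for t in _perm_tables(G.n))
    return f"{G.n}:{best:x}"


def is_isomorphic(G1: Digraph, G2: Digraph) -> bool:
    if G1.n != G2.n or len(G1.edges) != len(G2.edges):
        return False
    return canonical_form(G1) == canonical_form(G2)


def isomorphisms(G1: Digraph, G2: Digraph) -> Iterator[dict[int, int]]:
    """All vertex bijections phi with phi(G1) = G2 (brute force)."""
    if G1.n != G2.n or len(G1.edges) != len(G2.edges):
        return
    for p in itertools.permutations(G2.vertices):
        phi = dict(zip(G1.vertices, p))
        if all((phi[i], phi[j]) in G2.edges for i, j in G1.edges):
            yield phi


def automorphisms(G: Digraph) -> list[dict[int, int]]:
    return list(isomorphisms(G, G))


# ---------------------------------------------------------------------------
# Enumeration of oriented graphs with no sinks
# ---------------------------------------------------------------------------

def _oriented_assignments(n: int) -> Iterator[frozenset[tuple[int, int]]]:
    """All labeled oriented graphs: each unordered pair is absent, ->, or <-."""
    pairs = list(itertools.combinations(range(1, n + 1), 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (i, j), s in zip(pairs, states):
            if s == 1:
                edges.add((i, j))
            elif s == 2:
                edges.add((j, i))
        yield frozenset(edges)


def _dedupe(graphs: Iterable[Digraph]) -> list[Digraph]:
    """One representative per isomorphism class, in encounter order."""
    seen: set[str] = set()
    reps = []
    for G in graphs:
        key = canonical_form(G)
        if key not in seen:
            seen.add(key)
            reps.append(G)
    return reps


def enumerate_oriented_nosink(n: int) -> list[Digraph]:
    """All oriented graphs with no sinks on n vertices, one per iso class.

    Generates every labeled oriented graph (each unordered pair in one of
    three states) and buckets by canonical form.  There is 1 class at n = 3
    (the 3-cycle), 7 at n = 4, and 152 at n = 5.
    """
    if not 1 <= n <= 6:
        raise ValueError("practical bound: 1 <= n <= 6")
    # Fast labeled-level dedup: membership of the raw adjacency integer in
    # the union of permuted variants of classes already seen.
    tables = _perm_tables(n)
    seen_raw: set[int] = set()
    reps: list[Digraph] = []
    for edges in _oriented_assignments(n):
        G = Digraph(n, edges)
        if G.sinks():
            continue
        raw = _bits(G)
        if raw in seen_raw:
            continue
        variants = {_permuted_bits(raw, t) for t in tables}
        seen_raw |= variants
        reps.append(G)
    return reps


# ---------------------------------------------------------------------------
# Base graphs and the construction notation
# ---------------------------------------------------------------------------

BASE_IDS = ("3cyc", "D", "E", "F", "T", "S", "5cyc")

_BASE_EDGES = {
    "3cyc": {(1, 2), (2, 3), (3, 1)},
    # D and E: the two n=4 oriented no-sink extensions of the 3-cycle by a
    # non-source node that are not F.  The labelings are pinned jointly by
    # the isomorphisms D1[2,3] = E2[3] and D3[1,2] = E3[1] and by the D/E
    # attractor sequence 1234 (node 4, fed by node 3, peaks last).
    "D": {(1, 2), (2, 3), (3, 1), (3, 4), (4, 1)},
    "E": {(1, 2), (2, 3), (3, 1), (3, 4), (4, 1), (4, 2)},
    "F": {(1, 2), (2, 3), (3, 1), (3, 4), (4, 2)},
    "T": {(1, 2), (2, 3), (3, 1), (3, 4)},
    "S": {(1, 2), (2, 3), (3, 4), (4, 1)},
    "5cyc": {(1, 2), (2, 3), (3, 4), (4, 5), (5, 1)},
}

_BASE_N = {"3cyc": 3, "D": 4, "E": 4, "F": 4, "T": 4, "S": 4, "5cyc": 5}


def base_graph(base_id: str, swap_de: bool = False) -> Digraph:
    """One of the fixed base graphs: 3cyc, D, E, F, T, S, 5cyc.

    ``swap_de`` exchanges the D and E letters (a pure renaming; the census
    totals are unaffected).
    """
    if base_id not in _BASE_EDGES:
        raise KeyError(f"unknown base graph {base_id!r}; expected one of {BASE_IDS}")
    bid = base_id
    if swap_de and base_id in ("D", "E"):
        bid = "E" if base_id == "D" else "D"
    return Digraph(_BASE_N[base_id], frozenset(_BASE_EDGES[bid]))


@dataclass(frozen=True)
class GraphName:
    """Construction label: base graph + node wired by in_set / out_set.

    ``D1[2,3]`` is the D graph plus node 5 with edges 1->5, 5->2 and 5->3.
    An empty in_set (printed "0") makes the added node a source.
    """

    base: str
    in_set: frozenset[int]
    out_set: frozenset[int]

    def __post_init__(self) -> None:
        if self.base not in _BASE_EDGES:
            raise ValueError(f"unknown base {self.base!r}")
        object.__setattr__(self, "in_set", frozenset(self.in_set))
        object.__setattr__(self, "out_set", frozenset(self.out_set))
        if not self.out_set:
            raise ValueError("out_set must be non-empty (the added node may not be a sink)")
        if self.in_set & self.out_set:
            raise ValueError("in_set and out_set overlap (graph would not be oriented)")
        nb = _BASE_N[self.base]
        if not (self.in_set | self.out_set) <= set(range(1, nb + 1)):
            raise ValueError("in/out sets must be vertices of the base graph")

    def __str__(self) -> str:
        ins = sorted(self.in_set)
        if not ins:
            head = "0"
        elif len(ins) == 1:
            head = str(ins[0])
        else:
            head = "[" + ",".join(map(str, ins)) + "]"
        return f"{self.base}{head}[" + ",".join(map(str, sorted(self.out_set))) + "]"

    _NAME_RE = re.compile(
        r"^(?P<base>3cyc|5cyc|[DEFTS])"
        r"(?:(?P<in0>0)|(?P<in1>\d)|\[(?P<inm>[\d,\s]+)\])"
        r"\[(?P<out>[\d,\s]+)\]$"
    )

    @classmethod
    def parse(cls, text: str) -> "GraphName":
        m = cls._NAME_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse graph name {text!r}")
        if m.group("in0"):
            in_set: frozenset[int] = frozenset()
        elif m.group("in1"):
            in_set = frozenset({int(m.group("in1"))})
        else:
            in_set = frozenset(int(x) for x in m.group("inm").split(","))
        out_set = frozenset(int(x) for x in m.group("out").split(","))
        return cls(m.group("base"), in_set, out_set)


def build_from_name(name: GraphName | str, swap_de: bool = False) -> Digraph:
    """Construct the graph a name denotes: base plus node n_base+1."""
    if isinstance(name, str):
        name = GraphName.parse(name)
    base = base_graph(name.base, swap_de=swap_de)
    return base.add_vertex_with_edges(name.in_set, name.out_set)


@dataclass(frozen=True)
class MasterPattern:
    """A family of names: required, forbidden (~) and optional (*) out-edges.

    ``D2[~3,4,*]`` denotes every D2[...] name whose out_set contains 4,
    avoids 3, and is otherwise free: the pair D2[1,4] and D2[4].
    """

    base: str
    in_set: frozenset[int]
    required: frozenset[int]
    forbidden: frozenset[int]
    wildcard: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_set", frozenset(self.in_set))
        object.__setattr__(self, "required", frozenset(self.required))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        if self.required & self.forbidden:
            raise ValueError(
                f"vertices {sorted(self.required & self.forbidden)} both required and forbidden"
            )

    def __str__(self) -> str:
        ins = sorted(self.in_set)
        head = "0" if not ins else (
            str(ins[0]) if len(ins) == 1 else "[" + ",".join(map(str, ins)) + "]"
        )
        items = [f"~{v}" for v in sorted(self.forbidden)]
        items += [str(v) for v in sorted(self.required)]
        if self.wildcard:
            items.append("*")
        return f"{self.base}{head}[" + ",".join(items) + "]"

    _PAT_RE = re.compile(
        r"^(?P<base>3cyc|5cyc|[DEFTS])"
        r"(?:(?P<in0>0)|(?P<in1>\d)|\[(?P<inm>[\d,\s]+)\])"
        r"\[(?P<spec>[^\]]*)\]$"
    )

    @classmethod
    def parse(cls, text: str) -> "MasterPattern":
        text = text.replace("∼", "~")  # accept the typeset tilde
        m = cls._PAT_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse master pattern {text!r}")
        if m.group("in0"):
            in_set: frozenset[int] = frozenset()
        elif m.group("in1"):
            in_set = frozenset({int(m.group("in1"))})
        else:
            in_set = frozenset(int(x) for x in m.group("inm").split(","))
        required, forbidden, wildcard = set(), set(), False
        for item in (s.strip() for s in m.group("spec").split(",") if s.strip()):
            if item == "*":
                wildcard = True
            elif item.startswith("~"):
                forbidden.add(int(item[1:]))
            else:
                required.add(int(item))
        return cls(m.group("base"), in_set, frozenset(required), frozenset(forbidden), wildcard)


def expand_master(
    pattern: MasterPattern | str, dedupe_isomorphic: bool = False, swap_de: bool = False
) -> list[GraphName]:
    """All names matching a master pattern (optionally one per iso class)."""
    if isinstance(pattern, str):
        pattern = MasterPattern.parse(pattern)
    nb = _BASE_N[pattern.base]
    free = sorted(
        set(range(1, nb + 1)) - pattern.required - pattern.forbidden - pattern.in_set
    )
    if not pattern.wildcard:
        free = []
    names = []
    for r in range(len(free) + 1):
        for extra in itertools.combinations(free, r):
            out = pattern.required | set(extra)
            if not out:
                continue
            names.append(GraphName(pattern.base, pattern.in_set, frozenset(out)))
    if dedupe_isomorphic:
        seen: set[str] = set()
        uniq = []
        for nm in names:
            key = canonical_form(build_from_name(nm, swap_de=swap_de))
            if key not in seen:
                seen.add(key)
                uniq.append(nm)
        names = uniq
    return names


def name_graph(G: Digraph, swap_de: bool = False) -> list[GraphName]:
    """All base-construction names of a 5-vertex oriented no-source/no-sink
    graph: remove each vertex in turn and match the remainder to a base.

    The 5-cycle (and anything outside the family) yields an error.
    """
    if G.n != 5:
        raise ValueError("naming is defined for 5-vertex graphs")
    if not G.is_oriented() or G.sources() or G.sinks():
        raise ValueError("naming requires an oriented graph with no sources and no sinks")
    names = set()
    for v in G.vertices:
        rest = [u for u in G.vertices if u != v]
        H, mapping = induced_subgraph(G, rest, return_mapping=True)
        for base_id in ("D", "E", "F", "T", "S"):
            B = base_graph(base_id, swap_de=swap_de)
            for phi in isomorphisms(H, B):
                lift = {u: phi[mapping[u]] for u in rest}
                in_set = frozenset(lift[u] for u in G.in_neighbors(v))
                out_set = frozenset(lift[u] for u in G.out_neighbors(v))
                names.add(GraphName(base_id, in_set, out_set))
    if not names:
        raise ValueError(
            "no base decomposition found (the 5-cycle, or a graph outside the family)"
        )
    return sorted(names, key=str)


# ---------------------------------------------------------------------------
# The graph families of the n = 5 taxonomy
# ---------------------------------------------------------------------------

def source_extensions(base: Digraph) -> list[Digraph]:
    """Add one proper source (highest label) in every way, up to isomorphism."""
    out_choices = itertools.chain.from_iterable(
        itertools.combinations(base.vertices, r) for r in range(1, base.n + 1)
    )
    return _dedupe(base.add_vertex_with_edges((), out) for out in out_choices)


def three_cycle_double_source_graphs() -> list[Digraph]:
    """3-cycle plus nodes 4 and 5 added (in that order) as proper sources,
    up to isomorphism.  Node 5 may feed node 4.  There are 30 classes."""
    c3 = base_graph("3cyc")
    graphs = []
    for out4 in _nonempty_subsets((1, 2, 3)):
        G4 = c3.add_vertex_with_edges((), out4)
        for out5 in _nonempty_subsets((1, 2, 3, 4)):
            graphs.append(G4.add_vertex_with_edges((), out5))
    return _dedupe(graphs)


def _nonempty_subsets(items: Sequence[int]) -> Iterator[tuple[int, ...]]:
    for r in range(1, len(items) + 1):
        yield from itertools.combinations(items, r)


def constructed_nosource_graphs(swap_de: bool = False) -> list[tuple[GraphName, Digraph]]:
    """Every graph constructible as base + node 5 with >= 1 in- and out-edge
    that ends up with no sources and no sinks, one (name, graph) pair per
    isomorphism class.  There are 75; adding the 5-cycle completes the 76
    no-source oriented no-sink graphs."""
    pairs: list[tuple[GraphName, Digraph]] = []
    seen: set[str] = set()
    for base_id in ("D", "E", "F", "T", "S"):
        nb = _BASE_N[base_id]
        verts = tuple(range(1, nb + 1))
        for in_set in _nonempty_subsets(verts):
            for out_set in _nonempty_subsets(tuple(v for v in verts if v not in in_set)):
                nm = GraphName(base_id, frozenset(in_set), frozenset(out_set))
                G = build_from_name(nm, swap_de=swap_de)
                if G.sources() or G.sinks():
                    continue
                key = canonical_form(G)
                if key not in seen:
                    seen.add(key)
                    pairs.append((nm, G))
    return pairs
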