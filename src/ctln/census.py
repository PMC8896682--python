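"""The exhaustive n = 5 census: attractor prediction tested on every
oriented graph with no sinks.

For each of the 152 isomorphism classes the census enumerates FP(G) and
the core fixed points exactly, runs a fixed battery of initial conditions
(perturbations of every fixed point plus the 32 corners of the unit
cube), classifies the resulting attractors, and matches them to core
fixed points.  A core fixed point is *realized* when a perturbation of
that fixed point converges to an attractor whose high-firing neurons lie
in the support and whose participating neurons cover it; an unrealized
prediction is a *ghost*; an observed attractor matching no core fixed
point is *spurious*.

Graphs are kept in taxonomy coordinates (base graph on vertices 1..4,
added node 5), which aligns similarly embedded core motifs across graphs
and lets realized attractors be clustered into classes by orbit identity.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .digraph import (
    Digraph,
    GraphName,
    MasterPattern,
    base_graph,
    build_from_name,
    canonical_form,
    constructed_nosource_graphs,
    isomorphisms,
    source_extensions,
    three_cycle_double_source_graphs,
    _nonempty_subsets,
)
from .network import CTLNParams, enumerate_FP, stability
from .core import core_fixed_points
from .dynamics import (
    AttractorRecord,
    ClassifyOptions,
    Trajectory,
    battery,
    build_W,
    classify_trajectory,
    is_orbit_stable,
    orbit_persists,
    same_attractor,
    simulate_batch,
)

__all__ = [
    "CensusOptions",
    "CensusGraph",
    "census_graphs",
    "CorrespondenceResult",
    "test_correspondence",
    "CensusReport",
    "run_census",
    "AttractorClass",
    "classify_census",
    "records_same_class",
    "assign_ghosts_to_classes",
    "master_pattern_for_class",
]


@dataclass(frozen=True)
class CensusOptions:
    """Battery and horizon settings for the census."""

    T: float = 500.0             # first-pass horizon, time units
    extensions: tuple[float, ...] = (1500.0, 5000.0)  # horizons for unresolved runs
    dt: float = 0.01
    eta: float = 0.05            # perturbation magnitude
    n_random: int = 10           # random perturbations per fixed point
    seed: int = 0                # master seed for the random perturbations
    classify: ClassifyOptions = ClassifyOptions()

    def record_window(self) -> float:
        return self.classify.window + 10.0


def _graph_seed(master: int, canon: str) -> int:
    h = int(hashlib.md5(canon.encode()).hexdigest()[:8], 16)
    return (master + h) % (2**31)


# ---------------------------------------------------------------------------
# The catalog of census graphs in taxonomy coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusGraph:
    """One isomorphism class, held in taxonomy coordinates.

    ``alignments`` are all vertex permutations mapping this representative
    onto *any* constructed presentation of its class; applying one to an
    attractor puts it in the coordinates the published taxonomy uses, so
    attractors of different graphs can be compared directly.
    """

    label: str
    group: str  # "source" | "no-source"
    graph: Digraph
    names: tuple[str, ...]
    alignments: tuple[tuple[int, ...], ...]  # perm[i-1] = image of vertex i

    def alignment_maps(self) -> list[dict[int, int]]:
        return [
            {i + 1: perm[i] for i in range(len(perm))} for perm in self.alignments
        ]


def _presentation_catalog(swap_de: bool) -> dict[str, list[tuple[str, Digraph]]]:
    """Every constructed-form presentation, keyed by canonical form."""
    catalog: dict[str, list[tuple[str, Digraph]]] = {}

    def add(label: str, G: Digraph) -> None:
        catalog.setdefault(canonical_form(G), []).append((label, G))

    # no-source constructions: all valid names over the five bases
    for base_id in ("D", "E", "F", "T", "S"):
        nb = base_graph(base_id, swap_de=swap_de).n
        verts = tuple(range(1, nb + 1))
        for in_set in _nonempty_subsets(verts):
            for out_set in _nonempty_subsets(tuple(v for v in verts if v not in in_set)):
                nm = GraphName(base_id, frozenset(in_set), frozenset(out_set))
                G = build_from_name(nm, swap_de=swap_de)
                if not G.sources() and not G.sinks():
                    add(str(nm), G)
    add("5cyc", base_graph("5cyc"))
    # single added source on a 4-vertex base
    for base_id in ("D", "E", "F", "S"):
        B = base_graph(base_id, swap_de=swap_de)
        for out in _nonempty_subsets(B.vertices):
            nm = GraphName(base_id, frozenset(), frozenset(out))
            add(str(nm), build_from_name(nm, swap_de=swap_de))
    # two added sources on the 3-cycle
    c3 = base_graph("3cyc")
    for out4 in _nonempty_subsets((1, 2, 3)):
        G4 = c3.add_vertex_with_edges((), out4)
        for out5 in _nonempty_subsets((1, 2, 3, 4)):
            lbl = "3cyc[%s][%s]" % (
                ",".join(map(str, out4)),
                ",".join(map(str, out5)),
            )
            add(lbl, G4.add_vertex_with_edges((), out5))
    return catalog


def census_graphs(swap_de: bool = False) -> list[CensusGraph]:
    """The 152 census graphs (taxonomy representatives with alignments)."""
    catalog = _presentation_catalog(swap_de)
    reps: list[tuple[str, str, Digraph]] = []
    for nm, G in constructed_nosource_graphs(swap_de=swap_de):
        reps.append((str(nm), "no-source", G))
    reps.append(("5cyc", "no-source", base_graph("5cyc")))
    for G in three_cycle_double_source_graphs():
        reps.append((catalog[canonical_form(G)][0][0], "source", G))
    for base_id in ("D", "E", "F", "S"):
        for G in source_extensions(base_graph(base_id, swap_de=swap_de)):
            lbl = next(
                l for l, _ in catalog[canonical_form(G)] if l.startswith(base_id + "0")
            )
            reps.append((lbl, "source", G))

    out = []
    seen: set[str] = set()
    for label, group, G in reps:
        canon = canonical_form(G)
        if canon in seen:
            continue
        seen.add(canon)
        pres = catalog[canon]
        perms: set[tuple[int, ...]] = set()
        for _, P in pres:
            for phi in isomorphisms(G, P):
                perms.add(tuple(phi[i] for i in G.vertices))
        out.append(
            CensusGraph(
                label,
                group,
                G,
                tuple(sorted({l for l, _ in pres})),
                tuple(sorted(perms)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-graph correspondence test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservedAttractor:
    record: AttractorRecord
    origins: tuple[str, ...]  # initial-condition labels that reached it


@dataclass(frozen=True)
class CorrespondenceResult:
    """Core fixed points vs observed attractors for one graph."""

    label: str
    group: str
    core_supports: frozenset[frozenset[int]]
    realized: dict  # support -> AttractorRecord
    ghosts: frozenset[frozenset[int]]
    spurious: tuple[ObservedAttractor, ...]
    attractors: tuple[ObservedAttractor, ...]
    flagged: tuple[str, ...] = ()  # unresolved initial conditions

    @property
    def n_core(self) -> int:
        return len(self.core_supports)

    @property
    def n_realized(self) -> int:
        return len(self.realized)


def _classify_battery(
    W: np.ndarray,
    theta: float,
    ics: Sequence[tuple[str, np.ndarray]],
    opts: CensusOptions,
) -> list[AttractorRecord]:
    """Classify every initial condition, extending unresolved horizons."""
    labels = [lbl for lbl, _ in ics]
    X0 = np.stack([x for _, x in ics])
    horizons = (opts.T,) + opts.extensions
    records: dict[int, AttractorRecord] = {}
    todo = list(range(len(ics)))
    for h_idx, T in enumerate(horizons):
        if not todo:
            break
        rec_from = T - opts.record_window()
        t, X = simulate_batch(W, theta, X0[todo], T, opts.dt, record_from=rec_from)
        still = []
        for row, idx in enumerate(todo):
            traj = Trajectory(t, X[:, row, :], theta)
            rec = classify_trajectory(traj, opts.classify, origin=labels[idx])
            if rec.kind == "aperiodic" and h_idx + 1 < len(horizons):
                still.append(idx)  # may be a long transient; extend
            else:
                records[idx] = rec
        todo = still
    return [records[i] for i in sorted(records)]


def _dedupe_records(
    records: Iterable[AttractorRecord], copts: ClassifyOptions
) -> list[ObservedAttractor]:
    out: list[tuple[AttractorRecord, list[str]]] = []
    for rec in records:
        for known, origins in out:
            if same_attractor(rec, known, opts=copts):
                origins.append(rec.origin)
                break
        else:
            out.append((rec, [rec.origin]))
    return [ObservedAttractor(rec, tuple(org)) for rec, org in out]


def test_correspondence(
    G: Digraph,
    params: CTLNParams | None = None,
    opts: CensusOptions = CensusOptions(),
    label: str = "",
    group: str = "",
    allow_illegal: bool = False,
) -> CorrespondenceResult:
    """Run the battery on one graph and match attractors to core fixed points."""
    params = params or CTLNParams.standard()
    fps = enumerate_FP(G, params, allow_illegal=allow_illegal)
    cores = frozenset(core_fixed_points(G, params))
    seed = _graph_seed(opts.seed, canonical_form(G))
    ics = battery(G, fps, eta=opts.eta, n_random=opts.n_random, seed=seed)
    W = build_W(G, params, allow_illegal=allow_illegal)
    theta = float(params.theta)
    records = _classify_battery(W, theta, ics, opts)
    flagged = tuple(r.origin for r in records if r.kind == "aperiodic")

    # Drop groups that settled on an *unstable* invariant set: a symmetric
    # corner (or a perturbation inside a synchrony plane) can ride an
    # invariant subspace into a fixed point or cycle that is not an
    # attractor of the full system.
    def is_true_attractor(rec: AttractorRecord) -> bool:
        if rec.kind == "stable_fp":
            return stability(G, rec.high_set, params, allow_illegal=allow_illegal) == "stable"
        if rec.kind == "limit_cycle":
            # Floquet fast path; a claimed instability is confirmed by the
            # empirical persistence test (grazing orbits can fool the
            # linearization)
            return is_orbit_stable(W, theta, rec) or orbit_persists(
                W, theta, rec, dt=opts.dt, seed=seed
            )
        return True

    observed = tuple(
        obs for obs in _dedupe_records(records, opts.classify)
        if is_true_attractor(obs.record)
    )

    def corresponds(rec: AttractorRecord, sigma: frozenset[int]) -> bool:
        # the high-firing neurons must lie in the support, and the support
        # must not extend beyond the participating neurons; participants
        # outside the support are low-firing (e.g. a node dynamically
        # synchronized with a support neuron)
        return rec.high_set <= sigma <= rec.participating

    # The correspondence is injective: one observed attractor realizes one
    # core fixed point.  A symmetry can fix a single attractor serving two
    # symmetric cores (e.g. a synchrony that merges the pair of isomorphic
    # orbits); the partner core is then an unrealized (ghost) prediction.
    realized: dict[frozenset[int], AttractorRecord] = {}
    used: set[int] = set()
    for sigma in sorted(cores, key=lambda s: (len(s), sorted(s))):
        tag = "".join(map(str, sorted(sigma)))
        for k, obs in enumerate(observed):
            if k in used:
                continue
            from_own_fp = any(o.startswith(f"fp:{tag}:") for o in obs.origins)
            static = obs.record.kind == "stable_fp"
            if corresponds(obs.record, sigma) and (from_own_fp or static):
                realized[sigma] = obs.record
                used.add(k)
                break
    spurious = tuple(
        obs for obs in observed
        if not any(corresponds(obs.record, s) for s in cores)
    )
    ghosts = frozenset(s for s in cores if s not in realized)
    return CorrespondenceResult(
        label, group, cores, realized, ghosts, tuple(spurious), tuple(observed), flagged
    )


# ---------------------------------------------------------------------------
# The full census
# ---------------------------------------------------------------------------

@dataclass
class CensusReport:
    params: CTLNParams
    options: CensusOptions
    graphs: list[CensusGraph]
    results: dict  # label -> CorrespondenceResult

    def totals(self, group: str | None = None) -> dict[str, int]:
        rs = [
            r for g, r in ((g, self.results[g.label]) for g in self.graphs)
            if group is None or g.group == group
        ]
        return {
            "graphs": len(rs),
            "core_fps": sum(r.n_core for r in rs),
            "attractors": sum(r.n_realized for r in rs),
            "ghosts": sum(len(r.ghosts) for r in rs),
            "spurious": sum(len(r.spurious) for r in rs),
        }

    def ghost_entries(self) -> list[tuple[str, frozenset[int]]]:
        return [
            (g.label, s)
            for g in self.graphs
            for s in sorted(self.results[g.label].ghosts, key=sorted)
        ]

    def table2(self) -> dict:
        return {
            "with_source": self.totals("source"),
            "no_source": self.totals("no-source"),
            "total": self.totals(),
        }

    def to_dict(self, include_orbits: bool = False) -> dict:
        fmt = lambda s: "".join(map(str, sorted(s)))
        out = {
            "params": {
                "eps": str(self.params.eps),
                "delta": str(self.params.delta),
                "theta": str(self.params.theta),
            },
            "table2": self.table2(),
            "graphs": {},
        }
        for g in self.graphs:
            r = self.results[g.label]
            entry = {
                "group": g.group,
                "names": list(g.names),
                "core_fixed_points": sorted(fmt(s) for s in r.core_supports),
                "realized": {
                    fmt(s): (rec.to_dict() if include_orbits else {
                        "kind": rec.kind,
                        "sequence": rec.sequence_str,
                        "high_set": sorted(rec.high_set),
                        "low_set": sorted(rec.low_set),
                        "period": rec.period,
                    })
                    for s, rec in r.realized.items()
                },
                "ghosts": sorted(fmt(s) for s in r.ghosts),
                "spurious": [o.record.sequence_str for o in r.spurious],
                "flagged": list(r.flagged),
            }
            out["graphs"][g.label] = entry
        return out


def run_census(
    params: CTLNParams | None = None,
    opts: CensusOptions = CensusOptions(),
    graphs: Sequence[CensusGraph] | None = None,
    swap_de: bool = False,
    progress: bool = False,
) -> CensusReport:
    """Correspondence test on all 152 graphs (or a supplied subset)."""
    params = params or CTLNParams.standard()
    graphs = list(graphs if graphs is not None else census_graphs(swap_de=swap_de))
    results = {}
    for k, g in enumerate(graphs):
        results[g.label] = test_correspondence(
            g.graph, params, opts, label=g.label, group=g.group
        )
        if progress and (k + 1) % 20 == 0:
            print(f"  census: {k + 1}/{len(graphs)} graphs", flush=True)
    return CensusReport(params, opts, graphs, results)


# ---------------------------------------------------------------------------
# Attractor classes
# ---------------------------------------------------------------------------

@dataclass
class AttractorClass:
    """A group of realized attractors that are the same up to alignment."""

    class_id: str
    sequence: str
    members: list  # (graph label, core support, AttractorRecord)
    representative: AttractorRecord
    ghost_members: list = field(default_factory=list)  # (graph label, support)

    @property
    def n_attractors(self) -> int:
        return len(self.members)

    @property
    def n_graphs(self) -> int:
        return len({lbl for lbl, _, _ in self.members})


def _aligned_variants(
    rec: AttractorRecord, g: CensusGraph
) -> list[AttractorRecord]:
    return [rec.relabel(perm) for perm in g.alignment_maps()]


def records_same_class(
    a: AttractorRecord, b: AttractorRecord, copts: ClassifyOptions
) -> bool:
    """Class identity for two aligned attractors: same type, same high/low
    firing sets, and phase-aligned orbits within ``tol_match`` mean L2
    distance.

    Unlike :func:`ctln.dynamics.same_attractor` this does not compare the
    annotated sequences: the sequence is derived from the orbit and is
    overly sensitive to period-multiplying fine structure, while class
    identity is a statement about the rate curves themselves.
    """
    if a.kind != b.kind or a.high_set != b.high_set or a.low_set != b.low_set:
        return False
    if a.kind in ("limit_cycle", "stable_fp"):
        from .dynamics import orbit_distance

        return orbit_distance(a.orbit, b.orbit) < copts.tol_match
    return True  # aperiodic: combinatorial identity only


def _variants_match(
    va: Sequence[AttractorRecord], vb: Sequence[AttractorRecord], copts: ClassifyOptions
) -> bool:
    return any(records_same_class(a, b, copts) for a in va for b in vb)


def classify_census(
    report: CensusReport, copts: ClassifyOptions | None = None
) -> list[AttractorClass]:
    """Single-linkage grouping of all realized attractors under alignment.

    Attractors are compared after relabeling onto every constructed
    presentation of their graph, which implements the taxonomy-based
    vertex alignment.
    """
    copts = copts or report.options.classify
    by_label = {g.label: g for g in report.graphs}
    items = []  # (label, support, record, aligned variants)
    for g in report.graphs:
        r = report.results[g.label]
        for s, rec in sorted(r.realized.items(), key=lambda kv: sorted(kv[0])):
            items.append((g.label, s, rec, _aligned_variants(rec, by_label[g.label])))

    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    # coarse key prunes the quadratic comparison
    def key(it) -> tuple:
        rec = it[2]
        return (rec.kind, len(rec.high_set), len(rec.low_set))

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if key(items[i]) != key(items[j]):
                continue
            if find(i) == find(j):
                continue
            if _variants_match(items[i][3], items[j][3], copts):
                union(i, j)

    groups: dict[int, list] = {}
    for i, it in enumerate(items):
        groups.setdefault(find(i), []).append(it)
    classes = []
    for members in groups.values():
        members.sort(key=lambda it: (it[0], sorted(it[1])))
        rep = members[0][2]
        # canonical display sequence: the aligned variant's sequence of the rep
        rep_aligned = _aligned_variants(rep, by_label[members[0][0]])[0]
        classes.append(
            AttractorClass(
                "",
                rep_aligned.sequence_str,
                [(lbl, s, rec) for lbl, s, rec, _ in members],
                rep_aligned,
            )
        )
    classes.sort(key=lambda c: (-c.n_attractors, c.sequence, c.members[0][0]))
    for k, c in enumerate(classes):
        c.class_id = f"class{k + 1:02d}"
    return classes


def assign_ghosts_to_classes(
    report: CensusReport,
    classes: list[AttractorClass],
    rescue_params: CTLNParams | None = None,
) -> list[AttractorClass]:
    """Attach each ghost prediction to an attractor class.

    Ghosts are not realized at the census parameters, so each ghost graph
    is re-run in the higher-inhibition regime where the ghost attractor
    exists; so is one representative graph of every class.  A ghost joins
    the class whose representative's rescue-regime attractor matches its
    own (aligned); ghosts matching no class form new ghost-only classes.
    Returns the updated class list (new classes appended).
    """
    rescue_params = rescue_params or CTLNParams.high_inhibition()
    copts = report.options.classify
    by_label = {g.label: g for g in report.graphs}
    ghost_entries = report.ghost_entries()
    if not ghost_entries:
        return classes

    rescue_cache: dict[str, CorrespondenceResult] = {}

    def rescue(label: str) -> CorrespondenceResult:
        if label not in rescue_cache:
            rescue_cache[label] = test_correspondence(
                by_label[label].graph, rescue_params, report.options,
                label=label, group=by_label[label].group,
            )
        return rescue_cache[label]

    def rescue_variants(label: str, support: frozenset[int]):
        r = rescue(label)
        rec = r.realized.get(support)
        if rec is None:
            # a symmetry-fixed attractor may serve two cores and be booked
            # under the partner; fall back to the loose correspondence
            tag = "".join(map(str, sorted(support)))
            for obs in r.attractors:
                if any(o.startswith(f"fp:{tag}:") for o in obs.origins) and (
                    obs.record.high_set <= support <= obs.record.participating
                ):
                    rec = obs.record
                    break
        if rec is None:
            return None
        return _aligned_variants(rec, by_label[label])

    class_rescue = []
    for cls in classes:
        lbl, sup, _ = cls.members[0]
        class_rescue.append(rescue_variants(lbl, sup))

    unmatched = []
    for lbl, sup in ghost_entries:
        gv = rescue_variants(lbl, sup)
        placed = False
        if gv is not None:
            for cls, cv in zip(classes, class_rescue):
                if cv is not None and _variants_match(gv, cv, copts):
                    cls.ghost_members.append((lbl, sup))
                    placed = True
                    break
        if not placed:
            unmatched.append((lbl, sup, gv))

    # ghost-only classes: group the leftovers among themselves
    while unmatched:
        lbl, sup, gv = unmatched.pop(0)
        group = [(lbl, sup)]
        rest = []
        for lbl2, sup2, gv2 in unmatched:
            if gv is not None and gv2 is not None and _variants_match(gv, gv2, copts):
                group.append((lbl2, sup2))
            else:
                rest.append((lbl2, sup2, gv2))
        unmatched = rest
        seq = gv[0].sequence_str if gv else ""
        cls = AttractorClass(
            f"class{len(classes) + 1:02d}(ghost)",
            seq,
            [],
            gv[0] if gv else None,
            ghost_members=group,
        )
        classes.append(cls)
    return classes


# ---------------------------------------------------------------------------
# Master patterns
# ---------------------------------------------------------------------------

def master_pattern_for_class(
    cls: AttractorClass,
    graphs: Sequence[CensusGraph],
    swap_de: bool = False,
) -> list[MasterPattern]:
    """Compact description of a class's graph family via master patterns.

    Members are grouped by a shared (base, in_set) presentation; within a
    group the common out-edges are required, the differing ones optional,
    and the rest forbidden.  A wildcard is widened as far as it goes
    without pulling in non-member graphs.
    """
    by_label = {g.label: g for g in graphs}
    member_labels = sorted({lbl for lbl, _, _ in cls.members} |
                           {lbl for lbl, _ in cls.ghost_members})
    member_canon = {canonical_form(by_label[l].graph) for l in member_labels}

    # candidate (base, in_set) presentations per member
    def name_keys(label: str) -> dict[tuple, frozenset[int]]:
        keys = {}
        for nm_str in by_label[label].names:
            if nm_str == "5cyc" or nm_str.startswith("3cyc"):
                continue
            nm = GraphName.parse(nm_str)
            keys[(nm.base, nm.in_set)] = nm.out_set
        return keys

    remaining = set(member_labels)
    patterns: list[MasterPattern] = []
    while remaining:
        # greedy: the (base, in_set) shared by the most remaining members
        counts: dict[tuple, list[str]] = {}
        for lbl in remaining:
            for key in name_keys(lbl):
                counts.setdefault(key, []).append(lbl)
        if not counts:
            break  # members without construction names (5-cycle, sources)
        key, labels = max(counts.items(), key=lambda kv: (len(kv[1]), str(kv[0])))
        base_id, in_set = key
        outs = [name_keys(l)[key] for l in labels]
        required = frozenset.intersection(*outs)
        allowed = frozenset.union(*outs)
        nb = base_graph(base_id, swap_de=swap_de).n
        all_free = frozenset(range(1, nb + 1)) - in_set

        def valid(req: frozenset, allw: frozenset) -> bool:
            free = sorted(allw - req)
            for r in range(len(free) + 1):
                for extra in itertools.combinations(free, r):
                    out = req | frozenset(extra)
                    if not out:
                        continue
                    G = build_from_name(GraphName(base_id, in_set, out), swap_de=swap_de)
                    if G.sources() or G.sinks():
                        continue
                    if canonical_form(G) not in member_canon:
                        return False
            return True

        # prefer the most general valid pattern
        chosen = None
        for req, allw in ((frozenset(), all_free), (required, all_free), (required, allowed)):
            if valid(req, allw):
                chosen = (req, allw)
                break
        req, allw = chosen if chosen else (required, allowed)
        patterns.append(
            MasterPattern(
                base_id, in_set, req, all_free - allw, wildcard=bool(allw - req)
            )
        )
        remaining -= set(labels)
    return patterns
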