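"""Parameter-free graph rules for fixed-point supports.

These combinatorial rules decide membership of a support sigma in FP(G)
directly from the graph, with no reference to (eps, delta, theta):

* sources   — a proper source inside sigma (in G|_sigma or in G) rules
              sigma out;
* sinks     — a singleton {i} is in FP(G) iff i is a sink of G;
* uniform   — if G|_sigma has uniform in-degree d, then sigma is in FP(G)
              iff no outside vertex receives more than d edges from sigma;
* parity    — |FP(G)| is odd, which can force the last unknown support.

They serve as an independent second route to FP(G), cross-checked against
the numeric enumeration.  The rules are sound but not complete: supports
they leave undecided must be settled numerically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

from .digraph import Digraph, induced_subgraph, uniform_in_degree, vertex_roles

__all__ = [
    "rule_sources",
    "rule_sinks",
    "rule_uniform_in_degree",
    "decide_by_rules",
    "RuleDecision",
]

EXCLUDED = "excluded"
INCLUDED = "included"
UNDECIDED = "undecided"


def rule_sources(G: Digraph, sigma: Iterable[int]) -> str:
    """Excluded when some i in sigma is a proper source in G|_sigma or in G."""
    sig = sorted(set(sigma))
    if not sig:
        raise ValueError("sigma must be non-empty")
    roles_G = vertex_roles(G)
    H, mapping = induced_subgraph(G, sig, return_mapping=True)
    roles_H = vertex_roles(H)
    for i in sig:
        if roles_G[i].is_proper_source or roles_H[mapping[i]].is_proper_source:
            return EXCLUDED
    return UNDECIDED


def rule_sinks(G: Digraph, sigma: Iterable[int]) -> str:
    """Decides every singleton: {i} is in FP(G) iff i is a sink of G."""
    sig = set(sigma)
    if len(sig) != 1:
        return UNDECIDED
    (i,) = sig
    return INCLUDED if vertex_roles(G)[i].is_sink else EXCLUDED


def rule_uniform_in_degree(G: Digraph, sigma: Iterable[int]) -> str:
    """If G|_sigma has uniform in-degree d: included iff every outside
    vertex receives at most d edges from sigma, else excluded."""
    sig = sorted(set(sigma))
    H = induced_subgraph(G, sig)
    d = uniform_in_degree(H)
    if d is None:
        return UNDECIDED
    for k in G.vertices:
        if k in sig:
            continue
        received = sum(1 for j in sig if G.has_edge(j, k))
        if received > d:
            return EXCLUDED
    return INCLUDED


_RULES = (
    ("sinks", rule_sinks),
    ("sources", rule_sources),
    ("uniform in-degree", rule_uniform_in_degree),
)


@dataclass(frozen=True)
class RuleDecision:
    """Outcome for one support: 'in', 'out' or 'unknown', with the rule named."""

    support: frozenset[int]
    verdict: str  # "in" | "out" | "unknown"
    rule: str | None


def decide_by_rules(G: Digraph) -> dict[frozenset[int], RuleDecision]:
    """Apply all rules to every support; close with parity when forced.

    Parity is applied only when exactly one support remains unknown: the
    total number of fixed points must be odd, so the last unknown is
    decided to make it so.  No speculative closure is attempted.
    """
    decisions: dict[frozenset[int], RuleDecision] = {}
    for size in range(1, G.n + 1):
        for sig in itertools.combinations(G.vertices, size):
            support = frozenset(sig)
            verdict, rule_name = "unknown", None
            for name, rule in _RULES:
                out = rule(G, sig)
                if out == INCLUDED:
                    verdict, rule_name = "in", name
                    break
                if out == EXCLUDED:
                    verdict, rule_name = "out", name
                    break
            decisions[support] = RuleDecision(support, verdict, rule_name)

    unknown = [s for s, d in decisions.items() if d.verdict == "unknown"]
    if len(unknown) == 1:
        n_in = sum(1 for d in decisions.values() if d.verdict == "in")
        forced = "out" if n_in % 2 == 1 else "in"
        decisions[unknown[0]] = RuleDecision(unknown[0], forced, "parity")
    return decisions
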