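"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: per-base
pileup arrays instead of event counters, boolean-matrix reachability
instead of Tarjan SCCs, and exhaustive simple-cycle search with a post-hoc
alternation filter instead of role-constrained DFS.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from nanocirc.breakpoint_graph import COVERAGE, COVERAGE_SPLIT, DELETION, SPLIT

ROLE_OPTIONS = {
    COVERAGE: ("cov",),
    DELETION: ("jun",),
    SPLIT: ("jun",),
    COVERAGE_SPLIT: ("cov", "jun"),
}


def pileup_depth(segments, contig, length):
    """Naive per-base pileup counter."""
    depth = np.zeros(length, dtype=np.int64)
    for seg in segments:
        if seg.contig == contig:
            depth[seg.start : seg.end] += 1
    return depth


def reachability_sccs(graph):
    """SCC partition from the boolean reachability closure."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in graph.edges:
        reach[idx[u], idx[v]] = True
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    groups = {}
    for i, node in enumerate(nodes):
        key = tuple(sorted(j for j in range(n) if reach[i, j] and reach[j, i]))
        groups.setdefault(key, []).append(node)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def cycle_key(nodes, roles):
    """Canonical identity of an (node, role) cycle: min over rotations of
    the forward and reversed traversal."""
    k = len(nodes)
    fwd = tuple(zip(nodes, roles))
    rev_nodes = tuple(nodes[(k - j) % k] for j in range(k))
    rev_roles = tuple(roles[(k - 1 - j) % k] for j in range(k))
    rev = tuple(zip(rev_nodes, rev_roles))
    return min(seq[r:] + seq[:r] for seq in (fwd, rev) for r in range(k))


def alternating_assignments(graph, cycle):
    """All role sequences making the node cycle a plausible circular path."""
    k = len(cycle)
    out = []
    for first in ("cov", "jun"):
        roles = []
        ok = True
        want = first
        for i in range(k):
            u, v = cycle[i], cycle[(i + 1) % k]
            if want not in ROLE_OPTIONS[graph[u][v]["type"]]:
                ok = False
                break
            roles.append(want)
            want = "jun" if want == "cov" else "cov"
        # cyclic alternation additionally needs even length
        if ok and k % 2 == 0:
            out.append(tuple(roles))
    return out


def brute_force_plausible_cycles(graph):
    """Exhaustive simple-cycle search filtered by the alternation predicate,
    deduplicated by canonical key.  Returns a set of keys."""
    keys = set()
    for cycle in nx.simple_cycles(graph):
        if len(cycle) < 2:
            continue
        for roles in alternating_assignments(graph, tuple(cycle)):
            keys.add(cycle_key(tuple(cycle), roles))
    return keys


def random_typed_digraph(rng, n_nodes=None, p_edge=0.35):
    """Random digraph with circle-caller edge types on nodes (contig, pos)."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 9))
    types = [COVERAGE, DELETION, SPLIT, COVERAGE_SPLIT]
    g = nx.DiGraph()
    nodes = [("c", int(i) * 100) for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for u, v in itertools.permutations(nodes, 2):
        if rng.random() < p_edge:
            t = types[int(rng.integers(4))]
            g.add_edge(u, v, type=t, mean_depth=10.0,
                       n_split_reads=1 if t in (SPLIT, COVERAGE_SPLIT) else 0)
    return g
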