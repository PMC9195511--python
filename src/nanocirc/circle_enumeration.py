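"""Plausible circular paths through strongly connected components.

A circle candidate is a simple cycle in the breakpoint graph whose edges
alternate between the coverage role (``coverage`` / ``coverage+split``
edges: a covered reference segment) and the junction role (``split`` /
``deletion`` / ``coverage+split`` edges: a breakpoint joining two loci).
Every second edge has to be a coverage edge — otherwise no reference
sequence would be covered between junctions.  The simplest candidate is two
nodes connected by a pair of ``coverage+split`` edges: a plain circle on one
contig whose junction reads map back onto the covered segment itself.

Enumeration is a Johnson-style rooted DFS per SCC with the alternation
constraint applied during the search, so implausible branches are pruned
immediately rather than filtered afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .breakpoint_graph import (
    COVERAGE_TYPES,
    JUNCTION_TYPES,
    DELETION,
    SPLIT,
    COVERAGE_SPLIT,
)

ROLE_COVERAGE = "cov"
ROLE_JUNCTION = "jun"

#: default safety limits; SCCs can hold exponentially many simple cycles
DEFAULT_MAX_CYCLES = 10_000
DEFAULT_MAX_EDGES = 64
_MAX_DFS_STEPS = 5_000_000


def edge_roles(edge_type: str) -> tuple[str, ...]:
    """Roles an edge of the given type may serve in a plausible path."""
    roles = ()
    if edge_type in COVERAGE_TYPES:
        roles += (ROLE_COVERAGE,)
    if edge_type in JUNCTION_TYPES:
        roles += (ROLE_JUNCTION,)
    return roles


@dataclass(frozen=True)
class Junction:
    """One junction of a circle: donor exits the preceding segment, acceptor
    enters the following one.  Endpoints are (contig, 0-based pos, side)."""

    donor: tuple
    acceptor: tuple
    kind: str  # "split" | "deletion"
    n_split_reads: int = 0


@dataclass
class CircleCandidate:
    """A canonical plausible circular path.

    ``nodes[i]`` is left by the edge with role ``roles[i]``; segments are the
    reference intervals of the coverage-role edges and junctions the
    split/deletion-role edges, both in traversal order.  With strict
    alternation there is exactly one segment between consecutive junctions.
    """

    nodes: tuple
    roles: tuple
    edge_types: tuple
    segments: list  # [(contig, start, end), ...] traversal order
    junctions: list  # [Junction, ...] traversal order
    mean_depths: tuple = ()
    circle_id: str = ""
    key: tuple = field(default=(), repr=False)

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def breakpoints(self) -> list:
        """All segment boundaries as (contig, position), sorted."""
        out = set()
        for c, s, e in self.segments:
            out.add((c, s))
            out.add((c, e))
        return sorted(out)

    def sorted_segments(self) -> list:
        return sorted(self.segments)


@dataclass
class EnumerationResult:
    candidates: list
    truncated: bool = False
    warnings: list = field(default_factory=list)


def strongly_connected_components(graph: nx.DiGraph) -> list:
    """Maximal strongly connected components, deterministically ordered."""
    return sorted((sorted(c) for c in nx.strongly_connected_components(graph)),
                  key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------------

def _cycle_key(nodes: tuple, roles: tuple) -> tuple:
    """Identity key of a cycle: lexicographic minimum of the (node, role)
    sequence over all rotations of the forward and the reversed traversal."""
    k = len(nodes)
    seqs = []
    fwd = tuple(zip(nodes, roles))
    rev_nodes = tuple(nodes[(k - j) % k] for j in range(k))
    rev_roles = tuple(roles[(k - 1 - j) % k] for j in range(k))
    rev = tuple(zip(rev_nodes, rev_roles))
    for seq in (fwd, rev):
        for r in range(k):
            seqs.append(seq[r:] + seq[:r])
    return min(seqs)


def _traversal_valid(graph: nx.DiGraph, nodes: tuple, roles: tuple) -> bool:
    k = len(nodes)
    for i in range(k):
        u, v = nodes[i], nodes[(i + 1) % k]
        if not graph.has_edge(u, v):
            return False
        if roles[i] not in edge_roles(graph[u][v]["type"]):
            return False
    return True


def canonicalize(graph: nx.DiGraph, nodes, roles) -> CircleCandidate:
    """Build the canonical :class:`CircleCandidate` for an alternating cycle.

    The rotation is fixed to start at the lexicographically smallest
    (contig, position) node; between a cycle and its reverse traversal the
    orientation with the smaller key is used when both are valid in the
    graph, so either traversal of the same circle yields the same candidate.
    """
    nodes, roles = tuple(nodes), tuple(roles)
    k = len(nodes)
    if k < 2 or k % 2 != 0:
        raise ValueError(f"alternating cycle must have even length >= 2, got {k}")
    for i in range(k):
        if roles[i] == roles[(i + 1) % k]:
            raise ValueError("cycle does not alternate coverage/junction roles")
    if not _traversal_valid(graph, nodes, roles):
        raise ValueError("cycle is not a valid traversal of the graph")

    key = _cycle_key(nodes, roles)
    # pick the orientation realizing the key when traversable, else forward
    orientations = [(nodes, roles)]
    rev_nodes = tuple(nodes[(k - j) % k] for j in range(k))
    rev_roles = tuple(roles[(k - 1 - j) % k] for j in range(k))
    if _traversal_valid(graph, rev_nodes, rev_roles):
        orientations.append((rev_nodes, rev_roles))

    def oriented_key(nr):
        ns, rs = nr
        return min(
            tuple(zip(ns, rs))[r:] + tuple(zip(ns, rs))[:r] for r in range(k)
        )

    nodes, roles = min(orientations, key=oriented_key)
    # rotate to the smallest starting node (ties broken by the full sequence)
    seq = tuple(zip(nodes, roles))
    best = min(range(k), key=lambda r: seq[r:] + seq[:r])
    nodes = nodes[best:] + nodes[:best]
    roles = roles[best:] + roles[:best]

    segments, junctions, types, depths = [], [], [], []
    for i in range(k):
        u, v = nodes[i], nodes[(i + 1) % k]
        d = graph[u][v]
        types.append(d["type"])
        if roles[i] == ROLE_COVERAGE:
            if u[0] != v[0]:
                raise ValueError(f"coverage edge spans contigs: {u} -> {v}")
            segments.append((u[0], min(u[1], v[1]), max(u[1], v[1])))
            depths.append(float(d.get("mean_depth", 0.0)))
        else:
            kind = DELETION if d["type"] == DELETION else SPLIT
            if "sides" in d:
                s_src, s_dst = d["sides"]
            else:  # deletion (or untyped): sides follow traversal direction
                rightward = u[1] < v[1]
                s_src = "L" if rightward else "R"
                s_dst = "R" if rightward else "L"
            junctions.append(
                Junction(
                    donor=(u[0], u[1], s_src),
                    acceptor=(v[0], v[1], s_dst),
                    kind=kind,
                    n_split_reads=int(d.get("n_split_reads", 0)),
                )
            )
    return CircleCandidate(
        nodes=nodes, roles=roles, edge_types=tuple(types),
        segments=segments, junctions=junctions,
        mean_depths=tuple(depths), key=key,
    )


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def enumerate_plausible_cycles(
    graph: nx.DiGraph,
    sccs=None,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    max_edges: int = DEFAULT_MAX_EDGES,
    require_split: bool = True,
) -> EnumerationResult:
    """Enumerate all plausible (alternating) simple cycles per SCC.

    ``require_split`` demands at least one split-backed junction per
    candidate, discarding cycles explained by coverage/deletion edges alone.
    Exceeding ``max_cycles`` or the internal step budget aborts enumeration
    with a truncation flag on the result rather than raising.
    """
    if sccs is None:
        sccs = strongly_connected_components(graph)
    found: dict[tuple, CircleCandidate] = {}
    result = EnumerationResult(candidates=[])
    steps = 0

    for scc in sccs:
        if len(scc) < 2:
            continue
        scc_sorted = sorted(scc)
        order = {n: i for i, n in enumerate(scc_sorted)}
        sub = graph.subgraph(scc_sorted)

        for root in scc_sorted:
            stack_nodes = [root]
            stack_roles: list[str] = []
            onpath = {root}

            def dfs(node, prev_role):
                nonlocal steps
                if result.truncated:
                    return
                for nbr in sub.successors(node):
                    if order[nbr] < order[root]:
                        continue
                    steps += 1
                    if steps > _MAX_DFS_STEPS:
                        result.truncated = True
                        result.warnings.append("step budget exhausted")
                        return
                    for role in edge_roles(sub[node][nbr]["type"]):
                        if role == prev_role:
                            continue
                        if nbr == root:
                            if len(stack_roles) >= 1 and role != stack_roles[0]:
                                _emit(tuple(stack_nodes), tuple(stack_roles) + (role,))
                                if len(found) > max_cycles:
                                    result.truncated = True
                                    result.warnings.append(
                                        f"more than {max_cycles} cycles"
                                    )
                                    return
                        elif nbr not in onpath and len(stack_roles) + 1 < max_edges:
                            stack_nodes.append(nbr)
                            stack_roles.append(role)
                            onpath.add(nbr)
                            dfs(nbr, role)
                            onpath.discard(nbr)
                            stack_roles.pop()
                            stack_nodes.pop()

            def _emit(nodes, roles):
                cand = canonicalize(sub, nodes, roles)
                if require_split and not any(
                    j.kind == SPLIT for j in cand.junctions
                ):
                    return
                found.setdefault(cand.key, cand)

            dfs(root, None)
            if result.truncated:
                break
        if result.truncated:
            break

    candidates = sorted(found.values(), key=lambda c: c.key)
    for i, cand in enumerate(candidates):
        cand.circle_id = f"circle_{i}"
    result.candidates = candidates
    return result
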