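"""Typed directed breakpoint graph from depth profile and split links.

Nodes are genomic loci ``(contig, position)``: the boundaries of enriched
(covered) regions of the depth profile plus the endpoints of split reads,
clustered within a merge tolerance.  Edges between contig neighbours are
typed by the depth over the spanned interval:

* ``coverage`` — the interval lies in an enriched region with mean depth
  >= theta;
* ``deletion`` — the interval is effectively uncovered (permitted inside
  circles, since library preparation can fragment molecules);

and split links add ``split`` edges between their endpoint nodes; a node
pair that is simultaneously coverage- and split-connected carries a single
``coverage+split`` edge.

Coverage-run segmentation
-------------------------
Circle-enriched libraries are not perfectly clean: residual linear DNA
leaves a sparse background (about 1x after enrichment), and at moderate
coverage sampling alone leaves holes inside genuinely covered segments.
Classifying each base as covered the moment a single read touches it would
therefore litter deletion intervals with phantom covered islands and break
covered segments at every sampling dip.  The graph is instead built on a
smoothed run classification of each contig:

1. candidate run boundaries are placed where the depth profile crosses
   ``zero_depth`` pointwise, and wherever depth steps concentrated within
   the merge tolerance add up to at least ``min_step`` — breakpoints of an
   enriched circle collect the starts/ends of many reads at one locus,
   while background and sampling noise move depth by one read at a time;
2. each run between boundaries is enriched (covered) when its mean depth
   reaches ``min_island_depth``; weaker runs are attributed to residual
   background;
3. an uncovered run of length g flanked by enriched coverage of depth c is
   absorbed as sampling dropout unless ``c * g / read_length > gap_factor``
   — the expected number of reads a c-deep library would have placed across
   the hole; only holes that are implausible under sampling count as
   deletions.

``GraphParams.strict()`` disables the smoothing and recovers the literal
rules (any read covers, any zero-coverage interval is a deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .alignment_evidence import DepthProfile, SplitLink

logger = logging.getLogger("nanocirc")

COVERAGE = "coverage"
DELETION = "deletion"
SPLIT = "split"
COVERAGE_SPLIT = "coverage+split"

#: edge types that can serve the coverage role in a plausible path
COVERAGE_TYPES = frozenset({COVERAGE, COVERAGE_SPLIT})
#: edge types that can serve the junction role
JUNCTION_TYPES = frozenset({SPLIT, DELETION, COVERAGE_SPLIT})

# DOT colors follow the usual convention: blue coverage, red deletion,
# orange split, green coverage+split.
_DOT_COLORS = {COVERAGE: "blue", DELETION: "red", SPLIT: "orange",
               COVERAGE_SPLIT: "green"}


@dataclass(frozen=True)
class GraphParams:
    """Construction parameters, recorded on the graph for provenance.

    theta: minimum mean depth of a coverage edge.
    merge_tol: clustering tolerance (bp) for noisy breakpoint endpoints.
    mapq_min: minimum MAPQ for split links entering the graph.
    zero_depth: pointwise crossings of this depth mark candidate run
        boundaries (delimits background islands from true zero coverage).
    min_step: net depth change, concentrated within merge_tol, that marks a
        candidate run boundary; breakpoints pile many read starts/ends onto
        one locus.  None disables step detection.
    min_island_depth: minimum mean depth for a run to count as enriched
        rather than residual-background stacking.
    gap_factor: significance factor for real deletions; an uncovered run is
        a deletion only if flanking coverage would have been expected to
        place more than ``gap_factor`` reads across it.
    read_length_hint: typical read length used by the gap test; estimated
        from the data when None.
    max_deletion_length: cap on deletion-edge length.  Library preparation
        drops stretches of a circle at the fragment scale; without a cap,
        any two enriched regions of a contig become graph neighbours and
        unrelated circles chain into chimeric candidates.  None disables.
    """

    theta: float = 1.0
    merge_tol: int = 10
    mapq_min: int = 0
    zero_depth: float = 3.0
    min_step: float | None = 4.0
    min_island_depth: float = 5.0
    gap_factor: float = 4.0
    read_length_hint: float | None = None
    max_deletion_length: int | None = 10_000

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError(f"theta must be >= 1, got {self.theta}")
        if self.merge_tol < 0:
            raise ValueError("merge_tol must be >= 0")

    @classmethod
    def strict(cls, **kwargs) -> "GraphParams":
        """Literal classification: any read covers, any zero interval is a
        deletion, no smoothing."""
        base = dict(zero_depth=1.0, min_step=None, min_island_depth=1e-9,
                    gap_factor=0.0, max_deletion_length=None)
        base.update(kwargs)
        return cls(**base)


@dataclass
class Run:
    start: int
    end: int
    covered: bool
    mean: float

    @property
    def length(self) -> int:
        return self.end - self.start


def step_boundaries(profile: DepthProfile, contig: str, merge_tol: int,
                    min_step: float) -> list[int]:
    """Loci where depth steps concentrated within ``merge_tol`` add up to at
    least ``min_step`` in magnitude.

    A circle breakpoint collects the starts (or ends) of many reads at one
    locus, so the net step there is on the order of the circle coverage;
    background reads and sampling noise change depth by one read at a time.
    The reported locus is the position of the largest single step of the
    cluster (the unjittered majority of endpoints).
    """
    positions, depths = profile.steps(contig)
    if len(positions) == 0:
        return []
    steps = np.diff(np.concatenate(([0], depths)))
    out = []
    cluster: list[int] = []

    def flush():
        if not cluster:
            return
        net = sum(steps[i] for i in cluster)
        if abs(net) >= min_step:
            best = max(cluster, key=lambda i: abs(steps[i]))
            out.append(int(positions[best]))

    for i in range(len(positions)):
        if cluster and positions[i] - positions[cluster[-1]] > merge_tol:
            flush()
            cluster = []
        cluster.append(i)
    flush()
    return out


def coverage_runs(
    profile: DepthProfile,
    contig: str,
    params: GraphParams,
    read_length: float,
) -> list[Run]:
    """Smoothed enriched/uncovered segmentation of one contig."""
    bounds = set(int(p) for p in profile.state_changepoints(contig, params.zero_depth))
    if params.min_step is not None:
        bounds.update(step_boundaries(profile, contig, params.merge_tol,
                                      params.min_step))
    bounds = sorted(bounds)
    if len(bounds) < 2:
        return []
    runs = [
        Run(a, b, False, profile.mean_depth(contig, a, b))
        for a, b in zip(bounds, bounds[1:])
    ]
    for i, r in enumerate(runs):
        runs[i] = Run(r.start, r.end, r.mean >= params.min_island_depth, r.mean)

    def merge_adjacent(rs: list[Run]) -> list[Run]:
        out: list[Run] = []
        for r in rs:
            if out and out[-1].covered == r.covered:
                prev = out[-1]
                total = prev.length + r.length
                mean = (prev.mean * prev.length + r.mean * r.length) / total
                out[-1] = Run(prev.start, r.end, r.covered, mean)
            else:
                out.append(r)
        return out

    runs = merge_adjacent(runs)
    for _ in range(20):
        changed = False
        # absorb sampling-dropout holes between enriched runs
        for i, r in enumerate(runs):
            if r.covered or i == 0 or i == len(runs) - 1:
                continue
            left, right = runs[i - 1], runs[i + 1]
            if not (left.covered and right.covered):
                continue
            c = min(left.mean, right.mean)
            if c * r.length <= params.gap_factor * read_length:
                runs[i] = Run(r.start, r.end, True, r.mean)
                changed = True
        runs = merge_adjacent(runs)
        # re-derive merged means from the profile for accuracy
        runs = [Run(r.start, r.end, r.covered,
                    profile.mean_depth(contig, r.start, r.end)) for r in runs]
        if not changed:
            break
    # drop leading/trailing uncovered runs: no covered anchor beyond them
    while runs and not runs[0].covered:
        runs.pop(0)
    while runs and not runs[-1].covered:
        runs.pop()
    return runs


def estimate_read_length(profile: DepthProfile, links=None, default=8000.0,
                         segments=None) -> float:
    """Typical aligned-segment length, for the gap significance test."""
    if segments:
        spans = [s.span for s in segments]
        if spans:
            return float(np.clip(np.mean(spans), 500.0, 50_000.0))
    return default


def _cluster_positions(positions: list[int], merge_tol: int) -> dict[int, int]:
    """Greedy gap-clustering: map each position to the integer median of its
    cluster; a new cluster starts when the gap to the previous position
    exceeds ``merge_tol``."""
    mapping: dict[int, int] = {}
    if not positions:
        return mapping
    positions = sorted(set(positions))
    cluster = [positions[0]]

    def flush():
        rep = int(np.median(cluster))
        for p in cluster:
            mapping[p] = rep

    for p in positions[1:]:
        if p - cluster[-1] > merge_tol:
            flush()
            cluster = [p]
        else:
            cluster.append(p)
    flush()
    return mapping


def collect_nodes(
    profile: DepthProfile,
    links: list[SplitLink],
    params: GraphParams = GraphParams(),
    read_length: float | None = None,
) -> tuple[list[tuple[str, int]], list[SplitLink]]:
    """Collect graph nodes and re-point split links to cluster medians.

    Nodes are the union of covered-run boundaries and split-link endpoints;
    positions within ``params.merge_tol`` on the same contig are clustered
    to a single node at the median position.  Returns the node list and the
    remapped links.
    """
    if read_length is None:
        read_length = estimate_read_length(profile)
    per_contig: dict[str, list[int]] = {}
    for contig in profile.contigs:
        ps = per_contig.setdefault(contig, [])
        for run in coverage_runs(profile, contig, params, read_length):
            if run.covered:
                ps.extend((run.start, run.end))
    for lk in links:
        for contig, pos, _side in (lk.end_a, lk.end_b):
            per_contig.setdefault(contig, []).append(int(pos))
    mapping = {
        contig: _cluster_positions(ps, params.merge_tol)
        for contig, ps in per_contig.items()
    }
    nodes = sorted(
        {(contig, rep) for contig, m in mapping.items() for rep in m.values()}
    )
    remapped: list[SplitLink] = []
    n_dropped = 0
    for lk in links:
        ca, pa, sa = lk.end_a
        cb, pb, sb = lk.end_b
        end_a = (ca, mapping[ca][pa], sa)
        end_b = (cb, mapping[cb][pb], sb)
        if (end_a[0], end_a[1]) == (end_b[0], end_b[1]):
            n_dropped += 1  # both endpoints collapsed onto one node
            continue
        remapped.append(replace(lk, end_a=end_a, end_b=end_b))
    if n_dropped:
        logger.info("collect_nodes: dropped %d self-collapsed links", n_dropped)
    return nodes, remapped


def build_graph(
    nodes: list[tuple[str, int]],
    profile: DepthProfile,
    links: list[SplitLink],
    params: GraphParams = GraphParams(),
    read_length: float | None = None,
) -> nx.DiGraph:
    """Build the typed directed breakpoint graph.

    Neighbouring nodes on a contig get coverage edges (both directions) when
    the interval lies in an enriched run with mean depth >= theta, deletion
    edges (both directions) when it is effectively uncovered, and no
    neighbour edge when the mean is positive but sub-threshold.  Split links
    are merged on their unordered endpoint set and materialized as split
    edges in both directions (forward- and reverse-strand junction reads
    witness the two traversal orientations of the same physical junction).
    """
    if read_length is None:
        read_length = estimate_read_length(profile)
    g = nx.DiGraph(params=params)
    g.add_nodes_from(nodes)

    runs_by_contig = {
        contig: coverage_runs(profile, contig, params, read_length)
        for contig in profile.contigs
    }

    def covered_at(contig: str, pos: float) -> bool:
        for run in runs_by_contig.get(contig, []):
            if run.start <= pos < run.end:
                return run.covered
        return False

    per_contig: dict[str, list[int]] = {}
    for contig, pos in nodes:
        per_contig.setdefault(contig, []).append(pos)
    for contig, positions in per_contig.items():
        positions.sort()
        for a, b in zip(positions, positions[1:]):
            mean = profile.mean_depth(contig, a, b)
            if covered_at(contig, (a + b) / 2):
                if mean < params.theta:
                    continue  # sub-threshold: neither covered nor deleted
                etype = COVERAGE
            else:
                if (params.max_deletion_length is not None
                        and b - a > params.max_deletion_length):
                    continue
                etype = DELETION
            u, v = (contig, a), (contig, b)
            attrs = dict(type=etype, mean_depth=mean, n_split_reads=0, link_ids="")
            g.add_edge(u, v, **attrs)
            g.add_edge(v, u, **dict(attrs))

    # merge links on their unordered endpoint set
    junctions: dict[frozenset, dict] = {}
    for lk in links:
        if lk.mapq_min < params.mapq_min:
            continue
        info = junctions.setdefault(
            lk.endpoints, {"n": 0, "reads": [], "ends": (lk.end_a, lk.end_b)}
        )
        info["n"] += 1
        info["reads"].append(lk.read_id)

    for info in junctions.values():
        end_a, end_b = info["ends"]
        u = (end_a[0], end_a[1])
        v = (end_b[0], end_b[1])
        for src, dst, s_src, s_dst in ((u, v, end_a[2], end_b[2]),
                                       (v, u, end_b[2], end_a[2])):
            if g.has_edge(src, dst):
                data = g[src][dst]
                if data["type"] == COVERAGE:
                    data["type"] = COVERAGE_SPLIT
                elif data["type"] == DELETION:
                    # uncovered neighbours joined by split reads: the split
                    # evidence defines the junction type
                    data["type"] = SPLIT
                data["n_split_reads"] += info["n"]
                data["sides"] = (s_src, s_dst)
                data["link_ids"] = ",".join(sorted(set(info["reads"])))
            else:
                g.add_edge(
                    src, dst, type=SPLIT, mean_depth=0.0,
                    n_split_reads=info["n"], sides=(s_src, s_dst),
                    link_ids=",".join(sorted(set(info["reads"]))),
                )
    return g


def build_breakpoint_graph(
    profile: DepthProfile,
    links: list[SplitLink],
    params: GraphParams = GraphParams(),
    segments=None,
) -> nx.DiGraph:
    """Convenience: collect nodes, remap links, and build the graph."""
    read_length = estimate_read_length(profile, segments=segments)
    nodes, remapped = collect_nodes(profile, links, params, read_length)
    return build_graph(nodes, profile, remapped, params, read_length)


def prune_graph(graph: nx.DiGraph) -> nx.DiGraph:
    """Remove nodes without any incident coverage-type edge.

    A plausible path alternates between coverage and junction edges, so a
    node touching only split/deletion edges can never lie on one.  Iterates
    to a fixpoint (idempotent).
    """
    g = graph.copy()
    while True:
        doomed = [
            n for n in g.nodes
            if not any(
                d["type"] in COVERAGE_TYPES
                for _, _, d in list(g.in_edges(n, data=True))
                + list(g.out_edges(n, data=True))
            )
        ]
        if not doomed:
            return g
        g.remove_nodes_from(doomed)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _stringify(g: nx.DiGraph) -> nx.DiGraph:
    out = nx.DiGraph(**{k: str(v) for k, v in g.graph.items()})
    for n in g.nodes:
        out.add_node(f"{n[0]}:{n[1]}", contig=n[0], position=int(n[1]))
    for u, v, d in g.edges(data=True):
        out.add_edge(
            f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}",
            type=d["type"], mean_depth=float(d.get("mean_depth", 0.0)),
            n_split_reads=int(d.get("n_split_reads", 0)),
            link_ids=str(d.get("link_ids", "")),
        )
    return out


def write_graphml(graph: nx.DiGraph, path: str) -> None:
    nx.write_graphml(_stringify(graph), path)


def write_dot(graph: nx.DiGraph, path: str) -> None:
    """Minimal DOT export with the conventional edge colors."""
    with open(path, "w") as fh:
        fh.write("digraph breakpoints {\n")
        for n in sorted(graph.nodes):
            fh.write(f'  "{n[0]}:{n[1]}";\n')
        for u, v, d in graph.edges(data=True):
            color = _DOT_COLORS.get(d["type"], "black")
            label = d["type"]
            if d["type"] in COVERAGE_TYPES:
                label += f' {d.get("mean_depth", 0.0):.1f}x'
            if d.get("n_split_reads", 0):
                label += f' n={d["n_split_reads"]}'
            fh.write(
                f'  "{u[0]}:{u[1]}" -> "{v[0]}:{v[1]}" '
                f'[color={color}, label="{label}"];\n'
            )
        fh.write("}\n")
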