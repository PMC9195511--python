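"""End-to-end detection pipeline over in-memory alignment records.

Chains the stages: depth profile + split links -> breakpoint graph ->
pruning -> SCC partition -> plausible-cycle enumeration -> junction support
collection -> posterior scoring.  The CLI wraps this with file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .alignment_evidence import (
    AlignedSegment,
    compute_depth_profile,
    extract_split_links,
)
from .breakpoint_graph import GraphParams, build_breakpoint_graph, prune_graph
from .circle_enumeration import (
    DEFAULT_MAX_CYCLES,
    DEFAULT_MAX_EDGES,
    enumerate_plausible_cycles,
)
from .circle_scoring import ScoringModel, score_candidates


@dataclass
class DetectionResult:
    profile: object
    links: list
    graph: object
    pruned: object
    enumeration: object
    calls: list = field(default_factory=list)

    @property
    def candidates(self) -> list:
        return self.enumeration.candidates


def detect_circles(
    segments: Sequence[AlignedSegment],
    params: GraphParams = GraphParams(),
    model: ScoringModel | None = None,
    support_tolerance: int = 10,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    max_edges: int = DEFAULT_MAX_EDGES,
    require_split: bool = True,
    depth_mapq_filter: bool = False,
) -> DetectionResult:
    """Run the full detection chain on mapped read segments.

    ``depth_mapq_filter`` also applies ``params.mapq_min`` to the depth
    estimate (by default the threshold filters only split links; with the
    default ``mapq_min = 0`` the two behave identically).
    """
    segments = sorted(segments, key=lambda s: (s.contig, s.start, s.read_id))
    profile = compute_depth_profile(
        segments, mapq_min=params.mapq_min if depth_mapq_filter else 0
    )
    links = extract_split_links(segments, mapq_min=params.mapq_min)
    graph = build_breakpoint_graph(profile, links, params, segments=segments)
    pruned = prune_graph(graph)
    enumeration = enumerate_plausible_cycles(
        pruned, max_cycles=max_cycles, max_edges=max_edges,
        require_split=require_split,
    )
    calls = score_candidates(
        enumeration.candidates, segments, links,
        model=model, tolerance=support_tolerance, mapq_min=params.mapq_min,
    )
    return DetectionResult(
        profile=profile, links=links, graph=graph, pruned=pruned,
        enumeration=enumeration, calls=calls,
    )
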