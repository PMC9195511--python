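"""Read-depth profiles and split-read junction links from mapped long reads.

This module is the evidence layer of the circle caller.  From a stream of
mapped read segments (primary + supplementary alignments) it derives

* a :class:`DepthProfile` — a per-contig step function of read depth built
  from start/end counter events (the mosdepth-style estimator: increment a
  counter at each segment's reference start, decrement at its reference end,
  take the cumulative sum), and
* :class:`SplitLink` records — one per adjacent pair of aligned segments of
  the same read in query order, marking a junction between two reference
  loci evidenced by a split alignment.

Coordinates are 0-based half-open throughout; conversion to 1-based happens
only at VCF/report boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nanocirc")

#: side of a junction a segment occupies: the segment lies to the Left of the
#: breakpoint position (read exits rightward across it) or to the Right of it
#: (read enters from it).
SIDE_LEFT = "L"
SIDE_RIGHT = "R"

# CIGAR operation codes (pysam numeric convention)
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H, _CIG_EQ, _CIG_X = 0, 1, 2, 3, 4, 5, 7, 8
_REF_CONSUMING = {_CIG_M, _CIG_D, _CIG_N, _CIG_EQ, _CIG_X}
_CLIP_OPS = {_CIG_S, _CIG_H}

_CIGAR_CODE = {"M": _CIG_M, "I": _CIG_I, "D": _CIG_D, "N": _CIG_N, "S": _CIG_S,
               "H": _CIG_H, "P": 6, "=": _CIG_EQ, "X": _CIG_X}


@dataclass
class AlignedSegment:
    """One aligned segment of a read (a primary or supplementary record).

    ``start``/``end`` are the 0-based half-open reference span of the
    alignment; ``query_start`` is the offset of this segment within the read
    in read orientation, used to order the segments of a split read.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    mapq: int = 60
    is_supplementary: bool = False
    query_start: int = 0
    cigar: tuple = ()  # ((op_code, length), ...) — optional, used for QC only
    sa_entries: tuple = ()  # ((contig, pos1, strand, cigar_str, mapq), ...)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.read_id} {self.contig}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"segment {self.read_id}: MAPQ {self.mapq} outside 0-255")
        if self.strand not in "+-":
            raise ValueError(f"segment {self.read_id}: strand must be '+' or '-'")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SplitLink:
    """A junction between two reference loci evidenced by one split read.

    Each endpoint is ``(contig, position, side)`` where ``side`` says which
    side of the breakpoint the aligned segment occupies (:data:`SIDE_LEFT` or
    :data:`SIDE_RIGHT`).  ``end_a`` is the donor (earlier in query order) and
    ``end_b`` the acceptor.
    """

    read_id: str
    end_a: tuple  # (contig, pos, side)
    end_b: tuple
    mapq_min: int

    def __post_init__(self) -> None:
        if self.end_a == self.end_b:
            raise ValueError(f"degenerate split link in read {self.read_id}")

    @property
    def endpoints(self) -> frozenset:
        """Unordered endpoint set; strand-opposite observations of the same
        physical junction have identical endpoint sets."""
        return frozenset((self.end_a, self.end_b))


def parse_sa_tag(sa: str) -> tuple:
    """Parse a standard SA tag value ``contig,pos,strand,CIGAR,mapQ,NM;...``.

    Raises ``ValueError`` on malformed entries.
    """
    entries = []
    for chunk in sa.strip(";").split(";"):
        if not chunk:
            continue
        parts = chunk.split(",")
        if len(parts) < 5:
            raise ValueError(f"malformed SA entry {chunk!r}")
        contig, pos, strand, cig = parts[0], int(parts[1]), parts[2], parts[3]
        if strand not in "+-":
            raise ValueError(f"malformed SA strand in {chunk!r}")
        entries.append((contig, pos, strand, cig, int(parts[4])))
    return tuple(entries)


def segment_from_pysam(rec) -> AlignedSegment:
    """Convert a mapped, non-secondary :class:`pysam.AlignedSegment`."""
    cig = tuple(rec.cigartuples or ())
    lead = 0
    for op, ln in cig:
        if op in _CLIP_OPS:
            lead += ln
        else:
            break
    trail = 0
    for op, ln in reversed(cig):
        if op in _CLIP_OPS:
            trail += ln
        else:
            break
    sa_entries: tuple = ()
    if rec.has_tag("SA"):
        try:
            sa_entries = parse_sa_tag(rec.get_tag("SA"))
        except ValueError as exc:
            warnings.warn(f"read {rec.query_name}: skipping SA tag ({exc})")
    return AlignedSegment(
        read_id=rec.query_name,
        contig=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        is_supplementary=rec.is_supplementary,
        # in read orientation the offset of a reverse-strand segment is its
        # trailing clip in reference orientation
        query_start=trail if rec.is_reverse else lead,
        cigar=cig,
        sa_entries=sa_entries,
    )


def read_alignments(path: str) -> Iterator[AlignedSegment]:
    """Stream mapped, non-secondary segments from a SAM/BAM file."""
    import pysam

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            yield segment_from_pysam(rec)


# ---------------------------------------------------------------------------
# Depth profile
# ---------------------------------------------------------------------------

class DepthProfile:
    """Per-contig right-open step function of read depth.

    Stored as arrays ``positions`` / ``depths`` where ``depths[i]`` holds on
    ``[positions[i], positions[i+1])``; depth is 0 before the first position
    and after the last (the profile closes at 0 by construction, since every
    increment has a matching decrement).
    """

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._steps = steps

    @property
    def contigs(self) -> list[str]:
        return list(self._steps)

    def steps(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        return self._steps.get(contig, (np.empty(0, dtype=np.int64),
                                        np.empty(0, dtype=np.int64)))

    def depth_at(self, contig: str, pos: int) -> float:
        positions, depths = self.steps(contig)
        i = int(np.searchsorted(positions, pos, side="right")) - 1
        if i < 0 or i >= len(depths):
            return 0.0
        return float(depths[i])

    def _interval_arrays(self, contig, start, end):
        positions, depths = self.steps(contig)
        if len(positions) == 0 or start >= end:
            return None
        # breakpoints of the step function clipped to [start, end)
        i0 = int(np.searchsorted(positions, start, side="right")) - 1
        i1 = int(np.searchsorted(positions, end, side="left"))
        cut = positions[max(i0, 0):i1].astype(np.int64)
        vals = depths[max(i0, 0):i1].astype(np.float64)
        if i0 < 0:
            cut = np.concatenate(([start], cut))
            vals = np.concatenate(([0.0], vals))
        cut = np.maximum(cut, start)
        bounds = np.concatenate((cut, [end]))
        widths = np.diff(bounds)
        return vals, widths

    def mean_depth(self, contig: str, start: int, end: int) -> float:
        """Length-weighted mean depth over [start, end); unprofiled bases
        count as depth 0."""
        if start >= end:
            raise ValueError(f"empty interval {contig}:{start}-{end}")
        arrs = self._interval_arrays(contig, start, end)
        if arrs is None:
            return 0.0
        vals, widths = arrs
        return float(np.dot(vals, widths) / (end - start))

    def max_depth(self, contig: str, start: int, end: int) -> float:
        arrs = self._interval_arrays(contig, start, end)
        if arrs is None:
            return 0.0
        vals, widths = arrs
        vals = vals[widths > 0]
        return float(vals.max()) if len(vals) else 0.0

    def changepoints(self, contig: str) -> np.ndarray:
        """All positions where the depth value changes."""
        positions, _ = self.steps(contig)
        return positions.copy()

    def state_changepoints(self, contig: str, zero_depth: float = 1.0) -> np.ndarray:
        """Positions where the depth crosses the covered/uncovered boundary
        (covered means depth >= ``zero_depth``).

        These are the loci at which the edge classification of the breakpoint
        graph can change; fluctuations within the covered state do not affect
        graph semantics and are not breakpoint candidates.
        """
        positions, depths = self.steps(contig)
        if len(positions) == 0:
            return positions
        covered = depths >= zero_depth
        prev = np.concatenate(([False], covered[:-1]))
        return positions[covered != prev]

    def to_bedgraph(self, path: str) -> None:
        """Write the profile as 4-column TSV (contig, start, end, depth)."""
        with open(path, "w") as fh:
            fh.write("#contig\tstart\tend\tdepth\n")
            for contig, (positions, depths) in self._steps.items():
                for i in range(len(positions) - 1):
                    fh.write(f"{contig}\t{positions[i]}\t{positions[i + 1]}\t{depths[i]}\n")


def compute_depth_profile(
    segments: Iterable[AlignedSegment], mapq_min: int = 0
) -> DepthProfile:
    """Build the depth step function from start/end counter events.

    Requires segments sorted by (contig, start) with contigs grouped;
    segments with MAPQ below ``mapq_min`` are excluded.  Secondary alignments
    must already have been dropped; supplementary segments contribute.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    events: dict[str, list[tuple[int, int]]] = {}
    seen_contigs: list[str] = []
    last_start = None
    for seg in segments:
        if not seen_contigs or seg.contig != seen_contigs[-1]:
            if seg.contig in seen_contigs:
                raise ValueError(
                    f"input not sorted: contig {seg.contig} re-appears at "
                    f"record {seg.read_id} {seg.contig}:{seg.start}"
                )
            seen_contigs.append(seg.contig)
            last_start = -1
        if seg.start < last_start:
            raise ValueError(
                f"input not sorted: record {seg.read_id} at {seg.contig}:{seg.start} "
                f"follows position {last_start}"
            )
        last_start = seg.start
        if seg.mapq < mapq_min:
            continue
        ev = events.setdefault(seg.contig, [])
        ev.append((seg.start, 1))
        ev.append((seg.end, -1))
    steps = {}
    for contig, ev in events.items():
        arr = np.asarray(ev, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        pos = arr[order, 0]
        delta = arr[order, 1]
        upos, idx = np.unique(pos, return_index=True)
        sums = np.add.reduceat(delta, idx)
        depth = np.cumsum(sums)
        # drop events that cancel (no depth change) to keep steps minimal
        keep = np.concatenate(([True], depth[1:] != depth[:-1]))
        keep &= np.concatenate(([depth[0] != 0], np.full(len(depth) - 1, True)))
        steps[contig] = (upos[keep], depth[keep])
    return DepthProfile(steps)


def mean_depth(profile: DepthProfile, contig: str, start: int, end: int) -> float:
    """Module-level convenience wrapper around :meth:`DepthProfile.mean_depth`."""
    return profile.mean_depth(contig, start, end)


# ---------------------------------------------------------------------------
# Split links
# ---------------------------------------------------------------------------

def _junction_endpoints(first: AlignedSegment, second: AlignedSegment):
    # donor: where the read's alignment leaves `first` (its query end);
    # acceptor: where it resumes in `second` (its query start).
    if first.strand == "+":
        end_a = (first.contig, first.end, SIDE_LEFT)
    else:
        end_a = (first.contig, first.start, SIDE_RIGHT)
    if second.strand == "+":
        end_b = (second.contig, second.start, SIDE_RIGHT)
    else:
        end_b = (second.contig, second.end, SIDE_LEFT)
    return end_a, end_b


def extract_split_links(
    segments: Iterable[AlignedSegment], mapq_min: int = 0
) -> list[SplitLink]:
    """One :class:`SplitLink` per adjacent pair of segments of a split read.

    Segments of a read are ordered by query coordinate; a read with k aligned
    segments yields exactly k - 1 links.  Links where either segment's MAPQ
    is below ``mapq_min`` are dropped.
    """
    by_read: dict[str, list[AlignedSegment]] = {}
    for seg in segments:
        by_read.setdefault(seg.read_id, []).append(seg)
    links: list[SplitLink] = []
    for read_id, segs in by_read.items():
        if len(segs) < 2:
            continue
        segs.sort(key=lambda s: (s.query_start, s.contig, s.start))
        for first, second in zip(segs, segs[1:]):
            if first.mapq < mapq_min or second.mapq < mapq_min:
                continue
            end_a, end_b = _junction_endpoints(first, second)
            if end_a == end_b:
                continue  # degenerate (zero-length hop), not a junction
            links.append(
                SplitLink(
                    read_id=read_id,
                    end_a=end_a,
                    end_b=end_b,
                    mapq_min=min(first.mapq, second.mapq),
                )
            )
    return links


def write_split_links(links: Sequence[SplitLink], path: str) -> None:
    rows = [
        {
            "read_id": lk.read_id,
            "contig_a": lk.end_a[0], "pos_a": lk.end_a[1], "side_a": lk.end_a[2],
            "contig_b": lk.end_b[0], "pos_b": lk.end_b[1], "side_b": lk.end_b[2],
            "mapq_min": lk.mapq_min,
        }
        for lk in links
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "contig_a", "pos_a", "side_a",
                 "contig_b", "pos_b", "side_b", "mapq_min"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC binning (Fig-5-style per-bin read categories)
# ---------------------------------------------------------------------------

SPLIT_AT_BREAKPOINTS = "split_at_breakpoints"
SPLIT_READ_IN = "split_read_in"
SPLIT_READ_OUT = "split_read_out"


def _near(pos: int, targets, window: int) -> bool:
    return any(abs(pos - t) <= window for t in targets)


def classify_split_read(link_endpoints, circle_segments, breakpoints, window: int) -> str:
    """Classify a split read by where its junction endpoints fall.

    * ``split_at_breakpoints`` — every endpoint within +/- window of a circle
      breakpoint;
    * ``split_read_in`` — endpoints inside the circle's segments but not all
      at breakpoints;
    * ``split_read_out`` — at least one endpoint outside the circle's regions.
    """
    def inside(contig, pos):
        return any(
            c == contig and s - window <= pos <= e + window
            for c, s, e in circle_segments
        )

    for contig, pos, _side in link_endpoints:
        if not inside(contig, pos):
            return SPLIT_READ_OUT
    for contig, pos, _side in link_endpoints:
        bps = [p for c, p in breakpoints if c == contig]
        if not _near(pos, bps, window):
            return SPLIT_READ_IN
    return SPLIT_AT_BREAKPOINTS


def qc_bin_counts(
    segments: Sequence[AlignedSegment],
    links: Sequence[SplitLink],
    circle,
    window: int = 3,
    n_bins: int = 50,
    mapq_min: int = 0,
) -> pd.DataFrame:
    """Per-bin QC table over a circle's segments.

    For each bin of the circle coordinate (segments concatenated in circle
    order) counts match/insertion/deletion bases from the CIGARs of reads
    overlapping the bin, bases belonging to split reads by category (at
    breakpoints within ``+/- window``, inside the circle, or linking out of
    it), and mean read depth.  All counts honour ``mapq_min``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    circle_segments = [(c, s, e) for c, s, e in circle.segments]
    breakpoints = [(c, s) for c, s, e in circle_segments] + \
                  [(c, e) for c, s, e in circle_segments]
    total = sum(e - s for _, s, e in circle_segments)
    n_bins = max(1, min(n_bins, total))
    edges = np.linspace(0, total, n_bins + 1).astype(np.int64)

    # circle coordinate offsets of each segment
    offsets = []
    off = 0
    for c, s, e in circle_segments:
        offsets.append((c, s, e, off))
        off += e - s

    cols = ["matches", "insertions", "deletions",
            SPLIT_AT_BREAKPOINTS, SPLIT_READ_IN, SPLIT_READ_OUT, "depth_bases"]
    counts = {col: np.zeros(n_bins, dtype=np.float64) for col in cols}

    # classify each split read once
    link_by_read: dict[str, list[SplitLink]] = {}
    for lk in links:
        link_by_read.setdefault(lk.read_id, []).append(lk)
    read_class: dict[str, str] = {}
    for read_id, lks in link_by_read.items():
        eps = [ep for lk in lks for ep in (lk.end_a, lk.end_b)]
        read_class[read_id] = classify_split_read(
            eps, circle_segments, breakpoints, window
        )

    def add_range(col, circ_start, circ_end, per_base=1.0):
        if circ_end <= circ_start:
            return
        i0 = int(np.searchsorted(edges, circ_start, side="right")) - 1
        i1 = int(np.searchsorted(edges, circ_end, side="left"))
        for b in range(max(i0, 0), min(i1, n_bins)):
            lo = max(circ_start, edges[b])
            hi = min(circ_end, edges[b + 1])
            counts[col][b] += per_base * max(0, hi - lo)

    def to_circ(contig, start, end):
        """Project a reference interval onto circle-coordinate chunks."""
        for c, s, e, off in offsets:
            if c != contig:
                continue
            lo, hi = max(start, s), min(end, e)
            if lo < hi:
                yield off + lo - s, off + hi - s

    for seg in segments:
        if seg.mapq < mapq_min:
            continue
        cls = read_class.get(seg.read_id)
        for lo, hi in to_circ(seg.contig, seg.start, seg.end):
            add_range("depth_bases", lo, hi)
            if cls is not None:
                add_range(cls, lo, hi)
        # CIGAR walk for match/ins/del placement
        if seg.cigar:
            ref = seg.start
            for op, ln in seg.cigar:
                if op in (_CIG_M, _CIG_EQ, _CIG_X):
                    for lo, hi in to_circ(seg.contig, ref, ref + ln):
                        add_range("matches", lo, hi)
                    ref += ln
                elif op == _CIG_D or op == _CIG_N:
                    for lo, hi in to_circ(seg.contig, ref, ref + ln):
                        add_range("deletions", lo, hi)
                    ref += ln
                elif op == _CIG_I:
                    for lo, hi in to_circ(seg.contig, ref, ref + 1):
                        add_range("insertions", lo, hi, per_base=float(ln))
        else:
            for lo, hi in to_circ(seg.contig, seg.start, seg.end):
                add_range("matches", lo, hi)

    widths = np.diff(edges).astype(np.float64)
    df = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:]})
    for col in cols:
        df[col] = counts[col]
    df["depth"] = np.where(widths > 0, counts["depth_bases"] / widths, 0.0)
    return df.drop(columns=["depth_bases"])
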