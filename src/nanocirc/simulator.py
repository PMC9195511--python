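"""Synthetic circle-enriched nanopore libraries and recall/precision study.

Emulates what a circle-enrichment protocol followed by long-read sequencing
produces: reads sampled from random rotations of each circular template at
high coverage (default 25x), fragmented to a log-normal read-length
distribution, with junction-crossing reads emitted as split alignments
(primary + supplementary records with SA tags), plus linear whole-genome
background reads at low coverage (default 1x) modelling residual
undigested DNA.  Three circle topologies are generated: a plain circle on
one contig, a chimeric circle joining two contigs, and a circle with an
internal uncovered stretch (library preparation can drop part of a circle,
leaving a coverage hole with no split reads across it).

The evaluator implements recall = |C∩T| / |T| and precision = |C∩T| / |C|
for a call set C against simulated truth T, where a call matches a true
circle iff it has the same segment count and every breakpoint lies within a
tolerance (default 50 bp); 0/0 is reported as 1.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_evidence import AlignedSegment

SIMPLE = "simple"
CHIMERIC = "chimeric"
WITH_DELETION = "with_deletion"
TOPOLOGIES = (SIMPLE, CHIMERIC, WITH_DELETION)

_CIG_M, _CIG_I, _CIG_D, _CIG_S = 0, 1, 2, 4


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters of the simulation.

    Defaults mirror the evaluation conditions: 25x coverage over the
    circles, 1x linear background, log-normal read lengths with a median of
    8 kb, and per-base error rates typical of nanopore data (5%
    substitutions, 3% insertions, 4% deletions).  ``junction_jitter`` moves
    split-alignment endpoints by up to the given number of bases to mimic
    imprecise alignment at junctions.
    """

    seed: int = 0
    n_circles: int = 20
    size_range: tuple = (2_000, 50_000)
    topology_weights: dict = field(default_factory=lambda: {
        SIMPLE: 0.4, CHIMERIC: 0.3, WITH_DELETION: 0.3,
    })
    circle_coverage: float = 25.0
    background_coverage: float = 1.0
    read_length_median: float = 8_000.0
    read_length_sigma: float = 0.6
    min_read_length: int = 300
    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.04
    junction_jitter: int = 0
    mapq: int = 60
    max_circle_length: int = 1_000_000
    placement_margin: int = 25_000
    deletion_gap_range: tuple = (3_000, 8_000)
    min_segment_length: int = 1_000

    def __post_init__(self) -> None:
        if self.circle_coverage < 0 or self.background_coverage < 0:
            raise ValueError("coverages must be >= 0")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range must be (low, high)")


@dataclass
class TrueCircle:
    """Ground truth for one simulated circle.

    ``segments`` are the covered reference intervals in circle order;
    ``junction_kinds[i]`` joins segment i to segment (i+1) % n: ``split``
    for a sequenced junction, ``deletion`` for a library-prep coverage hole.
    """

    circle_id: str
    segments: list  # [(contig, start, end, strand)]
    topology: str
    junction_kinds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("circle must have at least one segment")
        if not self.junction_kinds:
            if self.topology == SIMPLE:
                self.junction_kinds = ["split"]
            elif self.topology == CHIMERIC:
                self.junction_kinds = ["split"] * len(self.segments)
            elif self.topology == WITH_DELETION:
                self.junction_kinds = ["deletion"] * (len(self.segments) - 1) + ["split"]
        if len(self.junction_kinds) != len(self.segments):
            raise ValueError("one junction kind per segment boundary required")

    @property
    def length(self) -> int:
        return sum(e - s for _c, s, e, _st in self.segments)

    def plain_segments(self) -> list:
        return [(c, s, e) for c, s, e, _ in self.segments]


def simulate_reference(
    n_contigs: int = 1,
    lengths: int | Sequence[int] = 1_000_000,
    gc: float = 0.41,
    seed: int = 0,
) -> dict[str, str]:
    """Deterministic pseudo-random reference sequences."""
    if isinstance(lengths, int):
        lengths = [lengths] * n_contigs
    if len(lengths) != n_contigs:
        raise ValueError("one length per contig required")
    rng = np.random.default_rng([seed, 101])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"AGCT", dtype=np.uint8)
    out = {}
    for i, length in enumerate(lengths):
        arr = rng.choice(alphabet, size=int(length), p=p)
        out[f"contig_{i}"] = arr.tobytes().decode("ascii")
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reference_lengths(reference) -> dict[str, int]:
    return {name: len(seq) if not isinstance(seq, int) else seq
            for name, seq in reference.items()}


def simulate_truth(reference, config: SimConfig) -> list[TrueCircle]:
    """Place non-overlapping circles of the configured topology mix."""
    ref_lengths = reference_lengths(reference)
    rng = np.random.default_rng([config.seed, 202])
    contigs = sorted(ref_lengths)
    weights = np.array([ref_lengths[c] for c in contigs], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list] = {c: [] for c in contigs}

    def free(contig, start, end):
        m = config.placement_margin
        return all(e2 <= start - m or s2 >= end + m for s2, e2 in occupied[contig])

    def place(length) -> tuple[str, int] | None:
        for _ in range(2000):
            contig = contigs[int(rng.choice(len(contigs), p=weights))]
            hi = ref_lengths[contig] - length - 1
            if hi <= 1:
                continue
            start = int(rng.integers(1, hi))
            if free(contig, start, start + length):
                return contig, start
        return None

    truth: list[TrueCircle] = []
    names = list(config.topology_weights)
    probs = np.array([config.topology_weights[t] for t in names], dtype=float)
    probs /= probs.sum()
    for i in range(config.n_circles):
        topology = names[int(rng.choice(len(names), p=probs))]
        size = int(rng.integers(config.size_range[0], config.size_range[1] + 1))
        size = min(size, config.max_circle_length)
        gap_lo, gap_hi = config.deletion_gap_range
        if topology == WITH_DELETION and size < gap_lo + 2 * config.min_segment_length:
            topology = SIMPLE  # too small to carry a resolvable coverage hole
        if topology == CHIMERIC and size < 2 * config.min_segment_length:
            topology = SIMPLE
        if topology == SIMPLE:
            loc = place(size)
            if loc is None:
                raise RuntimeError(
                    "cannot place circles; reduce n_circles or circle sizes"
                )
            contig, start = loc
            segments = [(contig, start, start + size, "+")]
            occupied[contig].append((start, start + size))
        elif topology == CHIMERIC:
            len_a = int(rng.integers(config.min_segment_length,
                                     size - config.min_segment_length + 1))
            len_b = size - len_a
            loc_a = place(len_a)
            if loc_a is None:
                raise RuntimeError("cannot place circles; reduce n_circles or sizes")
            ca, sa = loc_a
            occupied[ca].append((sa, sa + len_a))
            loc_b = place(len_b)
            if loc_b is None:
                raise RuntimeError("cannot place circles; reduce n_circles or sizes")
            cb, sb = loc_b
            occupied[cb].append((sb, sb + len_b))
            segments = [(ca, sa, sa + len_a, "+"), (cb, sb, sb + len_b, "+")]
        else:  # WITH_DELETION
            gap = int(rng.integers(gap_lo, gap_hi + 1))
            span = size + gap
            loc = place(span)
            if loc is None:
                raise RuntimeError("cannot place circles; reduce n_circles or sizes")
            contig, start = loc
            d1 = start + int(rng.integers(
                config.min_segment_length, size - config.min_segment_length + 1
            ))
            d2 = d1 + gap
            segments = [
                (contig, start, d1, "+"),
                (contig, d2, start + span, "+"),
            ]
            occupied[contig].append((start, start + span))
        truth.append(TrueCircle(f"true_{i}", segments, topology))
    return truth


def write_truth(truth: Sequence[TrueCircle], path: str) -> None:
    rows = []
    for tc in truth:
        for k, (contig, start, end, strand) in enumerate(tc.segments):
            rows.append({
                "circle_id": tc.circle_id, "topology": tc.topology,
                "segment_index": k, "contig": contig, "start": start,
                "end": end, "strand": strand,
                "junction_kind": tc.junction_kinds[k],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> list[TrueCircle]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    truth = []
    for cid, grp in df.groupby("circle_id", sort=True):
        grp = grp.sort_values("segment_index")
        truth.append(TrueCircle(
            circle_id=str(cid),
            segments=[(r.contig, int(r.start), int(r.end), r.strand)
                      for r in grp.itertuples(index=False)],
            topology=grp.iloc[0]["topology"],
            junction_kinds=[str(k) for k in grp["junction_kind"]],
        ))
    return truth


# ---------------------------------------------------------------------------
# Read simulation (direct-alignment mode)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    segments: list  # AlignedSegment, coordinate-sorted
    origins: dict  # base read id -> circle id or "background"

    def circle_read_ids(self) -> set:
        return {rid for rid, org in self.origins.items() if org != "background"}


def _noisy_cigar(span: int, rng, config: SimConfig) -> tuple[tuple, int]:
    """A CIGAR consuming exactly ``span`` reference bases, with indel events
    at the configured rates; returns (cigar, query_length)."""
    event_rate = config.ins_rate + config.del_rate
    if event_rate <= 0 or span < 20:
        return ((_CIG_M, span),), span
    ops = []
    qlen = 0
    remaining = span
    # one indel event per ~1/event_rate matched bases
    while remaining > 0:
        m = int(min(remaining, rng.geometric(min(event_rate, 0.5))))
        m = max(m, 1)
        ops.append((_CIG_M, m))
        qlen += m
        remaining -= m
        if remaining <= 0:
            break
        if rng.random() < config.ins_rate / event_rate:
            ilen = 1 + int(rng.poisson(0.5))
            ops.append((_CIG_I, ilen))
            qlen += ilen
        else:
            dlen = int(min(remaining, 1 + rng.poisson(0.5)))
            ops.append((_CIG_D, dlen))
            remaining -= dlen
    # merge adjacent ops of the same kind
    merged = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += ln
        else:
            merged.append([op, ln])
    return tuple((op, ln) for op, ln in merged), qlen


def _draw_read_length(rng, config: SimConfig) -> int:
    mu = math.log(config.read_length_median)
    return max(config.min_read_length,
               int(rng.lognormal(mu, config.read_length_sigma)))


def _circle_pieces(circle: TrueCircle, u: int, length: int) -> list[dict]:
    """Reference pieces of a read of ``length`` starting at circle
    coordinate ``u``; each piece carries the junction index it crosses into
    next (or None at the read end)."""
    seg_lengths = [e - s for _c, s, e, _st in circle.segments]
    offsets = np.concatenate(([0], np.cumsum(seg_lengths)))
    L = int(offsets[-1])
    pieces = []
    cur = u % L
    remaining = min(length, L)
    while remaining > 0:
        idx = bisect_right(offsets, cur) - 1
        contig, s, e, _strand = circle.segments[idx]
        within = cur - int(offsets[idx])
        take = int(min(remaining, seg_lengths[idx] - within))
        piece = {"contig": contig, "start": s + within, "end": s + within + take,
                 "junction_after": None}
        remaining -= take
        cur = (cur + take) % L
        if remaining > 0:
            piece["junction_after"] = idx  # junction joining seg idx -> idx+1
        pieces.append(piece)
    return pieces


def _emit_read(pieces, kinds, read_id, strand, rng, config, contig_lengths, out,
               origins, origin):
    """Turn a piece walk into read fragments and alignment records.

    Split junctions keep pieces in one read (supplementary alignments);
    deletion junctions break the molecule, so following pieces start a new
    read.
    """
    fragments = [[]]
    for piece in pieces:
        fragments[-1].append(dict(piece))
        j = piece["junction_after"]
        if j is not None and kinds[j] == "deletion":
            fragments[-1][-1]["junction_after"] = None
            fragments.append([])
    fragments = [f for f in fragments if f]
    jitter = config.junction_jitter
    for k, frag in enumerate(fragments):
        rid = read_id if len(fragments) == 1 else f"{read_id}_f{k}"
        origins[rid] = origin
        # jitter split-junction boundaries
        for a, b in zip(frag, frag[1:]):
            if jitter > 0:
                d1 = int(rng.integers(-jitter, jitter + 1))
                d2 = int(rng.integers(-jitter, jitter + 1))
                a["end"] = int(np.clip(a["end"] + d1, a["start"] + 1,
                                       contig_lengths[a["contig"]]))
                b["start"] = int(np.clip(b["start"] + d2, 0, b["end"] - 1))
        cigars = [_noisy_cigar(p["end"] - p["start"], rng, config) for p in frag]
        qlens = [q for _c, q in cigars]
        # query order: reverse of circle order on the minus strand
        order = list(range(len(frag)))
        if strand == "-":
            order = order[::-1]
        q_off = 0
        q_starts = {}
        for idx in order:
            q_starts[idx] = q_off
            q_off += qlens[idx]
        primary = max(range(len(frag)), key=lambda i: qlens[i])
        for i, piece in enumerate(frag):
            sa = tuple(
                (frag[j]["contig"], frag[j]["start"] + 1, strand,
                 _cigar_str(cigars[j][0]), config.mapq)
                for j in range(len(frag)) if j != i
            )
            out.append(AlignedSegment(
                read_id=rid,
                contig=piece["contig"],
                start=piece["start"],
                end=piece["end"],
                strand=strand,
                mapq=config.mapq,
                is_supplementary=(i != primary),
                query_start=q_starts[i],
                cigar=cigars[i][0],
                sa_entries=sa,
            ))


def _cigar_str(cigar) -> str:
    names = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 7: "=", 8: "X"}
    return "".join(f"{ln}{names[op]}" for op, ln in cigar)


def simulate_alignments(reference, truth: Sequence[TrueCircle],
                        config: SimConfig) -> SimulatedReads:
    """Simulate circle and background reads directly as alignment records."""
    contig_lengths = reference_lengths(reference)
    rng = np.random.default_rng([config.seed, 303])
    out: list[AlignedSegment] = []
    origins: dict[str, str] = {}

    for circle in truth:
        L = circle.length
        target = config.circle_coverage * L
        emitted = 0
        n = 0
        while emitted < target:
            length = min(_draw_read_length(rng, config), L)
            u = int(rng.integers(0, L))
            strand = "+" if rng.random() < 0.5 else "-"
            pieces = _circle_pieces(circle, u, length)
            _emit_read(pieces, circle.junction_kinds,
                       f"{circle.circle_id}_r{n}", strand, rng, config,
                       contig_lengths, out, origins, circle.circle_id)
            emitted += length
            n += 1

    if config.background_coverage > 0:
        contigs = sorted(contig_lengths)
        weights = np.array([contig_lengths[c] for c in contigs], dtype=float)
        genome = weights.sum()
        weights /= genome
        target = config.background_coverage * genome
        emitted = 0
        n = 0
        while emitted < target:
            contig = contigs[int(rng.choice(len(contigs), p=weights))]
            length = _draw_read_length(rng, config)
            start = int(rng.integers(0, contig_lengths[contig]))
            end = min(start + length, contig_lengths[contig])
            emitted += length
            if end - start < 50:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cigar, _qlen = _noisy_cigar(end - start, rng, config)
            rid = f"bg_r{n}"
            origins[rid] = "background"
            out.append(AlignedSegment(
                read_id=rid, contig=contig, start=start, end=end,
                strand=strand, mapq=config.mapq, cigar=cigar,
            ))
            n += 1

    out.sort(key=lambda s: (s.contig, s.start, s.read_id, s.query_start))
    return SimulatedReads(segments=out, origins=origins)


def subsample_reads(sim: SimulatedReads, fraction: float, seed: int) -> SimulatedReads:
    """Thin circle-derived reads uniformly per read, keeping the linear
    background constant (subsampling emulates lower circle coverage from the
    same library)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 404])
    base_ids = sorted({rid.rsplit("_f", 1)[0] for rid, org in sim.origins.items()
                       if org != "background"})
    keep_base = {rid for rid in base_ids if rng.random() < fraction}

    def keep(rid: str) -> bool:
        if sim.origins.get(rid) == "background":
            return True
        return rid.rsplit("_f", 1)[0] in keep_base

    segments = [s for s in sim.segments if keep(s.read_id)]
    origins = {rid: org for rid, org in sim.origins.items() if keep(rid)}
    return SimulatedReads(segments=segments, origins=origins)


# ---------------------------------------------------------------------------
# SAM / FASTQ emission
# ---------------------------------------------------------------------------

def write_sam(sim_or_segments, contig_lengths: dict, path: str) -> None:
    """Write alignment records as a coordinate-sorted SAM file."""
    import pysam

    segments = getattr(sim_or_segments, "segments", sim_or_segments)
    qlen_by_read: dict[str, int] = {}
    for seg in segments:
        cig_q = sum(ln for op, ln in (seg.cigar or ((0, seg.span),))
                    if op in (0, 1, 7, 8))
        qlen_by_read[seg.read_id] = max(
            qlen_by_read.get(seg.read_id, 0), seg.query_start + cig_q
        )
    names = sorted(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(contig_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for seg in sorted(segments, key=lambda s: (tid[s.contig], s.start, s.read_id)):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = seg.read_id
            rec.reference_id = tid[seg.contig]
            rec.reference_start = seg.start
            rec.mapping_quality = seg.mapq
            rec.is_reverse = seg.strand == "-"
            rec.is_supplementary = seg.is_supplementary
            core = list(seg.cigar or ((0, seg.span),))
            qlen = qlen_by_read[seg.read_id]
            cig_q = sum(ln for op, ln in core if op in (0, 1, 7, 8))
            lead = seg.query_start
            trail = qlen - seg.query_start - cig_q
            if seg.strand == "-":
                lead, trail = trail, lead
            cig = []
            if lead > 0:
                cig.append((_CIG_S, lead))
            cig.extend(core)
            if trail > 0:
                cig.append((_CIG_S, trail))
            rec.cigartuples = cig
            rec.query_sequence = None
            if seg.sa_entries:
                sa = "".join(
                    f"{c},{p},{st},{cg},{mq},0;" for c, p, st, cg, mq in seg.sa_entries
                )
                rec.set_tag("SA", sa)
            fh.write(rec)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def write_fastq(reference: dict[str, str], sim: SimulatedReads, config: SimConfig,
                path: str) -> None:
    """Emit read sequences with parametric errors, for running a real mapper.

    Sequences are regenerated from the reference pieces of each read with
    fresh errors at the configured rates (the direct-alignment records carry
    their own, independent error realization).
    """
    rng = np.random.default_rng([config.seed, 505])
    by_read: dict[str, list[AlignedSegment]] = {}
    for seg in sim.segments:
        by_read.setdefault(seg.read_id, []).append(seg)
    bases = "ACGT"
    with open(path, "w") as fh:
        for rid in sorted(by_read):
            segs = sorted(by_read[rid], key=lambda s: s.query_start)
            chunks = []
            for seg in segs:
                raw = reference[seg.contig][seg.start:seg.end]
                if seg.strand == "-":
                    raw = raw.translate(_COMPLEMENT)[::-1]
                chunks.append(raw)
            seq = "".join(chunks)
            noisy = []
            for ch in seq:
                r = rng.random()
                if r < config.del_rate:
                    continue
                elif r < config.del_rate + config.ins_rate:
                    noisy.append(bases[int(rng.integers(4))])
                    noisy.append(ch)
                elif r < config.del_rate + config.ins_rate + config.sub_rate:
                    noisy.append(bases[int(rng.integers(4))])
                else:
                    noisy.append(ch)
            read = "".join(noisy)
            fh.write(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _call_segments(call) -> list:
    if hasattr(call, "candidate"):
        return sorted(call.candidate.segments)
    if hasattr(call, "segments"):
        segs = call.segments
        if segs and len(segs[0]) == 4:
            return sorted((c, s, e) for c, s, e, _st in segs)
        return sorted(segs)
    return sorted(call)


def circles_match(call_segments, truth_segments, match_tol: int) -> bool:
    if len(call_segments) != len(truth_segments):
        return False
    for (c1, s1, e1), (c2, s2, e2) in zip(call_segments, truth_segments):
        if c1 != c2 or abs(s1 - s2) > match_tol or abs(e1 - e2) > match_tol:
            return False
    return True


def evaluate(calls: Sequence, truth: Sequence[TrueCircle],
             match_tol: int = 50) -> tuple[float, float, pd.DataFrame]:
    """Recall and precision of a call set against simulated truth.

    Matching is one-to-one (maximum bipartite matching); |C∩T| is the
    number of matched pairs.  Empty denominators report 1.0.
    """
    if match_tol < 0:
        raise ValueError("match_tol must be >= 0")
    call_segs = [_call_segments(c) for c in calls]
    truth_segs = [sorted(tc.plain_segments()) for tc in truth]
    compat = np.zeros((len(calls), len(truth)), dtype=bool)
    for i, cs in enumerate(call_segs):
        for j, ts in enumerate(truth_segs):
            compat[i, j] = circles_match(cs, ts, match_tol)
    pairs = []
    if compat.any():
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-compat.astype(float))
        for i, j in zip(rows, cols):
            if compat[i, j]:
                pairs.append((i, j))
    n_match = len(pairs)
    recall = n_match / len(truth) if truth else 1.0
    precision = n_match / len(calls) if calls else 1.0
    table = pd.DataFrame(
        [{
            "call_index": i,
            "call_id": getattr(calls[i], "circle_id", str(i)),
            "truth_id": truth[j].circle_id,
            "topology": truth[j].topology,
        } for i, j in pairs],
        columns=["call_index", "call_id", "truth_id", "topology"],
    )
    return recall, precision, table


# ---------------------------------------------------------------------------
# Coverage sweep
# ---------------------------------------------------------------------------

def run_detection(segments, detect_kwargs=None, min_prob: float = 0.95):
    """Detect + score + filter; thin wrapper used by the sweep."""
    from .pipeline import detect_circles
    from .circle_scoring import filter_calls

    result = detect_circles(segments, **(detect_kwargs or {}))
    return filter_calls(result.calls, min_prob=min_prob)


def coverage_sweep(
    reference,
    config: SimConfig,
    coverages: Sequence[float] = (5, 10, 15, 25),
    replicates: int = 3,
    match_tol: int = 50,
    detect_kwargs=None,
    min_prob: float = 0.95,
) -> pd.DataFrame:
    """Full-pipeline recall/precision across a coverage sweep.

    Each replicate simulates a library at the configured (full) circle
    coverage; lower coverages are produced by thinning circle reads from
    that same library, then the detection pipeline and the evaluator run on
    each thinned read set.
    """
    full = max(coverages)
    rows = []
    for rep in range(replicates):
        rep_config = replace(config, seed=config.seed + 1000 * (rep + 1),
                             circle_coverage=float(full))
        truth = simulate_truth(reference, rep_config)
        sim = simulate_alignments(reference, truth, rep_config)
        for cov in coverages:
            thinned = (sim if cov == full else
                       subsample_reads(sim, cov / full, rep_config.seed + int(cov)))
            calls = run_detection(thinned.segments, detect_kwargs, min_prob)
            recall, precision, _ = evaluate(calls, truth, match_tol)
            rows.append({
                "coverage": cov, "replicate": rep, "n_truth": len(truth),
                "n_calls": len(calls), "recall": recall, "precision": precision,
            })
    return pd.DataFrame(rows).sort_values(["coverage", "replicate"]).reset_index(drop=True)
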