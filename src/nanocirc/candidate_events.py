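"""Translate circle candidates to and from chains of VCF breakends.

Each junction of a candidate becomes a reciprocal pair of VCF 4.2 BND
records (bracket notation) sharing an EVENT id that groups all breakends of
one circle.  Deletion junctions are emitted as breakends too (not symbolic
``<DEL>``); the junction type travels in INFO.  This is the only place where
0-based internal coordinates become 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .circle_enumeration import CircleCandidate, Junction, ROLE_COVERAGE, ROLE_JUNCTION

VCF_HEADER_LINES = [
    '##fileformat=VCFv4.2',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of the mate breakend">',
    '##INFO=<ID=EVENT,Number=1,Type=String,Description="Circle candidate id grouping all breakends of one circle">',
    '##INFO=<ID=JTYPE,Number=1,Type=String,Description="Junction type: split or deletion">',
    '##INFO=<ID=NSPLIT,Number=1,Type=Integer,Description="Number of supporting split reads">',
    '##INFO=<ID=JIDX,Number=1,Type=Integer,Description="Junction index within the circle (traversal order)">',
    '##INFO=<ID=NJUNC,Number=1,Type=Integer,Description="Number of junctions in the circle">',
    '##INFO=<ID=CIRCLELEN,Number=1,Type=Integer,Description="Total covered length of the circle (bp)">',
    '##INFO=<ID=NSEG,Number=1,Type=Integer,Description="Number of covered segments in the circle">',
    '##INFO=<ID=PROB,Number=1,Type=Float,Description="Posterior probability that the circle is present">',
]

_ALT_RE = re.compile(
    r"^(?:(?P<base1>[ACGTNacgtn]+)(?P<br1>[\[\]])(?P<mate1>[^\[\]:]+):(?P<pos1>\d+)(?P=br1)"
    r"|(?P<br2>[\[\]])(?P<mate2>[^\[\]:]+):(?P<pos2>\d+)(?P=br2)(?P<base2>[ACGTNacgtn]+))$"
)


@dataclass
class BreakendRecord:
    contig: str
    pos: int  # 1-based
    record_id: str
    ref: str
    alt: str
    mate_id: str
    event: str
    info: dict


def _get_base(reference, contig: str, pos0: int) -> str:
    if reference is None:
        return "N"
    try:
        seq = reference[contig]
    except KeyError:
        return "N"
    if pos0 < 0 or pos0 >= len(seq):
        raise ValueError(f"junction position {contig}:{pos0} outside reference")
    base = str(seq[pos0 : pos0 + 1]).upper()
    return base if base in "ACGTN" else "N"


def _endpoint_vcf(endpoint) -> tuple[str, int, int]:
    """(contig, 1-based POS, 0-based index of the breakend base)."""
    contig, p, side = endpoint
    if side == "L":
        return contig, p, p - 1
    return contig, p + 1, p


def _alt_string(base: str, our_side: str, mate_contig: str, mate_pos1: int,
                mate_side: str) -> str:
    mate = f"{mate_contig}:{mate_pos1}"
    if our_side == "L":
        return f"{base}[{mate}[" if mate_side == "R" else f"{base}]{mate}]"
    return f"]{mate}]{base}" if mate_side == "L" else f"[{mate}[{base}"


def cycle_to_breakends(candidate: CircleCandidate, reference=None) -> list[BreakendRecord]:
    """One reciprocal breakend pair per junction of the candidate."""
    records = []
    njunc = len(candidate.junctions)
    for j, jn in enumerate(candidate.junctions):
        (c_a, pos_a, base_a_idx) = _endpoint_vcf(jn.donor)
        (c_b, pos_b, base_b_idx) = _endpoint_vcf(jn.acceptor)
        base_a = _get_base(reference, c_a, base_a_idx)
        base_b = _get_base(reference, c_b, base_b_idx)
        id_a = f"{candidate.circle_id}_j{j}_a"
        id_b = f"{candidate.circle_id}_j{j}_b"
        common = {
            "SVTYPE": "BND",
            "EVENT": candidate.circle_id,
            "JTYPE": jn.kind,
            "NSPLIT": jn.n_split_reads,
            "JIDX": j,
            "NJUNC": njunc,
            "CIRCLELEN": candidate.length,
            "NSEG": candidate.n_segments,
        }
        records.append(BreakendRecord(
            contig=c_a, pos=pos_a, record_id=id_a, ref=base_a,
            alt=_alt_string(base_a, jn.donor[2], c_b, pos_b, jn.acceptor[2]),
            mate_id=id_b, event=candidate.circle_id, info=dict(common),
        ))
        records.append(BreakendRecord(
            contig=c_b, pos=pos_b, record_id=id_b, ref=base_b,
            alt=_alt_string(base_b, jn.acceptor[2], c_a, pos_a, jn.donor[2]),
            mate_id=id_a, event=candidate.circle_id, info=dict(common),
        ))
    return sorted(records, key=lambda r: (r.contig, r.pos, r.record_id))


def write_vcf(records, contigs: dict, path: str, posteriors: dict | None = None) -> None:
    """Write BND records as VCF 4.2; ``contigs`` maps name -> length.

    ``posteriors`` (event id -> probability) adds a PROB INFO field.
    """
    with open(path, "w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.contig, r.pos, r.record_id)):
            info = dict(rec.info)
            info["MATEID"] = rec.mate_id
            if posteriors is not None and rec.event in posteriors:
                info["PROB"] = f"{posteriors[rec.event]:.6g}"
            info_str = ";".join(f"{k}={v}" for k, v in info.items())
            fh.write(
                f"{rec.contig}\t{rec.pos}\t{rec.record_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t{info_str}\n"
            )


def _parse_alt(alt: str, record_context: str) -> tuple[str, str, int, str]:
    """Return (our_side, mate_contig, mate_pos1, mate_side)."""
    m = _ALT_RE.match(alt)
    if not m:
        raise ValueError(f"malformed breakend ALT {alt!r} in record {record_context}")
    if m.group("base1") is not None:
        our_side = "L"
        bracket, contig, pos = m.group("br1"), m.group("mate1"), int(m.group("pos1"))
        mate_side = "R" if bracket == "[" else "L"
    else:
        our_side = "R"
        bracket, contig, pos = m.group("br2"), m.group("mate2"), int(m.group("pos2"))
        mate_side = "L" if bracket == "]" else "R"
    return our_side, contig, pos, mate_side


def _endpoint_from_vcf(contig: str, pos1: int, side: str) -> tuple:
    p = pos1 if side == "L" else pos1 - 1
    return (contig, p, side)


def read_vcf(path: str):
    """Read the module's own BND dialect back into circle candidates.

    Returns ``(candidates, posteriors)`` where ``posteriors`` maps circle id
    to the PROB INFO value when present.
    """
    import pysam

    events: dict[str, dict[int, dict]] = {}
    posteriors: dict[str, float] = {}
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = dict(rec.info)
            event = info["EVENT"]
            jidx = int(info["JIDX"])
            ctx = f"{rec.chrom}:{rec.pos} {rec.id}"
            side, mate_contig, mate_pos, mate_side = _parse_alt(rec.alts[0], ctx)
            jn = events.setdefault(event, {}).setdefault(
                jidx,
                {"kind": info["JTYPE"], "nsplit": int(info["NSPLIT"]),
                 "njunc": int(info["NJUNC"])},
            )
            role = rec.id.rsplit("_", 1)[-1]
            jn[role] = _endpoint_from_vcf(rec.chrom, rec.pos, side)
            if "PROB" in info:
                posteriors[event] = float(info["PROB"])

    candidates = []
    for event in sorted(events):
        jdict = events[event]
        njunc = next(iter(jdict.values()))["njunc"]
        if sorted(jdict) != list(range(njunc)):
            raise ValueError(f"event {event}: missing junction records")
        junctions = []
        for j in range(njunc):
            jn = jdict[j]
            if "a" not in jn or "b" not in jn:
                raise ValueError(f"event {event} junction {j}: unpaired breakends")
            junctions.append(Junction(
                donor=jn["a"], acceptor=jn["b"], kind=jn["kind"],
                n_split_reads=jn["nsplit"],
            ))
        segments = []
        nodes, roles, types = [], [], []
        for j, jn in enumerate(junctions):
            nxt = junctions[(j + 1) % njunc]
            c1, p1, _ = jn.acceptor
            c2, p2, _ = nxt.donor
            if c1 != c2:
                raise ValueError(
                    f"event {event}: segment between junctions {j} and "
                    f"{(j + 1) % njunc} spans contigs {c1}/{c2}"
                )
            segments.append((c1, min(p1, p2), max(p1, p2)))
            nodes.extend([jn.donor[:2], jn.acceptor[:2]])
            roles.extend([ROLE_JUNCTION, ROLE_COVERAGE])
            types.extend([jn.kind, "coverage"])
        candidates.append(CircleCandidate(
            nodes=tuple(nodes), roles=tuple(roles), edge_types=tuple(types),
            segments=segments, junctions=junctions, circle_id=event,
        ))
    return candidates, posteriors
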