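"""Final annotated outputs: gene overlap, junction sequences, TSV report.

Gene annotations come from BED (0-based half-open) or GFF3 (1-based
inclusive, converted on read); overlap queries run against per-contig
interval trees.  Junction sequences are the sequence a junction-spanning
amplicon would have — flank bases upstream of the donor breakend followed by
flank bases downstream of the acceptor, in circle orientation — intended to
be pasted into a primer-design tool for wet-lab validation of a predicted
circle (default flank 2 kb, the usual primer-design window).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .circle_scoring import CircleCall

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_bed(path: str) -> dict[str, IntervalTree]:
    """BED intervals (0-based half-open); column 4 is the gene name."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"contig": str, "name": str},
    )
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.contig, IntervalTree()).addi(
                int(row.start), int(row.end), str(row.name)
            )
    return trees


def read_gff3(path: str, feature_type: str = "gene") -> dict[str, IntervalTree]:
    """GFF3 gene intervals, converted from 1-based inclusive to half-open."""
    cols = ["contig", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"contig": str})
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        if row.type != feature_type:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "?")
        start0, end0 = int(row.start) - 1, int(row.end)
        if end0 > start0:
            trees.setdefault(row.contig, IntervalTree()).addi(start0, end0, name)
    return trees


def read_gene_intervals(path: str) -> dict[str, IntervalTree]:
    if str(path).lower().endswith((".gff", ".gff3")):
        return read_gff3(path)
    return read_bed(path)


def annotate_genes(call: CircleCall, gene_trees: dict[str, IntervalTree]) -> list[str]:
    """Sorted unique genes whose interval overlaps any circle segment."""
    unknown = sorted(
        {c for c, _s, _e in call.candidate.segments if c not in gene_trees}
    )
    if unknown:
        raise ValueError(
            "contigs absent from the gene annotation: " + ", ".join(unknown)
        )
    genes: set[str] = set()
    for contig, start, end in call.candidate.segments:
        for iv in gene_trees[contig].overlap(start, end):
            genes.add(iv.data)
    return sorted(genes)


# ---------------------------------------------------------------------------
# Junction sequence for primer design
# ---------------------------------------------------------------------------

def _flank_sequence(reference, endpoint, segment, flank: int, upstream: bool) -> str:
    """Bases adjacent to a breakend, read in circle orientation.

    ``upstream=True`` returns the bases entering the breakend (donor side),
    ``False`` the bases leaving it (acceptor side).  Flanks are truncated to
    the breakend's own segment.
    """
    contig, pos, side = endpoint
    seq = reference[contig]
    if segment is not None:
        _seg_c, seg_s, seg_e = segment
        span = seg_e - seg_s
        if flank > span:
            warnings.warn(
                f"flank {flank} exceeds segment length {span} at "
                f"{contig}:{pos}; truncating"
            )
            flank = span
    # the side fixes which reference bases adjoin the breakend; whether the
    # circle enters (donor) or leaves (acceptor) fixes their orientation
    if side == "L":
        lo = max(pos - flank, 0)
        chunk = str(seq[lo:pos])
        return chunk if upstream else _revcomp(chunk)
    hi = min(pos + flank, len(seq))
    chunk = str(seq[pos:hi])
    return _revcomp(chunk) if upstream else chunk


def junction_sequence(call: CircleCall, reference, flank: int = 2000) -> list[str]:
    """Per junction: donor-side flank + acceptor-side flank, circle order."""
    seqs = []
    segments = call.candidate.segments
    k = len(call.candidate.junctions)
    for j, jn in enumerate(call.candidate.junctions):
        donor_segment = segments[(j - 1) % len(segments)] if segments else None
        acceptor_segment = segments[j % len(segments)] if segments else None
        up = _flank_sequence(reference, jn.donor, donor_segment, flank, upstream=True)
        down = _flank_sequence(reference, jn.acceptor, acceptor_segment, flank,
                               upstream=False)
        seqs.append(up + down)
    return seqs


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "circle_id", "n_segments", "n_junctions", "length", "posterior",
    "genes", "segments", "junctions", "support", "cover",
]


def _fmt_segments(segs) -> str:
    # 1-based inclusive display coordinates
    return ";".join(f"{c}:{s + 1}-{e}" for c, s, e in segs)


def _fmt_endpoint(ep) -> str:
    contig, pos, side = ep
    # 1-based position of the breakend base: the last covered base left of
    # the boundary (side L) or the first one right of it (side R)
    return f"{contig}:{pos if side == 'L' else pos + 1}{side}"


def _fmt_junctions(junctions) -> str:
    return ";".join(
        f"{_fmt_endpoint(jn.donor)}-{_fmt_endpoint(jn.acceptor)}:{jn.kind}"
        for jn in junctions
    )


def report_frame(calls: Sequence[CircleCall]) -> pd.DataFrame:
    rows = []
    ordered = sorted(calls, key=lambda c: (-c.posterior, -c.length, c.circle_id))
    for call in ordered:
        rows.append({
            "circle_id": call.circle_id,
            "n_segments": call.candidate.n_segments,
            "n_junctions": len(call.candidate.junctions),
            "length": call.length,
            "posterior": call.posterior,
            "genes": ",".join(call.genes),
            "segments": _fmt_segments(call.candidate.segments),
            "junctions": _fmt_junctions(call.candidate.junctions),
            "support": ",".join(f"{s.n_support:.4g}" for s in call.supports),
            "cover": ",".join(f"{s.n_cover:.4g}" for s in call.supports),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(calls: Sequence[CircleCall], path: str) -> pd.DataFrame:
    """One row per call, deterministic order (posterior desc, length desc)."""
    df = report_frame(calls)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_report(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"genes": str, "segments": str, "junctions": str,
               "support": str, "cover": str},
        keep_default_na=False,
    )


def plot_qc(qc_table: pd.DataFrame, path: str) -> None:
    """Render the per-bin QC table; cosmetic companion to the data table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    x = qc_table["bin_start"]
    for col, color in [
        ("matches", "tab:blue"), ("insertions", "tab:cyan"),
        ("deletions", "tab:green"), ("split_at_breakpoints", "tab:red"),
        ("split_read_in", "tab:orange"), ("split_read_out", "m"),
    ]:
        ax.plot(x, qc_table[col], label=col, color=color)
    ax.set_xlabel("circle coordinate (bp)")
    ax.set_ylabel("bases per bin")
    ax2 = ax.twinx()
    ax2.plot(x, qc_table["depth"], color="grey", alpha=0.6, label="depth")
    ax2.set_ylabel("read depth")
    ax.legend(loc="upper center", fontsize="small", ncol=3)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
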