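"""Posterior probability that a circle candidate is present in the sample.

A deliberately simple Bayesian model over junction support counts.  For
junction j let s_j be the (MAPQ-weighted) number of reads whose split
endpoints land on both breakends with compatible orientation, and c_j the
weighted number of reads that overlap a breakend locus without supporting
the junction.  Under the circle hypothesis a junction-overlapping read
supports the junction with probability rho (high in circle-enriched
libraries, where junction-crossing reads dominate at junction loci); under
the null it does so with the artifact rate epsilon.  The binomial
coefficient cancels in the likelihood ratio, so per junction

    log BF_j = s_j * log(rho / epsilon) + c_j * log((1 - rho) / (1 - epsilon))

junctions combine by independence, and with prior pi the posterior is
``expit(logit(pi) + sum_j log BF_j)``.  A junction with no nearby reads is
uninformative (BF = 1).  MAPQ enters by capping each read's weight at
``1 - 10^(-MAPQ/10)``, a crude stand-in for mapping uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy.special import expit, logit

from .alignment_evidence import AlignedSegment, SplitLink
from .circle_enumeration import CircleCandidate


@dataclass
class ScoringModel:
    """Priors of the junction-support model.

    prior: probability that a candidate is real before seeing support.
    error_rate: chance a non-circle read presents as junction-supporting
        (mapping/chimera artifacts).
    support_fraction: expected fraction of junction-overlapping reads that
        support a true junction in a circle-enriched library.
    """

    prior: float = 0.5
    error_rate: float = 0.01
    support_fraction: float = 0.9

    def __post_init__(self) -> None:
        for name in ("prior", "error_rate", "support_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.error_rate >= self.support_fraction:
            raise ValueError("error_rate must be below support_fraction")


@dataclass
class JunctionSupport:
    junction_index: int
    n_support: float  # MAPQ-weighted
    n_cover: float
    support_reads: tuple = ()
    cover_reads: tuple = ()


@dataclass
class CircleCall:
    """A scored candidate, later enriched with annotations by the reporter."""

    candidate: CircleCandidate
    posterior: float
    supports: list
    genes: list = field(default_factory=list)
    junction_sequences: list = field(default_factory=list)

    @property
    def circle_id(self) -> str:
        return self.candidate.circle_id

    @property
    def length(self) -> int:
        return self.candidate.length


def mapq_weight(mapq: int) -> float:
    """Contribution weight of a read: 1 - 10^(-MAPQ/10)."""
    return 1.0 - 10.0 ** (-mapq / 10.0)


def _matches(endpoint, target, tolerance) -> bool:
    (c1, p1, s1), (c2, p2, s2) = endpoint, target
    return c1 == c2 and abs(p1 - p2) <= tolerance and s1 == s2


def collect_junction_support(
    candidate: CircleCandidate,
    segments: Sequence[AlignedSegment],
    links: Sequence[SplitLink],
    tolerance: int = 10,
    mapq_min: int = 0,
) -> list[JunctionSupport]:
    """Per-junction support/coverage counts from the evidence layer.

    A link supports a junction when its two endpoints fall within
    ``tolerance`` of the two breakends with matching orientation (in either
    assignment — forward- and reverse-strand reads describe the same
    junction with swapped endpoint order).  A read covers a junction without
    supporting it when one of its segments spans a breakend locus by more
    than ``tolerance`` on both sides.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    out = []
    for j, jn in enumerate(candidate.junctions):
        support_reads: dict[str, float] = {}
        for lk in links:
            if lk.mapq_min < mapq_min:
                continue
            ok = (
                (_matches(lk.end_a, jn.donor, tolerance)
                 and _matches(lk.end_b, jn.acceptor, tolerance))
                or (_matches(lk.end_a, jn.acceptor, tolerance)
                    and _matches(lk.end_b, jn.donor, tolerance))
            )
            if ok:
                w = mapq_weight(lk.mapq_min)
                support_reads[lk.read_id] = max(support_reads.get(lk.read_id, 0.0), w)
        cover_reads: dict[str, float] = {}
        loci = [jn.donor[:2], jn.acceptor[:2]]
        for seg in segments:
            if seg.mapq < mapq_min or seg.read_id in support_reads:
                continue
            for contig, pos in loci:
                if (seg.contig == contig
                        and seg.start <= pos - tolerance - 1
                        and seg.end >= pos + tolerance + 1):
                    w = mapq_weight(seg.mapq)
                    cover_reads[seg.read_id] = max(cover_reads.get(seg.read_id, 0.0), w)
                    break
        out.append(JunctionSupport(
            junction_index=j,
            n_support=sum(support_reads.values()),
            n_cover=sum(cover_reads.values()),
            support_reads=tuple(sorted(support_reads)),
            cover_reads=tuple(sorted(cover_reads)),
        ))
    return out


def score_circle(
    candidate: CircleCandidate,
    supports: Sequence[JunctionSupport],
    model: ScoringModel,
) -> float:
    """Posterior probability in [0, 1] that the candidate is present.

    Deterministic in the counts and model; a junction with zero reads
    contributes a likelihood ratio of 1 (no evidence either way).
    """
    log_bf = 0.0
    for sup in supports:
        if sup.n_support + sup.n_cover <= 0:
            continue
        log_bf += sup.n_support * math.log(model.support_fraction / model.error_rate)
        log_bf += sup.n_cover * math.log(
            (1.0 - model.support_fraction) / (1.0 - model.error_rate)
        )
    return float(expit(logit(model.prior) + log_bf))


def score_candidates(
    candidates: Sequence[CircleCandidate],
    segments: Sequence[AlignedSegment],
    links: Sequence[SplitLink],
    model: ScoringModel | None = None,
    tolerance: int = 10,
    mapq_min: int = 0,
) -> list[CircleCall]:
    """Score every candidate; convenience wrapper used by the pipeline."""
    model = model or ScoringModel()
    calls = []
    for cand in candidates:
        supports = collect_junction_support(
            cand, segments, links, tolerance=tolerance, mapq_min=mapq_min
        )
        calls.append(CircleCall(
            candidate=cand,
            posterior=score_circle(cand, supports, model),
            supports=supports,
        ))
    return calls


def filter_calls(calls: Sequence[CircleCall], min_prob: float = 0.95) -> list[CircleCall]:
    """Keep calls with posterior >= min_prob, sorted by posterior then
    circle length, both descending."""
    if not 0.0 <= min_prob <= 1.0:
        raise ValueError("min_prob must lie in [0, 1]")
    kept = [c for c in calls if c.posterior >= min_prob]
    return sorted(kept, key=lambda c: (-c.posterior, -c.length, c.circle_id))
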