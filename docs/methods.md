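# Methods

`nanocirc` detects extrachromosomal circular DNA (eccDNA/ecDNA) from mapped
long reads of circle-enriched libraries.  In such libraries (exonuclease
digestion of linear DNA followed by rolling-circle amplification), read
depth is near zero everywhere except over circular templates, and reads
crossing a circle junction map as split alignments.  The caller turns these
two signals into a directed breakpoint graph, enumerates plausible circular
paths through its strongly connected components, and scores each candidate
with a posterior probability of being present.

## Evidence extraction

Depth is estimated with a counter sweep: each mapped segment (primary or
supplementary; secondary alignments are ignored) increments a counter at
its reference start and decrements one at its reference end, and the
cumulative sum gives the depth step function.  Depth is counted over the
full reference span of each segment — clipped bases are excluded, but
deletions inside an alignment count as covered.  By default no MAPQ filter
is applied when building the graph (`mapq_min = 0`); when a threshold is
set it always applies to split links, and optionally
(`depth_mapq_filter`) to the depth estimate as well.

Split junctions are taken from standard alignment features only (the
supplementary flag and SA tag dialect), so any mapper that emits them is
supported.  The aligned segments of a read are ordered by query coordinate;
each adjacent pair yields one junction link whose endpoints record the
reference boundary and the side of it the segment occupies.  A read with k
aligned segments yields exactly k − 1 links.  Forward- and reverse-strand
reads crossing the same junction produce the same unordered endpoint set,
which is how links are merged.

## Depth segmentation

Real enriched libraries carry residual linear background (about 1x here),
so the literal rules — "a node wherever depth changes", "a deletion
wherever no read covers" — degenerate: every read boundary becomes a node,
stray background reads bridge genuine coverage holes, and at moderate
coverage sampling alone pokes holes into genuinely covered segments.  The
graph is therefore built on a smoothed segmentation of each contig into
enriched and uncovered runs:

1. **Boundaries.**  Candidate run boundaries are placed where the depth
   profile crosses `zero_depth` (default 3) pointwise, and wherever depth
   steps concentrated within `merge_tol` (default 10 bp) sum to at least
   `min_step` (default 4).  The step rule is the workhorse: a true
   breakpoint collects the starts or ends of many reads at one locus (on
   the order of the circle coverage), whereas background and sampling noise
   move depth by one read at a time.  Coincident same-sign steps of 4+
   reads within 10 bp essentially never arise by chance at the coverages
   involved (read boundaries arrive at ~2c/L per bp; four in a 10 bp window
   at c = 26x, L = 8 kb has probability below 1e-6 per window).
2. **Classification.**  A run is enriched when its mean depth reaches
   `min_island_depth` (default 5): stacks of 5 independent background reads
   at 1x are a ~3e-4 pointwise event, while any useful circle coverage is
   well above 5.  Weaker runs are attributed to background.
3. **Gap absorption.**  An uncovered run of length g flanked by enriched
   coverage c is kept as a real coverage hole only if sampling dropout is
   implausible: `c * g / read_length > gap_factor` (default 4), i.e. the
   flanking library would have been expected to place more than 4 reads
   across the hole (a chance of roughly e^-4 of leaving it empty).  The
   typical read length is estimated from the mean aligned-segment span.

`GraphParams.strict()` switches all three rules off and restores the
literal semantics (any read covers; any zero-coverage interval is a
deletion); the test-suite checks of the literal textbook examples run in
this mode.

## Breakpoint graph

Nodes are the boundaries of enriched runs plus all split-link endpoints,
clustered per contig to the median of each group of positions within
`merge_tol`.  Edges between neighbouring nodes on a contig are typed by the
interval they span: **coverage** (enriched, mean depth ≥ θ, default θ = 1),
**deletion** (uncovered; permitted inside circles because library
preparation can drop part of a circle), or none (positive but
sub-threshold mean).  Deletion edges longer than `max_deletion_length`
(default 10 kb, the library fragment scale) are suppressed — without this
cap any two enriched regions of a contig become neighbours and unrelated
circles chain into chimeric candidates.  Neighbour edges are inserted in
both directions so a circle can be traversed in either rotation.

Split links merged on their unordered endpoint set become **split** edges
in both directions; a node pair that is both coverage- and split-connected
carries a single **coverage + split** edge.  Nodes with no incident
coverage-type edge cannot lie on any plausible path and are pruned
(iterated to a fixpoint; the operation is idempotent).

## Circle enumeration

A candidate is a simple cycle whose edges alternate between the coverage
role (coverage / coverage+split) and the junction role (split / deletion /
coverage+split) — every second edge must be a coverage edge, otherwise no
reference sequence would be covered between junctions.  The simplest
candidate is two nodes joined by a pair of coverage+split edges: a plain
one-contig circle.  Candidates are required to contain at least one
split-backed junction (`require_split`); cycles explained by coverage and
deletion edges alone are discarded.

Cycles can be exponentially many, so enumeration is a Johnson-style rooted
DFS per strongly connected component with the alternation constraint
applied during the search, capped by `max_cycles` (10 000) and `max_edges`
(64); hitting a cap flags the result as truncated instead of raising.
Candidates are canonicalized — rotation fixed at the lexicographically
smallest node, a cycle and its reverse traversal mapped to the same form —
and deduplicated on that key.  Because cycles must be simple, circles that
traverse the same locus twice (internal duplications) are out of reach.

## Breakend representation

Each junction becomes a reciprocal pair of VCF 4.2 BND records (bracket
notation chosen from the two endpoint sides), grouped per circle by the
EVENT field; deletion junctions are emitted as breakends too, with the
junction type in INFO.  All internal coordinates are 0-based half-open;
conversion to 1-based happens only at the VCF/report boundary.  The
module's own dialect round-trips losslessly; foreign SV VCFs are not
guaranteed.

## Posterior scoring

The upstream workflow this package reimplements delegates statistical
calling to an external probabilistic caller with pair-HMM realignment; that
model is out of scope here and replaced by a documented simplified one.
For junction j, let s_j be the (MAPQ-weighted) count of reads whose split
endpoints fall within `tolerance` (default 10 bp) of both breakends with
compatible orientation, and c_j the weighted count of reads spanning a
breakend locus without supporting the junction.  Under the circle
hypothesis a junction-overlapping read supports it with probability ρ
(`support_fraction`, default 0.9 — junction-crossing reads dominate at
junction loci in enriched libraries); under the null with the artifact
rate ε (`error_rate`, default 0.01).  The binomial coefficients cancel in
the likelihood ratio, so

    log BF_j = s_j log(ρ/ε) + c_j log((1−ρ)/(1−ε))

junctions combine by independence, and with prior π (default 0.5)

    posterior = expit(logit(π) + Σ_j log BF_j).

A junction with no nearby reads is uninformative (BF = 1), so deletion
junctions — which by construction have no read evidence — neither help nor
hurt.  Reads contribute weight 1 − 10^(−MAPQ/10), a crude stand-in for the
mapping uncertainty the original realignment model handles properly.  The
posterior is monotone in s_j (up) and c_j (down) and is reported at full
precision, rounded only for display.  Calls are filtered at `min_prob`
(default 0.95) and sorted by posterior, then length, descending.

## Annotation and report

Gene annotations come from BED (0-based half-open) or GFF3 (1-based
inclusive, converted on read); a call is annotated with every gene whose
interval overlaps any circle segment.  For wet-lab validation, each
junction gets the sequence a junction-spanning amplicon would have: flank
bases entering the donor breakend followed by flank bases leaving the
acceptor, in circle orientation, truncated to the flanking segments
(default flank 2 kb, the usual primer-design window).  The TSV report has
one row per call (id, segments, junctions, length, posterior, genes,
support counts) in deterministic order and parses back losslessly.  QC
tables bin each circle and count match/insertion/deletion bases plus split
reads classified as at-breakpoint (within ± `window`, default 3 bp),
within-circle, or linking out; plots are a cosmetic rendering of these
tables.

## Simulator

The generator emulates the evaluation conditions of the detection study:
circles at 25x coverage, linear whole-genome background at 1x, log-normal
read lengths (median 8 kb, σ = 0.6 in log space, minimum 300 bp, capped at
the circle length), per-base error rates of 5% substitutions / 3%
insertions / 4% deletions realized in alignment CIGARs, and optional
junction-endpoint jitter.  Three topologies are produced: a plain
one-contig circle, a chimeric circle joining two loci, and a circle with an
internal uncovered stretch of 3–8 kb whose reads simply stop at the gap
(no split evidence across it), mirroring library-prep dropout.  Circles are
placed without overlap and at least 25 kb apart, akin to drawing template
regions scattered across a genome.  Reads are emitted directly as sorted
alignment records with supplementary/SA annotations (no external mapper
needed); a FASTQ mode regenerates read sequences with parametric errors for
end-to-end runs through a real mapper.

What the generator does **not** emulate: trained nanopore error profiles
(errors are i.i.d. parametric), chimeric mapping artifacts, repeats and
mappability structure of a real genome, strand or rotation biases of
rolling-circle amplification, and copy-number heterogeneity between
circles.  Passing the simulation study therefore shows the graph machinery
and scoring behave correctly under idealized mapping, not that mapper
artifacts on real genomes are handled.

Evaluation uses recall = |C∩T| / |T| and precision = |C∩T| / |C| with
one-to-one maximum matching; a call matches a true circle iff it has the
same segment count and every breakpoint lies within `match_tol` (default
50 bp); empty denominators report 1.  Coverage sweeps simulate once at the
highest coverage and thin circle-derived reads per read, keeping the
background constant.

## Problem sizes used by the test suite

The simulation study runs at desk scale: 20 circles of 2–50 kb, mixed
topologies, on a 5 Mb two-contig synthetic genome at 25x circle / 1x
background coverage (about 2 000 reads), where the caller reaches
recall = precision = 1.0 with zero junction jitter and recall ≥ 0.9,
precision ≥ 0.95 with 5 bp jitter; the 5/10/15/25x sweep uses three
replicates of the same design.  With the single-interval design (the
analogue of simulating circles from sampled gene regions), precision
stays at 1.0 across the whole sweep while recall rises from ~0.7 at 5x to
1.0 at 15x and above.

## Known limitations

* Circles revisiting a locus (duplications within a circle) are invisible
  to simple-cycle enumeration.
* Strand/orientation of split edges is recorded and carried into breakends,
  but the plausibility rule ignores it; inversion-containing circles are
  enumerated without orientation consistency checks.
* The scoring model is a stand-in: no realignment, no FDR control across
  candidates, no tumor/normal scenarios.
* Overlapping candidates sharing junctions (e.g. from homologous loci) are
  all reported; no copy-number-aware decomposition into stoichiometric
  circles is attempted.
* Detection sensitivity has a floor at `min_island_depth` (5x) enriched
  coverage under the default segmentation.
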