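# Methods

This note records the model behind `overlapsv`, the parameter choices, the
numerical conventions, and what the simulation benchmarks do and do not
demonstrate.

## Library model and fragment reconstruction

The caller targets short-insert libraries sequenced as paired 150 bp reads
whose mates overlap centrally: fragments no longer than
2·*L* − *m*<sub>min</sub> = 287 bp.  Read 2 is the reverse complement of the
fragment end, so sliding reverse-complemented read 2 along read 1 and
scoring the overlap identifies the fragment.  The overlap score at offset
*i* is the fraction of matching bases over the overlap (denominator
*L* − *i*), so a perfect overlap of any length scores exactly 1 while
random sequence scores ≈ 0.25; on mixed-length libraries the maximal score
per pair is bimodal with modes near 0 and 1.  Only score-1 pairs are
reconstructed.  *m*<sub>min</sub> = 13 bounds the chance of a spurious
perfect overlap at ~*L*·4<sup>−13</sup> per pair.  N bases never match.
When several offsets reach score 1 (possible for periodic reads) the
smallest offset — the longest overlap, hence the shortest fragment — is
taken and the pair flagged ambiguous.  Base qualities are carried through
but never used: the filter is purely sequence-based.

## Seeds and exact classification

Reads that cross an SV junction do not align end-to-end, so only the 5′
prefix of each mate is placed: seeds of *k* = 30 bases, at most one
mismatch, and a placement is used only when it is unique genome-wide.
*k* = 30 is large enough for uniqueness on non-repetitive sequence (the
`alignability` subcommand measures this per reference) and small enough to
sit inside the unbroken flank of almost every informative fragment.

With read 1 forward at `pos1` and read 2's seed reverse at `pos2`, the
outer span is `D = pos2 + k − pos1` (mirror case symmetric).  Concordant
means: same chromosome, inward opposite orientation, and `D == l_f`
*exactly* — possible only because `l_f` is known per fragment.  There is no
insert-size distribution or threshold anywhere in the classification.

The bundled seed aligner is an exhaustive pigeonhole index (any ≤1-mismatch
placement leaves one seed half exact; both halves are looked up and every
candidate verified).  It is complete but intended for references up to
~10 Mb; for larger genomes, external-aligner SAM output can be ingested,
with multi-mapping or MAPQ-0 records making a pair unusable.

## Minimal reference and single-event alignment

For a discordant pair, two windows of length `l_f` are grown from the seed
placements — the left window in read 1's 3′ direction, the right window
backwards from read 2's seed — reverse-complemented as needed so that the
joined sequence is collinear with the fragment.  If the seeds are placed
correctly the fragment is contained in this 2·`l_f` construct, whatever the
SV.

The fragment is aligned under match +5, mismatch −4, gap open 10, gap
extension 0.5 (a 1 bp gap costs 10.5, cheaper than two mismatches).  Two
properties of the design are worth recording:

* **Anchoring.**  The seed placements pin fragment base 0 to the first
  column of the left window and the last base to the last column of the
  right window.  Alignments are therefore constrained to
  `anchored gapless block + one affine gap + anchored gapless block`.
  A free-floating formulation was tried first and rejected: with extension
  0.5, fragments carrying ≳60 bp of novel insertion admit higher-scoring
  alignments that chain coincidental partial matches across the 2·`l_f`
  reference, destroying the breakpoint.  One event per fragment is also the
  method's declared scope — nested or complex SVs within a single fragment
  are not handled.
* **Two placement families.**  Under the anchors, valid placements are
  exactly (i) *junction* splits — the gap consumes reference columns only;
  both breakpoints move jointly when the split slides through repeated
  sequence — and (ii) *insertion* splits, whose fragment-gap length g\* is
  fixed by the window geometry so that the two gap-adjacent columns map to
  the same reference coordinate.  Both families carry the same gap cost
  baseline; an insertion whose content duplicates the adjacent flank is
  sequence-identical to a back-jump junction of span g\* (which re-aligns
  g\* reference bases twice), so within that `match·g*` equivalence margin
  the insertion description wins.  This reproduces the intended semantics:
  an extra A in a homopolymer of n As is an insertion with n+1 equivalent
  placements (central one reported), not a 1 bp duplication junction, and
  direct-repeat insertions are insertions.

Breakpoints are junction coordinates (0-based position of the base to the
right).  Each breakpoint records the *side* from which the fragment
approaches it; the ordered side pair of a fragment determines the edge type
(a: left/left, b: left/right, c: right/left, d: right/right).  Alignments
with identity below 0.95 outside the gap, gapless alignments, and windowless
pairs (seed at a contig edge) contribute no evidence.

An insertion of ≥ 30 bp whose sequence occurs exactly once in the reference
(either strand) is re-interpreted as an insertional duplication pinned by a
single fragment: the evidence is rewritten as the two duplication junction
edges.

## Discordant graph, equivalent placements, prototypes

Sequencing orientation is arbitrary, so edges are canonicalized
(a and d symmetric in their endpoints; c(u,v) ≡ b(v,u); b keeps its
direction, which distinguishes deletions, u < v, from tandem-duplication
junctions, u > v).  Identical canonical edges merge with summed weights.

Repeat context makes placements ambiguous, and different fragments of one
event must nevertheless agree on coordinates or the component fragments.
Fragments with identical canonical placement sets form a *group*; groups
with overlapping candidate coordinates form a *cluster* (the evidence of one
SV, given the simulator's non-interacting spacing).  Within a cluster one
placement per group is chosen to minimize the number of distinct
breakpoints — the assignment with maximal merging, i.e. the highest-order
connected component; the true coordinates are co-optimal for every fragment
so a fully merged assignment always exists.  Among equivalent optima the
centrally placed one (lower median) is reported.  Clusters with more than
4096 combinations (never observed on spaced simulations) fall back to the
per-group central placement.

Donor-adjacency edges (type e) join the boundaries of a duplicated donor.
They are derived at graph construction: within a component, any
same-chromosome vertex pair not already joined by a sequence-level edge and
within `e_max_span` (default 1000 bp, the maximal donor size) receives an
e-edge.  A translocation carries the donor-excision junction b(dstart,dend),
so its boundaries are already joined and no e-edge appears — exactly what
separates the translocation prototypes from the insertional-duplication
prototypes.

The 16 prototypes are matched by brute-force vertex bijection (arity ≤ 3)
requiring typed-edge equivalence in both directions plus coordinate
constraints (donor start < end, up/downstream ordering, chromosome
identity).  Prototypes are tried in specificity order — translocations,
insertional duplications, inversion, tandem duplication, deletion,
insertion — and the first match wins; unmatched components are reported as
residuals, not typed.  One genuine degeneracy exists: moving donor [s,e)
upstream to p produces the same sample sequence as moving [p,s) downstream
past e, so intrachromosomal non-inverted translocations up- and downstream
share one signature; the caller reports the upstream description and the
evaluator treats the two as equivalent.

Calls carry the minimum sequence-level edge weight of their component; the
minimum required weight (MRW) filter drops weakly supported calls.

## Coverage and zygosity

Concordant pairs project their `l_f` span, discordant pairs both anchored
windows.  Zygosity uses r = concordant coverage at the breakpoints (taking
the junction-adjacent minimum, since e.g. a deletion's end coordinate is the
first retained base) over the median background within ±1 kb:
r ≤ 0.1 → homozygous, 0.3–0.7 → heterozygous, anything else — including
calls whose breakpoints keep full wildtype coverage, the technical-error
class — low confidence.  The cutoffs are calibration choices placed
symmetrically around the 0% and 50% expectations; they are configurable.

## Simulator

`generate_reference` draws i.i.d. sequence at a configurable GC content
(optionally stamped with identical repeat cassettes for alignability stress
tests).  `plant_svs` applies any mix of the 16 types to one or two
haplotypes, with events separated by at least twice the maximal fragment
length so signatures cannot interact (nested SVs are out of the caller's
scope by design) and duplication donors at least 2 kb from their insertion
sites.  Default size ranges follow the experimentally validated events of
the study system this class of libraries was developed on: insertions
22–133 bp, deletions 22–245 bp, tandem duplications 293–889 bp, inversions
and duplication donors 300–900 bp.  Indels are planted in locally
unambiguous context (no single-base junction microhomology) so that the
planted coordinate is the unique optimum and single-base exactness is a
well-defined claim; roughly a quarter of unconstrained random junctions
would otherwise have shift-equivalent placements with no single "true"
coordinate.  `simulate_read_pairs` draws uniform fragment starts, fragment
lengths either uniform on [200, 287] or truncated normal (untruncated mode
reproduces the bimodal overlap-score distribution), and applies uniform
substitution errors.  Truth sets record every breakpoint in reference
coordinates and serialize to JSON/BED.

The generator does **not** emulate the repeat and transposon landscape of
real genomes (unless asked), indel sequencing errors, quality profiles, or
PCR duplicates.  Consequently the benchmarks bound the *algorithmic* error
of the caller: on uniform random references every junction flank yields
unique seeds, and measured recalls (≈1.0 at coverage 20 for deletions and
intrachromosomal translocations alike) sit at the top of the bands observed
on real genomes, where per-junction seed losses of a few percent compound —
one junction for a deletion, three for a translocation.  Scaled benchmark
sizes used by the test-suite and the acceptance script (1–2 Mb references,
100–200 events per type, coverage 20) were chosen to keep binomial noise on
recall below about one percentage point.

## Evaluation

A planted event is recalled when a same-type call places every breakpoint
within the per-type tolerance (0 for indels, 10 bp for the remaining types,
mirroring the two-sample intersection tolerances), with 1-to-1 matching.
For translocations, insertional-duplication calls at the same coordinates
are tallied separately as partial-signature recoveries (the signature minus
the excision junction).

## Known limitations

* One event per fragment; nested or adjacent interacting SVs are not
  resolved and surface as residual components.
* The built-in seed aligner is exhaustive and memory-resident; use SAM
  ingestion beyond ~10 Mb references.
* Blocks of the single-event alignment are gapless: a sequencing *indel*
  error inside a fragment (not simulated; rare on the target chemistry)
  would suppress that fragment's evidence, costing weight but typically not
  the call.
* Insertions longer than `l_f` − 2·k cannot be spanned and are invisible,
  as are duplications whose donors exceed `e_max_span` when the excision
  junction is absent.
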