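"""Breakpoint localization for discordant read pairs.

For a discordant pair the two seed placements anchor two windows of length
l_f on the reference (the *minimal reference*): the left window grows from
the read-1 seed in the read's 3' direction, the right window grows from the
read-2 seed likewise, and reverse-strand windows are reverse-complemented so
the joined sequence is collinear with the reconstructed fragment.  The
fragment is then glocally aligned to the joined windows and the start/end of
the optimal internal gap (or the column where the alignment crosses the
window junction) maps back -- undoing any reverse complement -- to exact
reference breakpoint coordinates.

Breakpoint *sides* record the direction from which the fragment approaches a
coordinate (``left``: the fragment occupies reference positions before the
breakpoint; ``right``: from the breakpoint onward).  The ordered side pair of
one fragment determines the discordant-edge type (a: left/left, b:
left/right, c: right/left, d: right/right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import AlignmentPath, GappedAlignment, OP_ALIGN, OP_DEL, OP_INS, global_align_affine
from .config import PipelineConfig, DEFAULT_CONFIG
from .dna import reverse_complement
from .fragments import ReconstructedFragment
from .seeding import SeedAlignmentPair

LEFT = "left"
RIGHT = "right"

#: (side of read-1 breakpoint, side of read-2 breakpoint) -> edge type
EDGE_TYPE = {
    (LEFT, LEFT): "a",
    (LEFT, RIGHT): "b",
    (RIGHT, LEFT): "c",
    (RIGHT, RIGHT): "d",
}


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int  # 0-based junction coordinate (position of the base to the right)
    side: str  # left | right

    @property
    def coord(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class Window:
    """A reference window as it appears in minimal-reference coordinates."""

    chrom: str
    start: int  # [start, end) on the forward reference
    end: int
    reverse: bool  # True if the window sequence is reverse-complemented

    def __len__(self) -> int:
        return self.end - self.start

    def ref_coord(self, offset: int) -> int:
        """Forward-reference coordinate of window-local ``offset``."""
        if self.reverse:
            return self.end - 1 - offset
        return self.start + offset

    def extract(self, reference: dict[str, str]) -> str:
        seq = reference[self.chrom][self.start : self.end]
        return reverse_complement(seq) if self.reverse else seq


@dataclass
class MinimalReference:
    left: Window
    right: Window
    seq: str
    junction_offset: int  # index in seq where the right window begins

    def locate(self, offset: int) -> tuple[Window, int]:
        if offset < self.junction_offset:
            return self.left, offset
        return self.right, offset - self.junction_offset


@dataclass(frozen=True)
class EvidenceEdge:
    """A typed directed connection between two breakpoints from one fragment."""

    type: str  # a | b | c | d
    u: Breakpoint  # read-1 side
    v: Breakpoint  # read-2 side
    sv_seq: str = ""  # inserted fragment sequence, if any


@dataclass
class FragmentEvidence:
    """All equivalent breakpoint interpretations of one discordant fragment."""

    pair_id: str
    alternatives: list[tuple[EvidenceEdge, ...]]  # each: one co-optimal placement


def build_minimal_reference(
    aln: SeedAlignmentPair,
    l_f: int,
    reference: dict[str, str],
    k: int = 30,
) -> Optional[MinimalReference]:
    """Join the two l_f windows anchored by the seed placements.

    Returns None when a window would be (almost) empty because a seed sits at
    a contig edge; such pairs are dropped upstream.
    """

    def clip(chrom: str, start: int, end: int, reverse: bool) -> Optional[Window]:
        n = len(reference[chrom])
        start, end = max(0, start), min(n, end)
        if end - start < k:
            return None
        return Window(chrom, start, end, reverse)

    if aln.strand1 == "+":
        w1 = clip(aln.chrom1, aln.pos1, aln.pos1 + l_f, reverse=False)
    else:
        w1 = clip(aln.chrom1, aln.pos1 + k - l_f, aln.pos1 + k, reverse=True)
    # read 2 runs 3'->5' along the fragment: its window extends backwards
    if aln.strand2 == "-":
        w2 = clip(aln.chrom2, aln.pos2 + k - l_f, aln.pos2 + k, reverse=False)
    else:
        w2 = clip(aln.chrom2, aln.pos2, aln.pos2 + l_f, reverse=True)
    if w1 is None or w2 is None:
        return None
    seq1, seq2 = w1.extract(reference), w2.extract(reference)
    return MinimalReference(w1, w2, seq1 + seq2, len(seq1))


def global_align_fragment(
    fragment: str, minref: MinimalReference, config: PipelineConfig = DEFAULT_CONFIG
) -> GappedAlignment:
    """Glocal affine alignment of the fragment against the minimal reference."""
    tol = config.placement_tolerance * (config.match - config.mismatch)
    return global_align_affine(
        fragment,
        minref.seq,
        match=config.match,
        mismatch=config.mismatch,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        max_paths=config.max_placements,
        tolerance_score=tol,
    )


def _breakpoint_before(minref: MinimalReference, col: int) -> Breakpoint:
    """Breakpoint adjacent to the last aligned column before a gap."""
    window, o = minref.locate(col)
    ref = window.ref_coord(o)
    if window.reverse:
        return Breakpoint(window.chrom, ref, RIGHT)
    return Breakpoint(window.chrom, ref + 1, LEFT)


def _breakpoint_after(minref: MinimalReference, col: int) -> Breakpoint:
    """Breakpoint adjacent to the first aligned column after a gap."""
    window, o = minref.locate(col)
    ref = window.ref_coord(o)
    if window.reverse:
        return Breakpoint(window.chrom, ref + 1, LEFT)
    return Breakpoint(window.chrom, ref, RIGHT)


def breakpoints_from_path(
    path: AlignmentPath,
    minref: MinimalReference,
    fragment: str,
    min_identity: float = 0.95,
) -> Optional[tuple[EvidenceEdge, ...]]:
    """Interpret one optimal traceback as a typed breakpoint connection.

    Exactly one internal gap run is expected for a simple SV: a run of
    skipped reference columns is a junction (deletion-like or rearrangement),
    a run of unmatched fragment bases is an insertion carried by the
    fragment.  Gapless alignments carry no breakpoint and alignments with
    several gap runs (nested/complex events) are discarded.
    """
    if path.identity_outside_gaps(fragment, minref.seq) < min_identity:
        return None
    runs = path.gap_runs()
    if len(runs) != 1:
        return None
    row, start, end = runs[0]
    if start == 0 or end == len(path.ops):  # gap at an alignment boundary
        return None
    before_op = path.ops[start - 1]
    after_op = path.ops[end]
    if before_op[0] != OP_ALIGN or after_op[0] != OP_ALIGN:
        return None
    bp_u = _breakpoint_before(minref, before_op[2])
    bp_v = _breakpoint_after(minref, after_op[2])
    sv_seq = ""
    if row == "reference":  # extra fragment bases: an insertion
        frag_idx = [i for op, i, _ in path.ops[start:end]]
        sv_seq = fragment[frag_idx[0] : frag_idx[-1] + 1]
    etype = EDGE_TYPE[(bp_u.side, bp_v.side)]
    return (EvidenceEdge(etype, bp_u, bp_v, sv_seq),)


def enumerate_optimal_placements(
    alignment: GappedAlignment,
    minref: MinimalReference,
    min_identity: float = 0.95,
) -> list[tuple[EvidenceEdge, ...]]:
    """Distinct breakpoint interpretations over all co-optimal tracebacks.

    For a single-base insertion into a homopolymer of length n this yields
    the n+1 equivalent placements.
    """
    seen = set()
    out = []
    for path in alignment.paths:
        edges = breakpoints_from_path(path, minref, alignment.fragment, min_identity)
        if edges is None:
            continue
        key = tuple((e.type, e.u, e.v, e.sv_seq) for e in edges)
        if key not in seen:
            seen.add(key)
            out.append(edges)
    return out


def enumerate_single_event_placements(
    fragment: str,
    minref: MinimalReference,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[tuple[EvidenceEdge, ...]]:
    """Optimal single-event alignments of a fragment to its minimal reference.

    The seed placements define where the fragment enters the minimal
    reference: fragment base 0 sits on the first column of the left window
    and the last fragment base on the last column of the right window, so the
    alignment is an anchored gapless block on the left-window diagonal, one
    affine-cost gap, and an anchored gapless block on the right-window
    anti-diagonal (a discordant fragment carries exactly one event; nested
    SVs are out of scope).  Under these anchors the valid placements form two
    one-parameter families:

    * junctions -- the gap consumes reference columns only; sliding the
      block boundary moves both breakpoints jointly (deletion and
      rearrangement junctions, including their shift-equivalent placements);
    * insertions -- the gap additionally consumes g* fragment bases, where
      g* is fixed by the window geometry so that the two gap-adjacent
      columns map to the same reference coordinate (the insertion site).

    Every placement scoring within ``placement_tolerance``
    mismatch-equivalents of the optimum over both families is returned
    (exact co-optima by default); for a single-base insertion into a
    homopolymer of length n these are the n+1 equivalent placements.  An
    empty list is returned when a block-only alignment explains the fragment
    at least as well (no breakpoint) or when identity over the aligned
    blocks falls below ``min_identity``.
    """
    import numpy as np

    n, m = len(fragment), len(minref.seq)
    jct = minref.junction_offset
    if n < 2 or m <= n or jct < 1 or m - jct < 1:
        return []
    match, mis = config.match, config.mismatch
    open_, ext = config.gap_open, config.gap_extend

    fc = np.frombuffer(fragment.encode(), dtype=np.uint8)
    rc = np.frombuffer(minref.seq.encode(), dtype=np.uint8)
    valid_f = fc != ord("N")

    # block1 diagonal: fragment[t] vs column t (left window, anchored at 0)
    d1 = min(n, jct)
    eq1 = (fc[:d1] == rc[:d1]) & valid_f[:d1] & (rc[:d1] != ord("N"))
    sub1 = np.where(eq1, match, mis)
    prefix1 = np.concatenate(([0.0], np.cumsum(sub1)))  # prefix1[i1], i1 = 0..d1
    match1 = np.concatenate(([0], np.cumsum(eq1.astype(int))))

    # block2 anti-diagonal: fragment[t] vs column off+t (right window, end-anchored)
    off = m - n
    eq2 = (fc == rc[off : off + n]) & valid_f & (rc[off : off + n] != ord("N"))
    sub2 = np.where(eq2, match, mis)
    suffix2 = np.concatenate((np.cumsum(sub2[::-1])[::-1], [0.0]))  # suffix2[i2], i2 = 0..n
    match2 = np.concatenate((np.cumsum(eq2[::-1].astype(int))[::-1], [0]))

    def bp_u(i1: int) -> Breakpoint:
        return _breakpoint_before(minref, i1 - 1)

    def bp_v(i2: int) -> Breakpoint:
        return _breakpoint_after(minref, off + i2)

    # Both families are charged the same gap baseline (open + extend per
    # skipped reference column); the skipped fragment bases of an insertion
    # are not surcharged.
    #
    # insertion family: g* fixed by requiring both gap-adjacent columns to
    # map to the same reference coordinate (same slope, same chromosome)
    ins_fam = None
    w1, w2 = minref.left, minref.right
    if w1.chrom == w2.chrom and w1.reverse == w2.reverse:
        u0, v0 = bp_u(1).pos, bp_v(1).pos
        slope = -1 if w1.reverse else 1
        g = (u0 - v0) * slope  # both breakpoints move with the same slope
        if g >= 1:
            lo = max(1, jct - off - g)
            hi = min(d1, n - 1 - g)
            if hi >= lo:
                idx = np.arange(lo, hi + 1)
                scores = prefix1[idx] + suffix2[idx + g] - open_ - ext * off
                ins_fam = (scores, idx, g)

    # junction family: split at i, gap skips the off reference columns
    jun_fam = None
    i_lo = max(1, jct - off)  # block2 must start inside the right window
    i_hi = min(d1, n - 1)
    if i_hi >= i_lo:
        idx = np.arange(i_lo, i_hi + 1)
        scores = prefix1[idx] + suffix2[idx] - open_ - ext * off
        jun_fam = (scores, idx, 0)

    if ins_fam is None and jun_fam is None:
        return []
    opt = max(float(f[0].max()) for f in (ins_fam, jun_fam) if f is not None)
    gapless = []
    if jct - off <= 0:
        gapless.append(float(suffix2[0]))
    if n <= jct:
        gapless.append(float(prefix1[n]))
    if gapless and max(gapless) >= opt:
        return []
    # Family choice.  A junction whose insertion family exists is necessarily
    # a same-orientation back-jump of span g*: it re-aligns g* reference
    # bases twice and is sequence-identical to an insertion duplicating the
    # adjacent flank (an extra base in a homopolymer, a direct-repeat
    # insertion).  Such duplicative content is reported as the insertion, so
    # the insertion family wins whenever it lies within the equivalence
    # margin of match * g* (the doubly counted bases); otherwise the
    # higher-scoring family is kept.
    if ins_fam is not None and (
        jun_fam is None
        or float(ins_fam[0].max()) + match * ins_fam[2] >= float(jun_fam[0].max()) - 1e-9
    ):
        chosen = ins_fam
    else:
        chosen = jun_fam
    tol = config.placement_tolerance * (match - mis)
    need = float(chosen[0].max()) - tol - 1e-9

    placements: list[tuple[EvidenceEdge, ...]] = []
    seen = set()
    for scores, idx, g_f in [chosen]:
        for k in np.flatnonzero(scores >= need):
            i1 = int(idx[k])
            i2 = i1 + g_f
            matches = int(match1[i1] + match2[i2])
            if matches < config.min_identity * (n - g_f):
                continue
            u, v = bp_u(i1), bp_v(i2)
            if g_f == 0 and u.coord == v.coord:
                continue  # zero-length event
            sv_seq = fragment[i1:i2]
            key = (u, v, sv_seq)
            if key in seen:
                continue
            seen.add(key)
            placements.append((EvidenceEdge(EDGE_TYPE[(u.side, v.side)], u, v, sv_seq),))
            if len(placements) >= config.max_placements:
                return placements
    return placements


def _realign_insertion(
    edges: tuple[EvidenceEdge, ...],
    reference: dict[str, str],
    min_length: int,
) -> tuple[EvidenceEdge, ...]:
    """Re-align a long inserted sequence to detect short-donor duplications.

    An insertion whose sequence occurs exactly once in the reference (on
    either strand) pins three coordinates with a single fragment: the
    insertion site plus both donor boundaries.  The evidence is rewritten as
    the two duplication junction edges; the donor-adjacency e-edge follows at
    graph construction.
    """
    if len(edges) != 1:
        return edges
    e = edges[0]
    if e.type != "b" or e.u.coord != e.v.coord or len(e.sv_seq) < min_length:
        return edges
    hits: list[tuple[str, int, str]] = []
    for strand, query in (("+", e.sv_seq), ("-", reverse_complement(e.sv_seq))):
        for chrom, seq in reference.items():
            start = seq.find(query)
            while start != -1:
                hits.append((chrom, start, strand))
                if len(hits) > 2:
                    return edges
                start = seq.find(query, start + 1)
    if len(hits) != 1:
        return edges
    chrom, s, strand = hits[0]
    dend = s + len(e.sv_seq)
    site = e.u
    if strand == "+":
        return (
            EvidenceEdge("b", Breakpoint(site.chrom, site.pos, LEFT), Breakpoint(chrom, s, RIGHT)),
            EvidenceEdge("b", Breakpoint(chrom, dend, LEFT), Breakpoint(site.chrom, site.pos, RIGHT)),
        )
    return (
        EvidenceEdge("a", Breakpoint(site.chrom, site.pos, LEFT), Breakpoint(chrom, dend, LEFT)),
        EvidenceEdge("d", Breakpoint(site.chrom, site.pos, RIGHT), Breakpoint(chrom, s, RIGHT)),
    )


def fragment_evidence(
    aln: SeedAlignmentPair,
    frag: ReconstructedFragment,
    reference: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Optional[FragmentEvidence]:
    """Full breakpointing of one discordant pair.

    Builds the minimal reference, aligns the fragment, enumerates equivalent
    placements and applies insertion re-alignment.  Returns None when the
    pair yields no usable breakpoint (window at a contig edge, gapless or
    complex alignment, low identity).
    """
    minref = build_minimal_reference(aln, frag.length, reference, k=config.seed_length)
    if minref is None:
        return None
    placements = enumerate_single_event_placements(frag.seq, minref, config)
    if not placements:
        return None
    placements = [
        _realign_insertion(p, reference, config.min_realign_length) for p in placements
    ]
    return FragmentEvidence(pair_id=frag.pair_id, alternatives=placements)
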