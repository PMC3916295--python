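"""Seed extraction, placement and exact read-pair classification.

Full reads that span a structural variant fail to align, so only the
high-confidence 5' prefix of each mate (the seed, default 30 bp) is placed on
the reference.  Because the exact fragment length l_f is known from the read
overlap, classification needs no fragment-size distribution: a pair is
concordant if and only if its two seeds lie on the same chromosome, in inward
orientation, and the implied outer span D equals l_f exactly; everything else
is discordant.

The built-in aligner is an exhaustive half-k-mer pigeonhole index: any
placement with at most one mismatch matches one seed half exactly, so looking
up both halves and verifying candidates finds *every* placement.  It is meant
for synthetic genomes up to ~10 Mb; alignments from an external seed aligner
can be ingested from SAM/BAM instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .dna import reverse_complement
from .fragments import ReadPair, ReconstructedFragment

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNUSABLE = "unusable"


@dataclass
class Seed:
    pair_id: str
    mate: int  # 1 or 2
    seq: str


@dataclass
class Placement:
    chrom: str
    pos: int  # 0-based leftmost coordinate on the forward reference
    strand: str  # '+': seed matches forward; '-': reverse_complement(seed) matches
    mismatches: int


@dataclass
class SeedAlignmentPair:
    pair_id: str
    chrom1: Optional[str] = None
    pos1: Optional[int] = None
    strand1: Optional[str] = None
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    strand2: Optional[str] = None
    mismatches1: int = 0
    mismatches2: int = 0
    unique1: bool = False
    unique2: bool = False
    label: Optional[str] = None

    @property
    def usable(self) -> bool:
        return self.unique1 and self.unique2


def extract_seeds(pair: ReadPair, k: int = 30) -> tuple[Seed, Seed]:
    """5' prefixes of length k of both mates."""
    if k > pair.read_length:
        raise ValueError(f"seed length {k} exceeds read length {pair.read_length}")
    return Seed(pair.id, 1, pair.seq1[:k]), Seed(pair.id, 2, pair.seq2[:k])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in zip(b"ACGT", range(4)):
        codes[arr == base] = code
    return codes


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all k-mers and a validity mask (no N) at each start position."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = codes[i : i + n]
        out = out * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    return out, valid


def _seq_code(seq: str) -> Optional[int]:
    code = 0
    for b in seq:
        v = "ACGT".find(b)
        if v < 0:
            return None
        code = code * 4 + v
    return code


class SeedIndex:
    """Exhaustive placement index over a reference (pigeonhole on seed halves).

    Complete for up to one mismatch: a one-mismatch placement leaves at least
    one half of the seed exact, so the union of exact half matches contains
    every candidate, and each candidate is verified base by base (N never
    matches and always counts as a mismatch).
    """

    def __init__(self, reference: dict[str, str], k: int = 30, max_mismatch: int = 1):
        if not reference or all(len(s) == 0 for s in reference.values()):
            raise ValueError("empty reference")
        if max_mismatch > 1:
            raise ValueError("the pigeonhole index is complete only for <= 1 mismatch")
        self.k = k
        self.max_mismatch = max_mismatch
        self.reference = {c: s.upper() for c, s in reference.items()}
        self._h1 = k // 2
        # any <=1-mismatch placement leaves one half exact, hence also that
        # half's prefix; indexing at most 31 bases keeps 2-bit codes in int64
        self._len1 = min(self._h1, 31)
        self._len2 = min(k - self._h1, 31)
        self._chroms: list[str] = sorted(self.reference)
        # global position layout: offsets[c] .. offsets[c] + len(chrom)
        self._offsets = {}
        total = 0
        for c in self._chroms:
            self._offsets[c] = total
            total += len(self.reference[c])
        self._starts = np.array([self._offsets[c] for c in self._chroms], dtype=np.int64)
        self._index1 = self._build(self._len1, 0)
        self._index2 = self._build(self._len2, self._h1)

    def _build(self, h: int, shift: int):
        codes_all, pos_all = [], []
        for c in self._chroms:
            enc = _encode(self.reference[c])
            codes, valid = _kmer_codes(enc, h)
            # position p holds the half starting at seed offset `shift`,
            # i.e. candidate seed start = p - shift
            starts = np.arange(codes.size, dtype=np.int64) - shift
            keep = valid & (starts >= 0) & (starts + self.k <= len(self.reference[c]))
            codes_all.append(codes[keep])
            pos_all.append(starts[keep] + self._offsets[c])
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.int64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        return codes[order], pos[order]

    def _global_to_chrom(self, gpos: int) -> tuple[str, int]:
        idx = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        c = self._chroms[idx]
        return c, gpos - self._offsets[c]

    def _candidates(self, seq: str) -> np.ndarray:
        cands = []
        for (codes, pos), (start, h) in (
            (self._index1, (0, self._len1)),
            (self._index2, (self._h1, self._len2)),
        ):
            code = _seq_code(seq[start : start + h])
            if code is None:
                continue
            lo = np.searchsorted(codes, code, side="left")
            hi = np.searchsorted(codes, code, side="right")
            if hi > lo:
                cands.append(pos[lo:hi])
        if not cands:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(cands))

    def _verify(self, seq: str, gpos: int) -> Optional[int]:
        chrom, p = self._global_to_chrom(gpos)
        ref = self.reference[chrom]
        window = ref[p : p + self.k]
        mm = 0
        for x, y in zip(seq, window):
            if x != y or x == "N" or y == "N":
                mm += 1
                if mm > self.max_mismatch:
                    return None
        return mm

    def find(self, seq: str, stop_after: Optional[int] = None) -> list[Placement]:
        """All placements of ``seq`` with <= max_mismatch mismatches, both strands."""
        if len(seq) != self.k:
            raise ValueError(f"query length {len(seq)} != index k {self.k}")
        placements: list[Placement] = []
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for gpos in self._candidates(s):
                mm = self._verify(s, int(gpos))
                if mm is not None:
                    chrom, p = self._global_to_chrom(int(gpos))
                    placements.append(Placement(chrom, p, strand, mm))
                    if stop_after is not None and len(placements) >= stop_after:
                        return placements
        return placements


def align_seeds_internal(
    seeds: Iterable[Seed], reference: dict[str, str] | SeedIndex,
    max_mismatch: int = 1, k: Optional[int] = None,
) -> dict[tuple[str, int], list[Placement]]:
    """Place seeds with the built-in exhaustive aligner.

    Returns ``{(pair_id, mate): [Placement, ...]}`` with *all* placements so
    that uniqueness (exactly one placement genome-wide) can be decided.
    """
    seeds = list(seeds)
    if isinstance(reference, SeedIndex):
        index = reference
    else:
        klen = k or (len(seeds[0].seq) if seeds else 30)
        index = SeedIndex(reference, k=klen, max_mismatch=max_mismatch)
    return {(s.pair_id, s.mate): index.find(s.seq, stop_after=2) for s in seeds}


def place_pair(pair: ReadPair, index: SeedIndex) -> SeedAlignmentPair:
    """Place both seeds of a pair; unusable unless both are unique."""
    s1, s2 = extract_seeds(pair, index.k)
    p1 = index.find(s1.seq, stop_after=2)
    p2 = index.find(s2.seq, stop_after=2)
    aln = SeedAlignmentPair(pair_id=pair.id)
    aln.unique1 = len(p1) == 1
    aln.unique2 = len(p2) == 1
    if aln.unique1:
        aln.chrom1, aln.pos1, aln.strand1 = p1[0].chrom, p1[0].pos, p1[0].strand
        aln.mismatches1 = p1[0].mismatches
    if aln.unique2:
        aln.chrom2, aln.pos2, aln.strand2 = p2[0].chrom, p2[0].pos, p2[0].strand
        aln.mismatches2 = p2[0].mismatches
    if not (aln.unique1 and aln.unique2):
        aln.label = UNUSABLE
    return aln


def classify_pair(aln: SeedAlignmentPair, frag: ReconstructedFragment | int,
                  k: int = 30) -> str:
    """Exact concordant/discordant decision for a usable pair.

    With read 1 on the forward strand the outer span is
    ``D = (pos2 + k) - pos1`` (rightmost base of the reverse seed's placement
    + 1, minus the leftmost base of the forward seed); the mirrored case is
    symmetric.  Concordant requires the same chromosome, inward opposite
    orientation and D == l_f exactly.
    """
    if not aln.usable:
        raise ValueError("classify_pair requires a pair with two unique placements")
    l_f = frag if isinstance(frag, int) else frag.length
    if aln.chrom1 == aln.chrom2:
        if aln.strand1 == "+" and aln.strand2 == "-":
            if aln.pos2 + k - aln.pos1 == l_f:
                return CONCORDANT
        elif aln.strand1 == "-" and aln.strand2 == "+":
            if aln.pos1 + k - aln.pos2 == l_f:
                return CONCORDANT
    return DISCORDANT


def ingest_alignments(sam_path: str) -> Iterator[SeedAlignmentPair]:
    """Stream seed placements of read pairs from a SAM/BAM file.

    Pairs with an unmapped mate, a mate with more than one reported placement
    (secondary/supplementary records) or mapping quality 0 are yielded as
    unusable; malformed records are skipped (counted on the generator's
    ``skipped`` attribute once exhausted).
    """
    import pysam

    primary: dict[str, dict[int, list]] = defaultdict(lambda: {1: [], 2: []})
    skipped = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            try:
                if rec.query_name is None or not (rec.is_read1 or rec.is_read2):
                    skipped += 1
                    continue
                mate = 1 if rec.is_read1 else 2
                primary[rec.query_name][mate].append(rec)
            except (ValueError, AttributeError):
                skipped += 1
    for name, mates in primary.items():
        aln = SeedAlignmentPair(pair_id=name)
        sides = {}
        for mate in (1, 2):
            recs = [r for r in mates[mate]]
            mapped = [r for r in recs if not r.is_unmapped]
            n_placements = len(mapped)
            unique = (
                n_placements == 1
                and not mapped[0].is_secondary
                and not mapped[0].is_supplementary
                and (mapped[0].mapping_quality or 0) > 0
            )
            sides[mate] = (unique, mapped[0] if mapped else None)
        aln.unique1, r1 = sides[1]
        aln.unique2, r2 = sides[2]
        if aln.unique1:
            aln.chrom1 = r1.reference_name
            aln.pos1 = r1.reference_start
            aln.strand1 = "-" if r1.is_reverse else "+"
            aln.mismatches1 = int(r1.get_tag("NM")) if r1.has_tag("NM") else 0
        if aln.unique2:
            aln.chrom2 = r2.reference_name
            aln.pos2 = r2.reference_start
            aln.strand2 = "-" if r2.is_reverse else "+"
            aln.mismatches2 = int(r2.get_tag("NM")) if r2.has_tag("NM") else 0
        if not (aln.unique1 and aln.unique2):
            aln.label = UNUSABLE
        yield aln


def unique_alignability(
    reference: dict[str, str], k: int, max_mismatch: int = 1
) -> dict[str, tuple[float, float]]:
    """Per-chromosome fractions of k-mers placing uniquely vs multiply.

    Every position is tiled (step 1); k-mers containing N are excluded from
    the denominator of neither fraction (fractions may sum to < 1).
    """
    index = SeedIndex(reference, k=k, max_mismatch=max_mismatch)
    out = {}
    for chrom, seq in index.reference.items():
        n = len(seq) - k + 1
        if n <= 0:
            raise ValueError(f"k={k} exceeds length of {chrom}")
        unique = multiple = 0
        for p in range(n):
            kmer = seq[p : p + k]
            if "N" in kmer:
                continue
            hits = index.find(kmer, stop_after=2)
            if len(hits) == 1:
                unique += 1
            elif len(hits) > 1:
                multiple += 1
        out[chrom] = (unique / n, multiple / n)
    return out


def write_alignability_report(result: dict[str, tuple[float, float]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tfraction_unique\tfraction_multiple\n")
        for chrom, (u, m) in sorted(result.items()):
            fh.write(f"{chrom}\t{u:.6f}\t{m:.6f}\n")


def write_seed_fasta(seeds: Iterable[Seed], path: str) -> None:
    """Export seeds for an external aligner (report all placements, <=1 mismatch)."""
    with open(path, "w") as fh:
        for s in seeds:
            fh.write(f">{s.pair_id}/{s.mate}\n{s.seq}\n")
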