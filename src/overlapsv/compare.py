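"""Two-sample comparison and sequence-context analyses of SV calls.

Covers the analyses run on a tumor/control pair: intersecting the two call
sets with per-type breakpoint tolerances, the dependence of the shared
fraction on the minimum required weight (MRW), indel size spectra, the most
frequently inserted sequences, insertions within single-base simple repeats,
direct-repeat insertions (the footprint of conservative DNA-transposon
excision), and breakpoint densities across annotated genome compartments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .svgraph import SVCall

Coord = tuple[str, int]

_INDEL = {"insertion", "deletion"}


def _match_distance(a: SVCall, b: SVCall, tol: int) -> Optional[int]:
    """Max per-breakpoint distance if a and b describe the same event, else None."""
    if a.type != b.type:
        return None
    ca, cb = a.coords(), b.coords()
    if len(ca) != len(cb):
        return None
    dist = 0
    for (chrom_a, pos_a), (chrom_b, pos_b) in zip(ca, cb):
        if chrom_a != chrom_b:
            return None
        d = abs(pos_a - pos_b)
        if d > tol:
            return None
        dist = max(dist, d)
    if a.type == "insertion" and len(a.sv_seq) != len(b.sv_seq):
        return None
    return dist


def intersect_calls(
    calls_a: Sequence[SVCall],
    calls_b: Sequence[SVCall],
    tol_indel: int = 1,
    tol_complex: int = 10,
) -> tuple[list[tuple[SVCall, SVCall]], list[SVCall], list[SVCall]]:
    """Greedy 1-to-1 intersection of two call sets.

    Two calls match when they have the same type, the same chromosomes,
    every corresponding breakpoint within the per-type tolerance (1 bp for
    indels, 10 bp for the remaining types) and, for insertions, the same
    inserted length.  Pairs are matched nearest-first so no call is counted
    twice.  Returns (common pairs, A-specific, B-specific).
    """
    candidates = []
    for i, a in enumerate(calls_a):
        tol = tol_indel if a.type in _INDEL else tol_complex
        for j, b in enumerate(calls_b):
            d = _match_distance(a, b, tol)
            if d is not None:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    common = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        common.append((calls_a[i], calls_b[j]))
    a_specific = [c for i, c in enumerate(calls_a) if i not in used_a]
    b_specific = [c for j, c in enumerate(calls_b) if j not in used_b]
    return common, a_specific, b_specific


def filter_by_weight(calls: Iterable[SVCall], w: int) -> list[SVCall]:
    """Calls supported by at least ``w`` read pairs (the MRW filter)."""
    return [c for c in calls if c.weight >= w]


def overlap_vs_weight(
    calls_a: Sequence[SVCall],
    calls_b: Sequence[SVCall],
    w_range: Iterable[int] = range(1, 5),
    tol_indel: int = 1,
    tol_complex: int = 10,
) -> pd.DataFrame:
    """Shared fraction of two call sets as a function of the MRW.

    For each w the table reports the per-sample call counts, the number of
    common calls and the shared fraction |common| / |A union B| (Jaccard).
    Raising the MRW discards weakly supported, mostly sample-specific calls,
    so the shared fraction grows with w when the true events are germline.
    """
    rows = []
    for w in w_range:
        fa, fb = filter_by_weight(calls_a, w), filter_by_weight(calls_b, w)
        common, _, _ = intersect_calls(fa, fb, tol_indel, tol_complex)
        union = len(fa) + len(fb) - len(common)
        rows.append(
            {
                "w": w,
                "n_a": len(fa),
                "n_b": len(fb),
                "n_common": len(common),
                "shared_fraction": len(common) / union if union else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def size_distribution(calls: Iterable[SVCall]) -> Counter:
    """Histogram of signed indel sizes (insertions positive, deletions negative)."""
    out: Counter = Counter()
    for c in calls:
        if c.type == "insertion":
            out[len(c.sv_seq)] += 1
        elif c.type == "deletion":
            out[-(c.breakpoints["end"][1] - c.breakpoints["start"][1])] += 1
    return out


def top_inserted_sequences(calls: Iterable[SVCall], n: int = 10) -> list[tuple[str, int]]:
    """The n most frequently inserted sequences (ties broken lexicographically)."""
    counts = Counter(c.sv_seq for c in calls if c.type == "insertion" and c.sv_seq)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def _run_length_around(seq: str, pos: int, base: str, include_pos: bool) -> int:
    """Length of the ``base`` homopolymer run touching ``pos`` on the reference.

    For insertions (``include_pos`` False) the run spans both flanks of the
    insertion point; for single-base deletions (True) the run contains the
    deleted base itself.
    """
    left = pos - 1
    n = 0
    while left >= 0 and seq[left] == base:
        n += 1
        left -= 1
    right = pos if not include_pos else pos + 1
    if include_pos:
        if pos >= len(seq) or seq[pos] != base:
            return 0
        n += 1
    while right < len(seq) and seq[right] == base:
        n += 1
        right += 1
    return n


def simple_repeat_fraction(
    calls: Iterable[SVCall],
    reference: dict[str, str],
    min_run: int = 4,
) -> dict[str, tuple[int, int, float]]:
    """Fraction of single-base indels inside simple repeats of the same base.

    An event counts when its breakpoint abuts or lies inside a run of at
    least ``min_run`` copies of the inserted/deleted base on the reference
    (the run may span both flanks of an insertion point).  Returns
    ``{base: (n_in_repeat, n_total, fraction)}``.
    """
    per_base: dict[str, list[int]] = {b: [0, 0] for b in "ACGT"}
    for c in calls:
        if c.type == "insertion" and len(c.sv_seq) == 1:
            base = c.sv_seq
            chrom, pos = c.breakpoints["site"]
            include = False
        elif c.type == "deletion" and (
            c.breakpoints["end"][1] - c.breakpoints["start"][1] == 1
        ):
            chrom, pos = c.breakpoints["start"]
            base = c.sv_seq or reference[chrom][pos]
            include = True
        else:
            continue
        if base not in per_base:
            continue
        per_base[base][1] += 1
        if _run_length_around(reference[chrom], pos, base, include) >= min_run:
            per_base[base][0] += 1
    return {
        b: (hit, tot, hit / tot if tot else float("nan"))
        for b, (hit, tot) in per_base.items()
    }


def direct_repeat_insertions(
    calls: Iterable[SVCall],
    reference: dict[str, str],
) -> tuple[list[SVCall], list[SVCall]]:
    """Insertions > 2 bp identical to an immediately flanking sequence.

    A direct repeat requires the inserted sequence to equal the reference
    substring directly left or directly right of the insertion site.  The
    second return value is the non-simple subset (at least 3 distinct bases),
    the candidates for transposon-mediated events.
    """
    repeats: list[SVCall] = []
    nonsimple: list[SVCall] = []
    for c in calls:
        if c.type != "insertion" or len(c.sv_seq) < 3:
            continue
        chrom, pos = c.breakpoints["site"]
        seq = c.sv_seq
        ref = reference[chrom]
        left = ref[max(0, pos - len(seq)) : pos]
        right = ref[pos : pos + len(seq)]
        if seq == left or seq == right:
            repeats.append(c)
            if len(set(seq)) >= 3:
                nonsimple.append(c)
    return repeats, nonsimple


# ---------------------------------------------------------------------------
# genome compartments


@dataclass
class GeneModel:
    """A minimal gene model (coordinates 0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


def load_gff3(path: str) -> list[GeneModel]:
    """Gene models from a GFF3 file (gene/exon/CDS/UTR features)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        model = GeneModel(g.id, g.seqid, g.start - 1, g.end, g.strand)
        for feat, target in (
            ("exon", model.exons),
            ("CDS", model.cds),
            ("five_prime_UTR", model.utr5),
            ("three_prime_UTR", model.utr3),
        ):
            for f in db.children(g, featuretype=feat):
                target.append((f.start - 1, f.end))
        genes.append(model)
    return genes


def load_bed12(path: str) -> list[GeneModel]:
    """Gene models from BED12 (blocks become exons; thick region becomes CDS)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            thick = (int(f[6]), int(f[7])) if len(f) > 7 else (start, start)
            model = GeneModel(name, chrom, start, end, strand)
            if len(f) > 11:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                model.exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            else:
                model.exons = [(start, end)]
            if thick[1] > thick[0]:
                for s, e in model.exons:
                    cs, ce = max(s, thick[0]), min(e, thick[1])
                    if ce > cs:
                        model.cds.append((cs, ce))
            genes.append(model)
    return genes


def _mask(genome_len: dict[str, int]) -> dict[str, np.ndarray]:
    return {c: np.zeros(n, dtype=bool) for c, n in genome_len.items()}


def _paint(mask: dict[str, np.ndarray], chrom: str, start: int, end: int) -> None:
    arr = mask.get(chrom)
    if arr is not None:
        arr[max(0, start) : min(arr.size, end)] = True


def breakpoint_compartment_density(
    breakpoints: Iterable[Coord],
    genes: Sequence[GeneModel],
    genome_len: dict[str, int],
    splice_site_width: int = 2,
) -> pd.DataFrame:
    """Breakpoint density (count per bp) across functional genome compartments.

    Compartments: the full genome; unique genes (sharing no position with
    another gene) vs overlapping genes; exonic regions, 5'/3' UTRs and CDS
    taken from unique genes only (avoiding ambiguous assignment); introns of
    unique genes; intergenic space; and donor/acceptor splice sites
    (``splice_site_width`` bases each side of every unique-gene intron
    boundary).
    """
    gene_mask = _mask(genome_len)
    for g in genes:
        _paint(gene_mask, g.chrom, g.start, g.end)
    # unique = genes not overlapping any other gene
    unique_genes = []
    overlapping = []
    for g in genes:
        others = [
            o for o in genes
            if o is not g and o.chrom == g.chrom and o.start < g.end and o.end > g.start
        ]
        (overlapping if others else unique_genes).append(g)

    masks: dict[str, dict[str, np.ndarray]] = {
        "genome": {c: np.ones(n, dtype=bool) for c, n in genome_len.items()},
        "unique_genes": _mask(genome_len),
        "overlapping_genes": _mask(genome_len),
        "exonic": _mask(genome_len),
        "utr5": _mask(genome_len),
        "utr3": _mask(genome_len),
        "cds": _mask(genome_len),
        "intronic": _mask(genome_len),
        "intergenic": _mask(genome_len),
        "splice_sites": _mask(genome_len),
    }
    for g in overlapping:
        _paint(masks["overlapping_genes"], g.chrom, g.start, g.end)
    for g in unique_genes:
        _paint(masks["unique_genes"], g.chrom, g.start, g.end)
        for s, e in g.exons:
            _paint(masks["exonic"], g.chrom, s, e)
        for key, ivals in (("utr5", g.utr5), ("utr3", g.utr3), ("cds", g.cds)):
            for s, e in ivals:
                _paint(masks[key], g.chrom, s, e)
        # introns: gene span minus exons; splice sites flank intron boundaries
        exon_mask = np.zeros(g.end - g.start, dtype=bool)
        for s, e in g.exons:
            exon_mask[max(0, s - g.start) : max(0, e - g.start)] = True
        intron = ~exon_mask
        _paint_bool(masks["intronic"][g.chrom], g.start, intron)
        bounds = np.flatnonzero(np.diff(exon_mask.astype(int)))
        for b in bounds:
            _paint(masks["splice_sites"], g.chrom,
                   g.start + b + 1 - splice_site_width, g.start + b + 1 + splice_site_width)
    for c, arr in masks["intergenic"].items():
        arr[:] = ~gene_mask[c]

    bp_list = list(breakpoints)
    rows = []
    for name, mask in masks.items():
        total = int(sum(a.sum() for a in mask.values()))
        count = sum(
            1 for chrom, pos in bp_list
            if chrom in mask and 0 <= pos < mask[chrom].size and mask[chrom][pos]
        )
        rows.append(
            {
                "compartment": name,
                "bp_count": count,
                "length": total,
                "density": count / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _paint_bool(arr: np.ndarray, offset: int, mask: np.ndarray) -> None:
    end = min(arr.size, offset + mask.size)
    if end > offset >= 0:
        arr[offset:end] |= mask[: end - offset]


# ---------------------------------------------------------------------------
# plots


def plot_size_distribution(calls: Iterable[SVCall], ax=None):
    """Bar plot of the signed indel size spectrum."""
    import matplotlib.pyplot as plt

    hist = size_distribution(calls)
    if ax is None:
        _, ax = plt.subplots()
    sizes = sorted(hist)
    ax.bar(sizes, [hist[s] for s in sizes], width=0.9)
    ax.set_xlabel("signed indel size [bp]")
    ax.set_ylabel("count")
    return ax


def plot_overlap_vs_weight(table: pd.DataFrame, ax=None):
    """Shared fraction of two samples as a function of the MRW."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table["w"], table["shared_fraction"], marker="o")
    ax.set_xlabel("minimum required weight")
    ax.set_ylabel("shared fraction")
    ax.set_ylim(0, 1)
    return ax
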