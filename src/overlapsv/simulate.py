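"""Synthetic references, planted SVs, overlapping read pairs and scoring.

The simulator is the package's benchmark engine.  It emulates the study
design the caller targets: short-insert libraries (fragment sizes around
250 bp, at most 2L - m_min = 287 bp in overlap-guaranteed mode) sequenced as
150 bp paired-end reads so that mates overlap centrally, at coverages of
~20x.  Structural variants of all 16 detectable types are planted into one
or two haplotype copies of a random reference; every breakpoint is recorded
in reference coordinates as ground truth.

What the generator does *not* emulate: real genomes' repeat and transposon
landscape (sequence is i.i.d. unless repeat cassettes are requested), indel
sequencing errors, quality profiles and PCR duplicates.  Benchmarks on these
genomes therefore bound the algorithmic error of the caller, not the
repeat-induced losses seen on real genomes.

Default SV size ranges follow the experimentally validated events of the
study system: small insertions 22-133 bp, deletions 22-245 bp, tandem
duplications 293-889 bp; duplication/translocation donors default to
300-900 bp with insertion sites at least 2 kb away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .dna import reverse_complement, BASES
from .fragments import ReadPair
from .svgraph import SVCall

Coord = tuple[str, int]

#: planted types (identical naming to the prototype catalog)
SV_TYPES = (
    "insertion",
    "deletion",
    "tandem_duplication",
    "inversion",
    "insertional_duplication_intra_down",
    "insertional_duplication_intra_up",
    "insertional_duplication_inter",
    "insertional_duplication_intra_down_inverted",
    "insertional_duplication_intra_up_inverted",
    "insertional_duplication_inter_inverted",
    "translocation_intra_down",
    "translocation_intra_up",
    "translocation_inter",
    "translocation_intra_down_inverted",
    "translocation_intra_up_inverted",
    "translocation_inter_inverted",
)

DEFAULT_SIZE_RANGES = {
    "insertion": (22, 133),
    "deletion": (22, 245),
    "tandem_duplication": (293, 889),
    "inversion": (300, 900),
    "duplication_donor": (300, 900),
}

#: default breakpoint tolerance used when scoring calls, per type family
DEFAULT_EVAL_TOLERANCE = {
    "insertion": 0,
    "deletion": 0,
    "tandem_duplication": 10,
    "inversion": 10,
    "insertional_duplication": 10,
    "translocation": 10,
}


@dataclass
class SimulatedSV:
    type: str
    coords: dict[str, Coord]  # role -> reference coordinate
    size: int
    haplotypes: frozenset[int] = frozenset({0})
    seq: str = ""  # inserted sequence (novel insertions only)

    def to_json(self) -> dict:
        return {
            "type": self.type,
            "coords": {r: list(c) for r, c in self.coords.items()},
            "size": self.size,
            "haplotypes": sorted(self.haplotypes),
            "seq": self.seq,
        }

    @classmethod
    def from_json(cls, data: dict) -> "SimulatedSV":
        return cls(
            data["type"],
            {r: (c[0], int(c[1])) for r, c in data["coords"].items()},
            int(data["size"]),
            frozenset(data["haplotypes"]),
            data.get("seq", ""),
        )


@dataclass
class TruthSet:
    svs: list[SimulatedSV]
    genome_id: str = ""
    seed: int = 0

    def by_type(self) -> dict[str, list[SimulatedSV]]:
        out: dict[str, list[SimulatedSV]] = {}
        for sv in self.svs:
            out.setdefault(sv.type, []).append(sv)
        return out

    def to_json_file(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genome_id": self.genome_id,
                    "seed": self.seed,
                    "svs": [sv.to_json() for sv in self.svs],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json_file(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            [SimulatedSV.from_json(s) for s in data["svs"]],
            data.get("genome_id", ""),
            int(data.get("seed", 0)),
        )

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for sv in self.svs:
                for role, (chrom, pos) in sorted(sv.coords.items()):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sv.type}:{role}\n")


# ---------------------------------------------------------------------------
# reference generation


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                     p=[p_at, p_gc, p_gc, p_at])
    return arr.tobytes().decode()


def generate_reference(
    lengths: int | dict[str, int],
    gc: float = 0.5,
    seed: int | np.random.Generator = 0,
    repeat_fraction: float = 0.0,
    repeat_length: int = 1000,
    repeat_families: int = 5,
) -> dict[str, str]:
    """Random reference; optional interspersed repeat cassettes.

    ``lengths`` may be a single length (one chromosome ``chr1``) or a mapping
    of chromosome names to lengths.  With ``repeat_fraction > 0`` identical
    copies of a few repeat elements are stamped over the sequence until the
    requested genome fraction is repetitive -- a stress test for seed
    uniqueness, off by default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(lengths, int):
        lengths = {"chr1": lengths}
    genome = {c: random_sequence(rng, n, gc) for c, n in lengths.items()}
    if repeat_fraction > 0:
        elements = [random_sequence(rng, repeat_length, gc) for _ in range(repeat_families)]
        total = sum(lengths.values())
        n_copies = int(repeat_fraction * total / repeat_length)
        chroms = sorted(genome)
        weights = np.array([lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(n_copies):
            c = chroms[rng.choice(len(chroms), p=weights)]
            elem = elements[int(rng.integers(len(elements)))]
            if len(genome[c]) <= len(elem):
                continue
            p = int(rng.integers(0, len(genome[c]) - len(elem)))
            genome[c] = genome[c][:p] + elem + genome[c][p + len(elem):]
    return genome


# ---------------------------------------------------------------------------
# SV planting


class _Occupancy:
    """Reserved intervals per chromosome (keeps planted SVs non-interacting)."""

    def __init__(self) -> None:
        from intervaltree import IntervalTree

        self._trees: dict[str, "IntervalTree"] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is None or not tree.overlaps(start, end)

    def reserve(self, chrom: str, start: int, end: int) -> None:
        from intervaltree import IntervalTree

        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)


def _choose_haplotypes(rng: np.random.Generator, ploidy: int, het_fraction: float) -> frozenset[int]:
    if ploidy == 1:
        return frozenset({0})
    if rng.random() < het_fraction:
        return frozenset({int(rng.integers(ploidy))})
    return frozenset(range(ploidy))


def plant_svs(
    reference: dict[str, str],
    counts: dict[str, int],
    size_ranges: Optional[dict[str, tuple[int, int]]] = None,
    ploidy: int = 1,
    het_fraction: float = 0.0,
    min_spacing: int = 1148,
    donor_gap: int = 2000,
    avoid_ambiguous: bool = True,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> tuple[list[dict[str, str]], TruthSet]:
    """Plant SVs and return the haplotype sequences plus the truth set.

    ``counts`` maps SV type names (see :data:`SV_TYPES`) to event counts.
    Planted events are separated by ``min_spacing`` (default twice the
    maximal fragment length, so signatures cannot interact) and duplication
    donors sit at least ``donor_gap`` from their insertion site.  With
    ``avoid_ambiguous`` indel junctions are rejected when the flanking bases
    would allow shift-equivalent placements, keeping the planted coordinate
    the unique optimum (single-base evaluation stays well defined).

    Returns one edited genome per haplotype (index 0..ploidy-1); events are
    assigned to a single haplotype with probability ``het_fraction``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = dict(DEFAULT_SIZE_RANGES)
    if size_ranges:
        sizes.update(size_ranges)
    chroms = sorted(reference)
    lengths = {c: len(reference[c]) for c in chroms}
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied = _Occupancy()
    svs: list[SimulatedSV] = []
    edits: dict[int, dict[str, list[tuple]]] = {
        h: {c: [] for c in chroms} for h in range(ploidy)
    }

    def pick_chrom() -> str:
        return chroms[int(rng.choice(len(chroms), p=weights))]

    def rand_size(key: str) -> int:
        lo, hi = sizes[key]
        return int(rng.integers(lo, hi + 1))

    def place(type_name: str) -> Optional[SimulatedSV]:
        margin = min_spacing
        if type_name == "insertion":
            c = pick_chrom()
            size = rand_size("insertion")
            p = int(rng.integers(margin, lengths[c] - margin))
            if not occupied.free(c, p - margin, p + margin):
                return None
            seq = random_sequence(rng, size)
            if avoid_ambiguous:
                ref = reference[c]
                if seq[0] == ref[p] or seq[-1] == ref[p - 1]:
                    return None
            occupied.reserve(c, p - margin, p + margin)
            sv = SimulatedSV(type_name, {"site": (c, p)}, size, seq=seq)
            _apply(sv, [("ins", c, p, seq)])
            return sv
        if type_name in ("deletion", "tandem_duplication", "inversion"):
            c = pick_chrom()
            size = rand_size(type_name)
            s = int(rng.integers(margin, lengths[c] - margin - size))
            e = s + size
            if not occupied.free(c, s - margin, e + margin):
                return None
            ref = reference[c]
            if type_name == "deletion" and avoid_ambiguous:
                if ref[s] == ref[e] or ref[s - 1] == ref[e - 1]:
                    return None
            occupied.reserve(c, s - margin, e + margin)
            sv = SimulatedSV(type_name, {"start": (c, s), "end": (c, e)}, size)
            if type_name == "deletion":
                _apply(sv, [("del", c, s, e)])
            elif type_name == "tandem_duplication":
                _apply(sv, [("ins", c, e, ref[s:e])])
            else:
                _apply(sv, [("inv", c, s, e)])
            return sv

        # insertional duplications and translocations
        family = "translocation" if type_name.startswith("translocation") else "insertional_duplication"
        inverted = type_name.endswith("_inverted")
        place_kind = type_name.removeprefix(family + "_").removesuffix("_inverted")
        size = rand_size("duplication_donor")
        cd = pick_chrom()
        s = int(rng.integers(margin, lengths[cd] - margin - size))
        e = s + size
        if place_kind == "inter":
            others = [c for c in chroms if c != cd]
            if not others:
                return None
            cp = others[int(rng.integers(len(others)))]
            p = int(rng.integers(margin, lengths[cp] - margin))
        else:
            cp = cd
            if place_kind == "intra_up":
                lo, hi = margin, s - donor_gap
            else:
                lo, hi = e + donor_gap, lengths[cd] - margin
            if hi <= lo:
                return None
            p = int(rng.integers(lo, hi))
        if not occupied.free(cd, s - margin, e + margin) or not occupied.free(cp, p - margin, p + margin):
            return None
        occupied.reserve(cd, s - margin, e + margin)
        occupied.reserve(cp, p - margin, p + margin)
        donor = reference[cd][s:e]
        insert = reverse_complement(donor) if inverted else donor
        ops = [("ins", cp, p, insert)]
        if family == "translocation":
            ops.append(("del", cd, s, e))
        sv = SimulatedSV(
            type_name,
            {"site": (cp, p), "dstart": (cd, s), "dend": (cd, e)},
            size,
        )
        _apply(sv, ops)
        return sv

    def _apply(sv: SimulatedSV, ops: list[tuple]) -> None:
        sv.haplotypes = _choose_haplotypes(rng, ploidy, het_fraction)
        for op in ops:
            for h in sv.haplotypes:
                edits[h][op[1]].append((op[2],) + (op,))

    for type_name, n in counts.items():
        if type_name not in SV_TYPES:
            raise ValueError(f"unknown SV type: {type_name}")
        placed = 0
        tries = 0
        while placed < n:
            tries += 1
            if tries > max_tries * n:
                raise ValueError(
                    f"could not place {n} x {type_name}: genome too small for the "
                    f"requested counts and spacing"
                )
            sv = place(type_name)
            if sv is not None:
                svs.append(sv)
                placed += 1

    haplotypes = [
        {c: _rebuild(reference[c], sorted(edits[h][c])) for c in chroms}
        for h in range(ploidy)
    ]
    return haplotypes, TruthSet(svs, seed=int(rng.integers(2**31)))


def _rebuild(ref: str, keyed_ops: list[tuple]) -> str:
    parts = []
    cursor = 0
    for _, op in keyed_ops:
        kind = op[0]
        if kind == "ins":
            _, _, p, seq = op
            parts.append(ref[cursor:p])
            parts.append(seq)
            cursor = p
        elif kind == "del":
            _, _, s, e = op
            parts.append(ref[cursor:s])
            cursor = e
        elif kind == "inv":
            _, _, s, e = op
            parts.append(ref[cursor:s])
            parts.append(reverse_complement(ref[s:e]))
            cursor = e
        else:  # pragma: no cover
            raise AssertionError(kind)
    parts.append(ref[cursor:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# read simulation


def simulate_read_pairs(
    haplotypes: Sequence[dict[str, str]] | dict[str, str],
    coverage: float = 20.0,
    read_length: int = 150,
    frag_mean: float = 250.0,
    frag_sd: float = 30.0,
    frag_dist: str = "uniform",
    frag_range: tuple[int, int] = (200, 287),
    truncate_overlap: bool = True,
    error_rate: float = 0.0,
    min_overlap: int = 13,
    seed: int | np.random.Generator = 0,
) -> Iterator[ReadPair]:
    """Simulate overlapping paired-end reads from one or more haplotypes.

    Fragment starts are uniform; fragment lengths are drawn either uniformly
    from ``frag_range`` or from a normal(frag_mean, frag_sd).  In
    overlap-guaranteed mode lengths are truncated to
    [read_length, 2*read_length - min_overlap]; without truncation longer
    fragments produce non-overlapping pairs and reproduce the bimodal
    overlap-score distribution of a real library.  Read 2 is the reverse
    complement of the fragment end; substitution errors are applied per base
    at ``error_rate``.  Coverage counts fragment bases over all haplotypes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(haplotypes, dict):
        haplotypes = [haplotypes]
    L = read_length
    lo_bound = L
    hi_bound = 2 * L - min_overlap if truncate_overlap else None
    n_haps = len(haplotypes)
    pair_no = 0
    for h, genome in enumerate(haplotypes):
        for chrom in sorted(genome):
            seq = genome[chrom]
            if len(seq) < lo_bound:
                continue
            mean_lf = (
                (frag_range[0] + frag_range[1]) / 2 if frag_dist == "uniform" else frag_mean
            )
            n_frags = int(round(coverage * len(seq) / mean_lf / n_haps))
            if frag_dist == "uniform":
                lfs = rng.integers(frag_range[0], frag_range[1] + 1, size=n_frags)
            elif frag_dist == "normal":
                lfs = np.rint(rng.normal(frag_mean, frag_sd, size=n_frags)).astype(int)
            else:
                raise ValueError(f"unknown fragment distribution: {frag_dist}")
            lfs = np.clip(lfs, lo_bound, hi_bound if hi_bound else None)
            lfs = np.minimum(lfs, len(seq))
            starts = (rng.random(n_frags) * (len(seq) - lfs + 1)).astype(int)
            for start, lf in zip(starts, lfs):
                frag = seq[start : start + lf]
                r1 = frag[:L]
                r2 = reverse_complement(frag[-L:])
                if error_rate > 0:
                    r1 = _mutate(r1, error_rate, rng)
                    r2 = _mutate(r2, error_rate, rng)
                pair_no += 1
                yield ReadPair(f"sim{pair_no}:h{h}:{chrom}", r1, r2)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def write_fastq(pairs: Iterable[ReadPair], path1: str, path2: str) -> int:
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = p.qual1 or "I" * len(p.seq1)
            q2 = p.qual2 or "I" * len(p.seq2)
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")
            n += 1
    return n


def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str) -> dict[str, str]:
    import pysam

    out = {}
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            out[rec.name] = rec.sequence.upper()
    return out


# ---------------------------------------------------------------------------
# evaluation


_TRANSLOC_AMBIGUOUS = {"translocation_intra_up", "translocation_intra_down"}


def _family(type_name: str) -> str:
    for fam in ("insertional_duplication", "translocation"):
        if type_name.startswith(fam):
            return fam
    return type_name


def _type_compatible(truth_type: str, call_type: str) -> bool:
    if truth_type == call_type:
        return True
    # moving [s,e) upstream equals moving [p,s) downstream: same sample sequence
    return truth_type in _TRANSLOC_AMBIGUOUS and call_type in _TRANSLOC_AMBIGUOUS


def _coords_match(truth: SimulatedSV, call: SVCall, tol: int) -> bool:
    t = sorted(truth.coords.values())
    c = sorted(call.breakpoints.values())
    if len(t) != len(c):
        return False
    for (tc, tp), (cc, cp) in zip(t, c):
        if tc != cc or abs(tp - cp) > tol:
            return False
    return True


@dataclass
class TypeEvaluation:
    n_truth: int = 0
    n_calls: int = 0
    n_recalled: int = 0
    n_partial: int = 0  # translocations recovered as insertional duplications

    @property
    def recall(self) -> float:
        return self.n_recalled / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_recalled / self.n_calls if self.n_calls else float("nan")


def evaluate_calls(
    calls: list[SVCall],
    truth: TruthSet,
    tolerance: Optional[dict[str, int] | int] = None,
) -> dict[str, TypeEvaluation]:
    """Per-type recall/precision of a call set against planted truth.

    A planted event is recalled when a same-type call places every breakpoint
    within the per-type tolerance (1-to-1 matching).  Intrachromosomal
    non-inverted translocations planted up- or downstream are equivalent
    descriptions of the same sample sequence and match either call type.
    Translocations additionally tally insertional-duplication calls at the
    same coordinates as partial-signature recoveries.
    """
    if tolerance is None:
        tolerance = {}
    out: dict[str, TypeEvaluation] = {}
    used: set[int] = set()
    by_type = truth.by_type()
    for type_name, events in sorted(by_type.items()):
        tol = (
            tolerance
            if isinstance(tolerance, int)
            else tolerance.get(type_name, DEFAULT_EVAL_TOLERANCE.get(_family(type_name), 10))
        )
        ev = out.setdefault(type_name, TypeEvaluation())
        ev.n_truth += len(events)
        for sv in events:
            hit = None
            for idx, call in enumerate(calls):
                if idx in used or not _type_compatible(sv.type, call.type):
                    continue
                if _coords_match(sv, call, tol):
                    hit = idx
                    break
            if hit is not None:
                used.add(hit)
                ev.n_recalled += 1
            elif _family(type_name) == "translocation":
                suffix = "_inverted" if type_name.endswith("_inverted") else ""
                for idx, call in enumerate(calls):
                    if idx in used or _family(call.type) != "insertional_duplication":
                        continue
                    if call.type.endswith("_inverted") != bool(suffix):
                        continue
                    if _coords_match(sv, call, tol):
                        used.add(idx)
                        ev.n_partial += 1
                        break
    for call in calls:
        fam_counted = False
        for type_name, ev in out.items():
            if _type_compatible(type_name, call.type):
                ev.n_calls += 1
                fam_counted = True
                break
        if not fam_counted:
            out.setdefault(call.type, TypeEvaluation()).n_calls += 1
    return out


def write_evaluation_tsv(result: dict[str, TypeEvaluation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("type\tn_truth\tn_calls\tn_recalled\tn_partial\trecall\tprecision\n")
        for t, ev in sorted(result.items()):
            fh.write(
                f"{t}\t{ev.n_truth}\t{ev.n_calls}\t{ev.n_recalled}\t{ev.n_partial}\t"
                f"{ev.recall:.4f}\t{ev.precision:.4f}\n"
            )


def make_noise_calls(
    reference: dict[str, str], n: int, seed: int | np.random.Generator = 0,
    sample: str = "",
) -> list[SVCall]:
    """Synthetic weight-1 artifact calls (models library-preparation noise).

    Emulates the sample-specific low-confidence class of calls: single-base
    insertions at random positions, each supported by one read pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(reference)
    out = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(0, len(reference[c])))
        base = BASES[int(rng.integers(4))]
        out.append(SVCall("insertion", {"site": (c, p)}, base, weight=1, sample=sample))
    return out
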