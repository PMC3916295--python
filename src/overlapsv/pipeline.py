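"""End-to-end orchestration: reads -> fragments -> classification -> calls.

The stages mirror the method: (1) merge each read pair through its central
overlap into the exact fragment; (2) place both 5' seeds and classify the
pair exactly against l_f; (3) localize breakpoints of discordant pairs by
glocal alignment against the minimal reference; (4) assemble the discordant
graph and identify components by prototype isomorphism; (5) optionally
compute coverage tracks and zygosity.  Everything is deterministic given the
inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import breakpointing, coverage, seeding, svgraph
from .config import PipelineConfig, DEFAULT_CONFIG
from .fragments import ReadPair, reconstruct_fragment
from .seeding import CONCORDANT, DISCORDANT, SeedIndex
from .svgraph import SVCall


@dataclass
class PipelineCounts:
    n_pairs: int = 0
    n_reconstructed: int = 0
    n_ambiguous_overlap: int = 0
    n_usable: int = 0
    n_concordant: int = 0
    n_discordant: int = 0
    n_evidence: int = 0
    n_dropped_breakpointing: int = 0


@dataclass
class PipelineResult:
    calls: list[SVCall]
    residual: list[svgraph.Component]
    graph: svgraph.DiscordantGraph
    counts: PipelineCounts
    concordant_track: Optional[coverage.CoverageTrack] = None
    discordant_track: Optional[coverage.CoverageTrack] = None


def classify_pairs(
    pairs: Iterable[ReadPair],
    reference: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
    index: Optional[SeedIndex] = None,
):
    """Generator over (pair, fragment, seed placement, label) tuples.

    Pairs that do not overlap perfectly or whose seeds are not both unique
    come through with fragment/label None -- callers decide what to drop.
    """
    if index is None:
        index = SeedIndex(reference, k=config.seed_length, max_mismatch=config.max_mismatch)
    for pair in pairs:
        frag = reconstruct_fragment(pair, config.min_overlap)
        if frag is None:
            yield pair, None, None, None
            continue
        aln = seeding.place_pair(pair, index)
        if not aln.usable:
            yield pair, frag, aln, None
            continue
        label = seeding.classify_pair(aln, frag, k=config.seed_length)
        aln.label = label
        yield pair, frag, aln, label


def run_pipeline(
    reference: dict[str, str],
    pairs: Iterable[ReadPair],
    config: PipelineConfig = DEFAULT_CONFIG,
    sample: str = "",
    with_coverage: bool = False,
    with_zygosity: bool = False,
) -> PipelineResult:
    """Run the full caller over an in-memory reference and read stream."""
    counts = PipelineCounts()
    index = SeedIndex(reference, k=config.seed_length, max_mismatch=config.max_mismatch)
    evidence = []
    conc_intervals: list[tuple[str, int, int]] = []
    disc_intervals: list[tuple[str, int, int]] = []
    want_cov = with_coverage or with_zygosity
    k = config.seed_length

    for pair, frag, aln, label in classify_pairs(pairs, reference, config, index):
        counts.n_pairs += 1
        if frag is None:
            continue
        counts.n_reconstructed += 1
        if frag.ambiguous:
            counts.n_ambiguous_overlap += 1
        if label is None:
            continue
        counts.n_usable += 1
        l_f = frag.length
        if label == CONCORDANT:
            counts.n_concordant += 1
            if want_cov:
                start = aln.pos1 if aln.strand1 == "+" else aln.pos2
                conc_intervals.append((aln.chrom1, start, start + l_f))
            continue
        counts.n_discordant += 1
        if want_cov:
            if aln.strand1 == "+":
                disc_intervals.append((aln.chrom1, aln.pos1, aln.pos1 + l_f))
            else:
                disc_intervals.append((aln.chrom1, aln.pos1 + k - l_f, aln.pos1 + k))
            if aln.strand2 == "-":
                disc_intervals.append((aln.chrom2, aln.pos2 + k - l_f, aln.pos2 + k))
            else:
                disc_intervals.append((aln.chrom2, aln.pos2, aln.pos2 + l_f))
        ev = breakpointing.fragment_evidence(aln, frag, reference, config)
        if ev is None:
            counts.n_dropped_breakpointing += 1
        else:
            counts.n_evidence += 1
            evidence.append(ev)

    graph = svgraph.build_discordant_graph(evidence, config)
    calls, residual = svgraph.call_svs(
        graph, mrw=config.mrw, reference=reference, sample=sample
    )
    result = PipelineResult(calls, residual, graph, counts)
    if want_cov:
        result.concordant_track = coverage.compute_coverage(
            conc_intervals, reference, "concordant"
        )
        result.discordant_track = coverage.compute_coverage(
            disc_intervals, reference, "discordant"
        )
    if with_zygosity:
        coverage.annotate_zygosity(calls, result.concordant_track, config)
    return result
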