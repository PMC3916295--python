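"""Concordant/discordant coverage tracks and zygosity inference.

Concordant pairs project their full fragment span onto the reference;
discordant pairs project both seed-anchored windows.  The concordant track
carries the zygosity signal: a homozygous SV removes both wildtype alleles,
so concordant coverage at its breakpoints drops to ~0, while a heterozygous
SV retains one wildtype allele and shows ~50% of the local background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .svgraph import SVCall

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
LOW_CONFIDENCE = "low_confidence"


@dataclass
class CoverageTrack:
    data: dict[str, np.ndarray]
    label: str = "concordant"

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.data.values()))


def compute_coverage(
    intervals: Iterable[tuple[str, int, int]],
    reference: dict[str, str],
    label: str = "concordant",
) -> CoverageTrack:
    """Per-base count of pair projections over the genome.

    Each (chrom, start, end) interval increments every covered base;
    intervals are clipped to chromosome bounds.
    """
    diffs = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in reference.items()}
    for chrom, start, end in intervals:
        arr = diffs[chrom]
        s = max(0, start)
        e = min(len(arr) - 1, end)
        if e > s:
            arr[s] += 1
            arr[e] -= 1
    data = {c: np.cumsum(d[:-1]).astype(np.int64) for c, d in diffs.items()}
    return CoverageTrack(data, label)


def infer_zygosity(
    call: SVCall,
    concordant: CoverageTrack,
    config: PipelineConfig = DEFAULT_CONFIG,
    flank: int = 1000,
) -> str:
    """Classify a call from its breakpoint concordant coverage.

    r = mean concordant coverage over the breakpoints divided by the median
    background over +-``flank`` around the event.  r <= 0.1 -> homozygous
    (no wildtype allele), 0.3 <= r <= 0.7 -> heterozygous; anything else --
    including calls whose breakpoints keep full wildtype coverage, the
    technical-error class -- is low_confidence.
    """
    coords = sorted(call.breakpoints.values())
    values = []
    background = []
    for chrom, pos in coords:
        arr = concordant.data.get(chrom)
        if arr is None or arr.size == 0:
            return LOW_CONFIDENCE
        p = min(max(pos, 0), arr.size - 1)
        # breakpoints sit between bases: the affected side is the lower one
        # (a deletion's end coordinate is the first *retained* base)
        values.append(min(arr[p], arr[max(0, p - 1)]))
        lo = max(0, p - flank)
        hi = min(arr.size, p + flank)
        background.append(np.median(arr[lo:hi]))
    bg = float(np.median(background))
    if bg <= 0:
        return LOW_CONFIDENCE
    r = float(np.mean(values)) / bg
    if r <= config.zygosity_hom_max:
        return HOMOZYGOUS
    if config.zygosity_het_min <= r <= config.zygosity_het_max:
        return HETEROZYGOUS
    return LOW_CONFIDENCE


def annotate_zygosity(
    calls: list[SVCall],
    concordant: CoverageTrack,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> None:
    for call in calls:
        call.zygosity = infer_zygosity(call, concordant, config)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """bedGraph export; adjacent equal values merge into one interval."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.label}"\n')
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str, reference: dict[str, str], label: str = "") -> CoverageTrack:
    data = {c: np.zeros(len(s), dtype=np.int64) for c, s in reference.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.split("\t")
            data[chrom][int(s) : int(e)] = int(v)
    return CoverageTrack(data, label)
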