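"""Pipeline configuration.

All tunable parameters of the caller live in one dataclass so that the CLI,
the library API and the test-suite agree on defaults.  The defaults encode
the published protocol for 150 bp overlapping paired-end libraries:
a perfect read overlap of at least 13 bases (so reconstructable fragments are
at most 2*150-13 = 287 bp long), 30 bp 5'-end seeds placed with at most one
mismatch, and an affine-gap global alignment with gap open 10 and gap
extension 0.5 per base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


@dataclass
class PipelineConfig:
    #: read length L of both mates
    read_length: int = 150
    #: minimum perfect overlap between mates required for fragment reconstruction
    min_overlap: int = 13
    #: seed length k (5' prefix of each read used for genome placement)
    seed_length: int = 30
    #: maximum mismatches allowed when placing a seed
    max_mismatch: int = 1
    #: substitution scores of the glocal fragment-vs-minimal-reference alignment
    match: float = 5.0
    mismatch: float = -4.0
    #: affine gap model: a gap of length g costs gap_open + gap_extend * g
    gap_open: float = 10.0
    gap_extend: float = 0.5
    #: minimum identity outside gaps for a breakpoint alignment to be trusted
    min_identity: float = 0.95
    #: extra score tolerance (in score units per shifted base) when enumerating
    #: equivalent breakpoint placements; 0 keeps exact co-optima only
    placement_tolerance: int = 0
    #: cap on enumerated co-optimal placements per fragment
    max_placements: int = 64
    #: minimum required weight (read pairs supporting each edge) for a call
    mrw: int = 1
    #: maximum genomic span of a derived donor-adjacency (type e) edge;
    #: bounded by the largest donor an insertional duplication may copy
    e_max_span: int = 1000
    #: insertions at least this long are re-aligned to the reference to detect
    #: insertional duplications of short donors from a single fragment
    min_realign_length: int = 30
    #: zygosity classification on r = breakpoint concordant coverage / background
    zygosity_hom_max: float = 0.1
    zygosity_het_min: float = 0.3
    zygosity_het_max: float = 0.7
    #: breakpoint intersection tolerances between two samples
    tol_indel: int = 1
    tol_complex: int = 10
    #: random seed used by any stochastic helper (simulation, subsampling)
    seed: int = 0

    @property
    def max_fragment_length(self) -> int:
        """Longest fragment whose mates still overlap by ``min_overlap``."""
        return 2 * self.read_length - self.min_overlap

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(mapping))


DEFAULT_CONFIG = PipelineConfig()
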