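"""One-call drivers chaining the pipeline stages with default thresholds."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotate import (CandidateInterval, LTRHit, LTRLibrary, build_library,
                       cluster_hits, extract_sequences, filter_scaffolds,
                       intersect_candidates, scan_genome)
from .classify import (FormationStats, LTRPair, SoloLTR,
                       compute_formation_stats, pair_ltrs)


@dataclass
class DiscoveryResult:
    library: LTRLibrary
    hits: list[LTRHit]          # clustered, scaffold-filtered
    pairs: list[LTRPair]
    solos: list[SoloLTR]
    stats: FormationStats


def discover(genome: dict[str, str],
             set_a: Sequence[CandidateInterval],
             set_b: Sequence[CandidateInterval],
             *,
             library: LTRLibrary | None = None,
             min_identity: float = 65.0,
             min_qcov: float = 80.0,
             min_scaffold_len: int = 20_000,
             window: int = 20_000,
             min_pair_identity: float = 85.0) -> DiscoveryResult:
    """Full solo-LTR discovery on one genome.

    Intersect the two candidate annotation sources, build the non-redundant
    LTR library (unless one is supplied), scan the genome, keep the best hit
    per locus on scaffolds >= ``min_scaffold_len``, then split hits into
    pairs and solo-LTRs by reciprocal best hit.
    """
    if library is None:
        intervals = intersect_candidates(set_a, set_b)
        library = build_library(extract_sequences(genome, intervals))
    hits = scan_genome(genome, library, min_identity, min_qcov)
    hits = cluster_hits(hits)
    lengths = {name: len(seq) for name, seq in genome.items()}
    hits = filter_scaffolds(hits, lengths, min_scaffold_len)
    pairs, solos = pair_ltrs(hits, genome, window, min_pair_identity)
    stats = compute_formation_stats(pairs, solos, genome)
    return DiscoveryResult(library, hits, pairs, solos, stats)
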