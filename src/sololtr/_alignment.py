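"""Shared pairwise-alignment helpers.

One scoring scheme is used throughout the pipeline (match +1, mismatch -2,
gap open -5, gap extend -2), so hit scores, pair identities and library
cluster identities are all directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Seq import reverse_complement

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -5
GAP_EXTEND = -2


def revcomp(seq: str) -> str:
    return str(reverse_complement(seq))


@lru_cache(maxsize=None)
def _aligner(mode: str, free_ends: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    if free_ends:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query against a target window."""

    score: float
    identity: float        # percent, matches / aligned columns (internal gaps count)
    query_start: int
    query_end: int
    target_start: int
    target_end: int

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def local_align(query: str, target: str) -> LocalAlignment | None:
    """Smith-Waterman style local alignment (affine gaps), best hit only."""
    if not query or not target:
        return None
    aligner = _aligner("local")
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    if columns == 0:
        return None
    identity = 100.0 * counts.identities / columns
    # rows: target=query sequence (first argument), query=window (second)
    qstart, qend = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
    tstart, tend = int(aln.coordinates[1, 0]), int(aln.coordinates[1, -1])
    return LocalAlignment(float(aln.score), identity, qstart, qend, tstart, tend)


def global_identity(a: str, b: str) -> float:
    """Percent identity of a global alignment: matches over all columns,
    terminal gap columns included."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    aln = _aligner("global").align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def pair_identity(a: str, b: str) -> float:
    """Percent identity of the two LTR copies of a candidate pair.

    Global alignment (terminal gaps penalized, so the alignment spans both
    sequences); identity is matches over the aligned core columns (internal
    gaps count, terminal overhang columns are excluded, matching the
    module-wide identity definition).
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    aln = _aligner("global").align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    if columns == 0:
        return 0.0
    return 100.0 * counts.identities / columns


def cluster_identity(shorter: str, longer: str) -> tuple[float, float]:
    """Identity used by the 95% redundancy clustering.

    Local alignment of the shorter sequence against the longer; returns
    (percent identity over the aligned region, fraction of the shorter
    sequence covered by the aligned region).
    """
    if len(shorter) > len(longer):
        shorter, longer = longer, shorter
    aln = local_align(shorter, longer)
    if aln is None:
        return 0.0, 0.0
    coverage = aln.query_span / len(shorter)
    return aln.identity, coverage
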