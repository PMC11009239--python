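"""LTR library construction and genome scanning.

Stands in for the RepeatMasker/LTR-harvest + cd-hit + blastn stage of the
solo-LTR identification pipeline: intersect two candidate annotation
sources, cluster the sequences into a non-redundant library at 95%
similarity, then re-scan each genome with the library as query (65%
identity, 80% query coverage) and keep the best hit per locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from ._alignment import cluster_identity, local_align, revcomp

logger = logging.getLogger(__name__)

MIN_LTR_LEN = 100
MAX_LTR_LEN = 1000
SEED_K = 11


class CandidateInterval(NamedTuple):
    scaffold: str
    start: int
    end: int
    source: str = "A"


@dataclass(frozen=True)
class LibraryEntry:
    id: str
    family: str
    sequence: str


@dataclass
class LTRLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)
    clustering_identity: float = 0.95

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class LTRHit:
    scaffold: str
    start: int
    end: int
    strand: str
    library_id: str
    family: str
    identity: float         # percent
    query_coverage: float   # percent
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: dict[str, str]) -> str:
        seq = genome[self.scaffold][self.start:self.end]
        return revcomp(seq) if self.strand == "-" else seq


def _validate_intervals(intervals: Iterable[CandidateInterval], label: str) -> None:
    for iv in intervals:
        if iv.start >= iv.end or iv.start < 0:
            raise ValueError(f"malformed interval in set {label}: {iv}")


def intersect_candidates(set_a: Sequence[CandidateInterval],
                         set_b: Sequence[CandidateInterval],
                         min_len: int = MIN_LTR_LEN,
                         max_len: int = MAX_LTR_LEN) -> list[CandidateInterval]:
    """Pairwise intersections of the two candidate sets, kept when the
    overlap interval length is within [min_len, max_len]."""
    _validate_intervals(set_a, "A")
    _validate_intervals(set_b, "B")
    by_scaffold: dict[str, list[CandidateInterval]] = {}
    for iv in set_b:
        by_scaffold.setdefault(iv.scaffold, []).append(iv)
    for ivs in by_scaffold.values():
        ivs.sort(key=lambda x: x.start)
    out: list[CandidateInterval] = []
    for a in set_a:
        for b in by_scaffold.get(a.scaffold, ()):
            if b.start >= a.end:
                break
            start, end = max(a.start, b.start), min(a.end, b.end)
            if min_len <= end - start <= max_len:
                out.append(CandidateInterval(a.scaffold, start, end, "AB"))
    out.sort(key=lambda iv: (iv.scaffold, iv.start, iv.end))
    return out


def extract_sequences(genome: dict[str, str],
                      intervals: Sequence[CandidateInterval],
                      family: str = "LTR") -> list[tuple[str, str, str]]:
    """(id, family, sequence) triples for library construction; ids encode
    the coordinates."""
    return [(f"{iv.scaffold}:{iv.start}-{iv.end}", family,
             genome[iv.scaffold][iv.start:iv.end]) for iv in intervals]


def build_library(sequences: Sequence[tuple[str, str, str]],
                  identity: float = 0.95,
                  min_coverage: float = 0.9) -> LTRLibrary:
    """Greedy longest-first redundancy clustering at ``identity``.

    A sequence is retained iff, against every already-retained
    representative, its aligned identity is < ``identity`` or the aligned
    region covers < ``min_coverage`` of the shorter sequence.
    """
    if not sequences:
        logger.warning("build_library: empty input, returning empty library")
        return LTRLibrary(clustering_identity=identity)
    kept_input = [s for s in sequences if MIN_LTR_LEN <= len(s[2]) <= MAX_LTR_LEN]
    rejected = len(sequences) - len(kept_input)
    if rejected:
        logger.info("build_library: rejected %d sequences outside [%d, %d] bp",
                    rejected, MIN_LTR_LEN, MAX_LTR_LEN)
    kept_input.sort(key=lambda s: (-len(s[2]), s[0]))
    retained: list[LibraryEntry] = []
    for seq_id, family, seq in kept_input:
        redundant = False
        for rep in retained:
            ident, coverage = cluster_identity(seq, rep.sequence)
            if ident >= identity * 100.0 and coverage >= min_coverage:
                redundant = True
                break
        if not redundant:
            retained.append(LibraryEntry(seq_id, family, seq))
    return LTRLibrary(entries=retained, clustering_identity=identity)


def _seed_windows(query: str, index: dict[str, list[int]], pad: int,
                  target_len: int) -> list[tuple[int, int]]:
    """Candidate target windows from exact k-mer seed matches, merged."""
    positions: list[int] = []
    for qpos in range(0, len(query) - SEED_K + 1):
        positions.extend(index.get(query[qpos:qpos + SEED_K], ()))
    if not positions:
        return []
    positions.sort()
    windows: list[list[int]] = []
    for pos in positions:
        if windows and pos - windows[-1][1] <= pad:
            windows[-1][1] = pos
        else:
            windows.append([pos, pos])
    return [(max(0, a - pad), min(target_len, b + SEED_K + pad))
            for a, b in windows]


def _kmer_index(seq: str) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(0, len(seq) - SEED_K + 1):
        index.setdefault(seq[i:i + SEED_K], []).append(i)
    return index


def _hits_in_window(query: str, scaffold_seq: str, win_start: int, win_end: int,
                    min_identity: float, min_qcov: float, max_span: int,
                    out: list[tuple[int, int, float, float, float]],
                    depth: int = 0) -> None:
    """Best local alignment in the window, then recurse left/right of it so
    several nearby copies of one query are all reported."""
    window = scaffold_seq[win_start:win_end]
    aln = local_align(query, window)
    if aln is None or aln.score < SEED_K:
        return
    qcov = 100.0 * aln.query_span / len(query)
    start, end = win_start + aln.target_start, win_start + aln.target_end
    if (aln.identity >= min_identity and qcov >= min_qcov
            and end - start <= max_span):
        out.append((start, end, aln.identity, qcov, aln.score))
    if depth >= 4:
        return
    if start - win_start >= len(query) // 2:
        _hits_in_window(query, scaffold_seq, win_start, start, min_identity,
                        min_qcov, max_span, out, depth + 1)
    if win_end - end >= len(query) // 2:
        _hits_in_window(query, scaffold_seq, end, win_end, min_identity,
                        min_qcov, max_span, out, depth + 1)


def scan_genome(genome: dict[str, str], library: LTRLibrary,
                min_identity: float = 65.0, min_qcov: float = 80.0) -> list[LTRHit]:
    """Seed-and-extend scan of every library entry against every scaffold.

    Exact 11-mer seed matches nominate windows; each window is resolved by
    local alignment with the pipeline scoring scheme. A hit is reported iff
    identity >= ``min_identity`` and query coverage >= ``min_qcov``
    (percent); hits longer than 1.5x the query are discarded as pathological.
    """
    if not genome:
        raise ValueError("genome is empty")
    if len(library) == 0:
        raise ValueError("library is empty")
    hits: list[LTRHit] = []
    for scaffold, seq in genome.items():
        index = _kmer_index(seq)
        for entry in library:
            max_span = int(1.5 * len(entry.sequence))
            for strand in "+-":
                query = entry.sequence if strand == "+" else revcomp(entry.sequence)
                raw: list[tuple[int, int, float, float, float]] = []
                for win_start, win_end in _seed_windows(query, index,
                                                        len(query), len(seq)):
                    _hits_in_window(query, seq, win_start, win_end,
                                    min_identity, min_qcov, max_span, raw)
                hits.extend(LTRHit(scaffold, start, end, strand, entry.id,
                                   entry.family, ident, qcov, score)
                            for start, end, ident, qcov, score in raw)
    hits.sort(key=lambda h: (h.scaffold, h.start, h.end, h.strand, h.library_id))
    return hits


def cluster_hits(hits: Sequence[LTRHit]) -> list[LTRHit]:
    """Single-linkage clustering of overlapping hits per scaffold; one hit
    per cluster survives: highest score, then highest identity, then
    smallest start."""
    by_scaffold: dict[str, list[LTRHit]] = {}
    for hit in hits:
        by_scaffold.setdefault(hit.scaffold, []).append(hit)
    out: list[LTRHit] = []
    for scaffold in sorted(by_scaffold):
        group = sorted(by_scaffold[scaffold], key=lambda h: (h.start, h.end))
        cluster: list[LTRHit] = []
        cluster_end = -1
        for hit in group:
            if cluster and hit.start >= cluster_end:
                out.append(_best_of(cluster))
                cluster = []
            cluster.append(hit)
            cluster_end = max(cluster_end, hit.end)
        if cluster:
            out.append(_best_of(cluster))
    out.sort(key=lambda h: (h.scaffold, h.start))
    return out


def _best_of(cluster: Sequence[LTRHit]) -> LTRHit:
    return max(cluster, key=lambda h: (h.score, h.identity, -h.start))


def filter_scaffolds(hits: Sequence[LTRHit], scaffold_lengths: dict[str, int],
                     min_len: int = 20_000) -> list[LTRHit]:
    """Drop hits on scaffolds shorter than ``min_len`` (assembly-quality
    guard)."""
    for hit in hits:
        if hit.scaffold not in scaffold_lengths:
            raise ValueError(f"hit on unknown scaffold {hit.scaffold!r}")
    kept = [h for h in hits if scaffold_lengths[h.scaffold] >= min_len]
    removed = len(hits) - len(kept)
    if removed:
        logger.info("filter_scaffolds: removed %d hits on scaffolds < %d bp",
                    removed, min_len)
    return kept
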