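"""Partition LTR hits into paired LTRs (intact ERVs) and solo-LTRs.

The two LTRs of one provirus are each other's closest relatives in the
genome, so pairing is by reciprocal best hit: candidate partners lie on the
same scaffold and strand within 20 kb, "best" is pairwise global-alignment
identity, and a pair stands iff the two hits choose each other at >= 85%
identity. Unpaired hits are solo-LTRs. Target-site duplications (the 4-6 bp
host duplication flanking an integration) are verified as exact common
substrings of the two flanks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

from ._alignment import pair_identity
from .annotate import LTRHit

PAIR_WINDOW = 20_000
MIN_PAIR_IDENTITY = 85.0


@dataclass(frozen=True)
class LTRPair:
    hit_left: LTRHit
    hit_right: LTRHit
    inner_gap: int
    pair_identity: float


@dataclass
class SoloLTR:
    hit: LTRHit
    family: str
    tsd: "TSDReport | None" = None

    @property
    def id(self) -> str:
        return f"{self.hit.scaffold}:{self.hit.start}-{self.hit.end}"


@dataclass(frozen=True)
class TSDReport:
    flank_length: int
    motif_length: int
    motif: str
    left_offset: int     # motif start within the upstream flank
    right_offset: int    # motif start within the downstream flank
    passed: bool
    reason: str = ""


@dataclass
class FamilyStats:
    total_ltr_bp: int = 0
    solo_bp: int = 0
    paired_bp: int = 0
    solo_count: int = 0
    pair_count: int = 0
    formation_ratio: float = math.nan

    def finish(self) -> None:
        self.total_ltr_bp = self.solo_bp + self.paired_bp
        if self.total_ltr_bp:
            self.formation_ratio = self.solo_bp / self.total_ltr_bp


@dataclass
class FormationStats:
    genome_size: int
    total_ltr_bp: int
    solo_bp: int
    paired_bp: int
    solo_count: int
    pair_count: int
    proportion: float        # solo_bp / genome_size
    formation_ratio: float   # solo_bp / total LTR bp
    families: dict[str, FamilyStats] = field(default_factory=dict)


def _check_no_overlap(hits: Sequence[LTRHit]) -> None:
    by_scaffold: dict[str, list[LTRHit]] = {}
    for hit in hits:
        by_scaffold.setdefault(hit.scaffold, []).append(hit)
    for group in by_scaffold.values():
        group.sort(key=lambda h: h.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping hits {a.scaffold}:{a.start}-{a.end} and "
                    f"{b.scaffold}:{b.start}-{b.end}; run cluster_hits first")


def _gap(a: LTRHit, b: LTRHit) -> int:
    """Distance between facing boundaries; a precedes b."""
    return b.start - a.end


def pair_ltrs(hits: Sequence[LTRHit], genome: dict[str, str] | None = None,
              window: int = PAIR_WINDOW,
              min_pair_identity: float = MIN_PAIR_IDENTITY,
              distance_mode: str = "gap",
              identity_fn: Callable[[LTRHit, LTRHit], float] | None = None
              ) -> tuple[list[LTRPair], list[SoloLTR]]:
    """Reciprocal-best-hit pairing; everything unpaired becomes a solo-LTR.

    Mutual-best pairs are extracted greedily in descending identity with
    deterministic tie-breaks (smaller inner gap, then smaller partner
    start), so the result does not depend on input order. ``identity_fn``
    overrides the genome-based pairwise identity (used for testing).
    """
    if distance_mode not in ("gap", "span"):
        raise ValueError("distance_mode must be 'gap' or 'span'")
    hits = sorted(hits, key=lambda h: (h.scaffold, h.start, h.end, h.strand))
    _check_no_overlap(hits)
    if identity_fn is None:
        if genome is None:
            raise ValueError("either genome or identity_fn is required")

        def identity_fn(a: LTRHit, b: LTRHit) -> float:
            return pair_identity(a.sequence(genome), b.sequence(genome))

    # candidate edges: same scaffold, same strand, within the distance window
    n = len(hits)
    edges: dict[tuple[int, int], float] = {}
    neighbours: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = hits[i], hits[j]
            if a.scaffold != b.scaffold:
                break
            if a.strand != b.strand:
                continue
            distance = _gap(a, b) if distance_mode == "gap" else b.end - a.start
            if distance > window:
                continue
            ident = identity_fn(a, b)
            if ident >= min_pair_identity:
                edges[(i, j)] = ident
                neighbours[i].append(j)
                neighbours[j].append(i)

    def edge(i: int, j: int) -> float:
        return edges[(i, j) if i < j else (j, i)]

    def pair_gap(i: int, j: int) -> int:
        i, j = min(i, j), max(i, j)  # hits are start-sorted
        return _gap(hits[i], hits[j])

    def best_partner(i: int, free: set[int]) -> int | None:
        candidates = [j for j in neighbours[i] if j in free]
        if not candidates:
            return None
        return min(candidates,
                   key=lambda j: (-edge(i, j), pair_gap(i, j), hits[j].start))

    free = set(range(n))
    pairs: list[LTRPair] = []
    while True:
        best = {i: best_partner(i, free) for i in free}
        mutual = [(i, j) for i in free
                  if (j := best[i]) is not None and i < j and best[j] == i]
        if not mutual:
            break
        mutual.sort(key=lambda ij: (-edge(*ij),
                                    _gap(hits[ij[0]], hits[ij[1]]),
                                    hits[ij[0]].scaffold, hits[ij[0]].start))
        for i, j in mutual:
            left, right = hits[i], hits[j]
            pairs.append(LTRPair(left, right, _gap(left, right), edge(i, j)))
            free.discard(i)
            free.discard(j)
    solos = [SoloLTR(hit=hits[i], family=hits[i].family) for i in sorted(free)]
    pairs.sort(key=lambda p: (p.hit_left.scaffold, p.hit_left.start))
    return pairs, solos


def verify_tsd(genome: dict[str, str],
               intervals: tuple[int, int] | Sequence[tuple[int, int]],
               scaffold: str, flank_length: int = 10,
               min_motif: int = 4, max_motif: int = 6) -> TSDReport:
    """Exact TSD check: does some 4-6 bp substring occur in both the
    ``flank_length`` bp immediately upstream and downstream of the element?

    ``intervals`` is one interval for a solo-LTR or the two LTR intervals of
    a pair (flanks are taken outside the outermost boundaries). The longest
    motif is reported, leftmost in the upstream flank on ties.
    """
    if flank_length not in (10, 15, 20):
        raise ValueError("flank_length must be one of 10, 15, 20")
    if isinstance(intervals[0], int):
        intervals = [intervals]  # type: ignore[list-item]
    start = min(a for a, _ in intervals)
    end = max(b for _, b in intervals)
    seq = genome[scaffold]
    if start < flank_length or end + flank_length > len(seq):
        return TSDReport(flank_length, 0, "", -1, -1, False, "edge")
    left = seq[start - flank_length:start]
    right = seq[end:end + flank_length]
    for motif_len in range(max_motif, min_motif - 1, -1):
        for offset in range(0, flank_length - motif_len + 1):
            motif = left[offset:offset + motif_len]
            pos = right.find(motif)
            if pos >= 0:
                return TSDReport(flank_length, motif_len, motif, offset, pos, True)
    return TSDReport(flank_length, 0, "", -1, -1, False, "no_motif")


def compute_formation_stats(pairs: Sequence[LTRPair], solos: Sequence[SoloLTR],
                            genome_size: int | dict[str, str]) -> FormationStats:
    """Per-genome solo-LTR statistics: the solo proportion of the genome and
    the formation ratio solo_bp / (solo_bp + paired_bp)."""
    if isinstance(genome_size, dict):
        genome_size = sum(len(s) for s in genome_size.values())
    families: dict[str, FamilyStats] = {}

    def fam(name: str) -> FamilyStats:
        return families.setdefault(name, FamilyStats())

    solo_bp = paired_bp = 0
    for solo in solos:
        solo_bp += solo.hit.length
        fam(solo.family).solo_bp += solo.hit.length
        fam(solo.family).solo_count += 1
    for pair in pairs:
        bp = pair.hit_left.length + pair.hit_right.length
        paired_bp += bp
        fam(pair.hit_left.family).paired_bp += bp
        fam(pair.hit_left.family).pair_count += 1
    total = solo_bp + paired_bp
    if total == 0:
        warnings.warn("no LTR bp at all: formation_ratio is undefined (NaN)")
        ratio = math.nan
    else:
        ratio = solo_bp / total
    for stats in families.values():
        stats.finish()
    return FormationStats(
        genome_size=genome_size, total_ltr_bp=total, solo_bp=solo_bp,
        paired_bp=paired_bp, solo_count=len(solos), pair_count=len(pairs),
        proportion=solo_bp / genome_size if genome_size else math.nan,
        formation_ratio=ratio, families=families)


def threshold_sweep(hits: Sequence[LTRHit], genome: dict[str, str],
                    identities: Sequence[float] = (75, 80, 85, 90, 95),
                    windows: Sequence[int] = (PAIR_WINDOW,)):
    """Formation ratio across pairing thresholds (sensitivity analysis).

    Returns a pandas DataFrame with one row per (window, min_pair_identity).
    """
    import pandas as pd

    rows = []
    for window in windows:
        for ident in identities:
            pairs, solos = pair_ltrs(hits, genome, window=window,
                                     min_pair_identity=ident)
            stats = compute_formation_stats(pairs, solos, genome)
            rows.append({"window": window, "min_pair_identity": ident,
                         "pair_count": stats.pair_count,
                         "solo_count": stats.solo_count,
                         "formation_ratio": stats.formation_ratio})
    return pd.DataFrame(rows)
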