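"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline result by the most literal method
available (exhaustive pairs, explicit recompute loops, full enumeration)
and stays independent of the implementation path it checks.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

from sololtr.annotate import CandidateInterval, LTRHit


def brute_intersections(set_a, set_b, min_len=100, max_len=1000):
    """All-pairs candidate intersection filter."""
    out = []
    for a in set_a:
        for b in set_b:
            if a.scaffold != b.scaffold:
                continue
            start, end = max(a.start, b.start), min(a.end, b.end)
            if min_len <= end - start <= max_len:
                out.append(CandidateInterval(a.scaffold, start, end, "AB"))
    return sorted(out, key=lambda iv: (iv.scaffold, iv.start, iv.end))


def brute_cluster_best(hits: Sequence[LTRHit]) -> list[LTRHit]:
    """Connected components under interval overlap (quadratic), then max by
    (score, identity, -start) per component."""
    hits = list(hits)
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = hits[i], hits[j]
            if (a.scaffold == b.scaffold and a.start < b.end and b.start < a.end):
                parent[find(i)] = find(j)
    components: dict[int, list[LTRHit]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(hits[i])
    best = [max(group, key=lambda h: (h.score, h.identity, -h.start))
            for group in components.values()]
    return sorted(best, key=lambda h: (h.scaffold, h.start))


def brute_rbh_pairs(hits: Sequence[LTRHit],
                    identity_fn: Callable[[LTRHit, LTRHit], float],
                    window: int = 20_000,
                    min_identity: float = 85.0):
    """Literal reciprocal-best-hit extraction: recompute every hit's best
    partner among the remaining hits each round, extract one mutual-best
    pair (highest identity; ties smaller gap, then smaller start), repeat.

    Returns (pairs as sets of index pairs, solo indices) over the
    start-sorted hit list.
    """
    hits = sorted(hits, key=lambda h: (h.scaffold, h.start, h.end, h.strand))

    def gap(i, j):
        i, j = min(i, j), max(i, j)
        return hits[j].start - hits[i].end

    def candidates(i, free):
        out = []
        for j in free:
            if j == i:
                continue
            a, b = hits[i], hits[j]
            if a.scaffold != b.scaffold or a.strand != b.strand:
                continue
            if gap(i, j) > window:
                continue
            ident = identity_fn(a, b)
            if ident >= min_identity:
                out.append((j, ident))
        return out

    free = set(range(len(hits)))
    pairs = []
    while True:
        best = {}
        for i in free:
            cands = candidates(i, free)
            if cands:
                best[i] = min(cands, key=lambda ji: (-ji[1], gap(i, ji[0]),
                                                     hits[ji[0]].start))
        mutual = [(i, j, ident) for i, (j, ident) in best.items()
                  if i < j and best.get(j, (None,))[0] == i]
        if not mutual:
            break
        i, j, ident = min(mutual, key=lambda m: (-m[2], gap(m[0], m[1]),
                                                 hits[m[0]].scaffold,
                                                 hits[m[0]].start))
        pairs.append(frozenset((i, j)))
        free.discard(i)
        free.discard(j)
    return set(pairs), free, hits


def fisher_greater_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p by summing the probabilities of
    every table with the same margins and first cell >= a."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)
    p = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        if k >= a:
            p += math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
    return p


def pattern_tally(present) -> dict[tuple[str, ...], int]:
    """Hash-free double-loop tally of exact presence patterns."""
    rows = [tuple(col for col in present.columns if present.loc[idx, col])
            for idx in present.index]
    tally: dict[tuple[str, ...], int] = {}
    for pattern in rows:
        count = 0
        for other in rows:
            if other == pattern:
                count += 1
        tally[pattern] = count
    return tally


def make_random_hits(rng, n: int, scaffold: str = "s") -> list[LTRHit]:
    """Non-overlapping random hits on one scaffold for pairing tests."""
    hits = []
    cursor = 0
    for i in range(n):
        cursor += int(rng.integers(50, 4_000))
        length = int(rng.integers(100, 600))
        strand = "+" if rng.random() < 0.8 else "-"
        hits.append(LTRHit(scaffold, cursor, cursor + length, strand,
                           f"lib{i}", "ERVK", 90.0, 95.0, float(length)))
        cursor += length
    return hits


def make_identity_fn(rng, hits: Sequence[LTRHit]):
    """Symmetric random identity matrix over hit coordinates."""
    table = {}
    keyed = sorted((h.scaffold, h.start, h.end) for h in hits)
    for i, a in enumerate(keyed):
        for b in keyed[i + 1:]:
            table[(a, b)] = float(rng.uniform(60.0, 100.0))

    def identity_fn(x: LTRHit, y: LTRHit) -> float:
        ka, kb = (x.scaffold, x.start, x.end), (y.scaffold, y.start, y.end)
        if ka > kb:
            ka, kb = kb, ka
        return table[(ka, kb)]

    return identity_fn
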