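"""Statistical comparisons used in the solo-LTR analyses.

Welch's unequal-variance t-test (one- and two-sided), Pearson correlation
with a Fisher-z 95% confidence interval, speciation depth (internal node
counts from a named ancestor to each tip), one-sided Fisher exact
enrichment of peak overlap, and flanking-gene assignment at fixed windows.
The test statistics are computed from their closed forms; only tail
probabilities come from scipy's distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy import stats as sps

from .classify import SoloLTR

TWO_SIDED = "two_sided"
GREATER = "one_sided_greater"   # H1: mean(x) > mean(y)
LESS = "one_sided_less"


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    side: str


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class EnrichmentTable:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: interest/other; cols: overlap/not
    odds_ratio: float
    p: float


def welch_t(x: Sequence[float], y: Sequence[float],
            side: str = TWO_SIDED) -> WelchResult:
    """Welch's t-test with Welch-Satterthwaite degrees of freedom."""
    if side not in (TWO_SIDED, GREATER, LESS):
        raise ValueError(f"unknown side {side!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both samples have zero variance")
    sex, sey = vx / x.size, vy / y.size
    se = math.sqrt(sex + sey)
    t = (x.mean() - y.mean()) / se
    df = (sex + sey) ** 2 / (sex ** 2 / (x.size - 1) + sey ** 2 / (y.size - 1))
    if side == TWO_SIDED:
        p = 2.0 * sps.t.sf(abs(t), df)
    elif side == GREATER:
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    return WelchResult(float(t), float(df), float(p), side)


def pearson_ci(x: Sequence[float], y: Sequence[float],
               confidence: float = 0.95) -> PearsonResult:
    """Pearson product-moment correlation, Fisher-z confidence interval and
    a two-sided p-value from the exact t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = float(dx @ dx), float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation is undefined for a constant sample")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    n = int(x.size)
    if abs(r) == 1.0:
        p, ci_low, ci_high = 0.0, r, r
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
        z = math.atanh(r)
        zcrit = sps.norm.ppf(0.5 + confidence / 2.0)
        half = zcrit / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return PearsonResult(r, float(ci_low), float(ci_high), float(p), n)


def speciation_depth(tree: "dendropy.Tree | str", ancestor: str,
                     tips: Sequence[str]) -> dict[str, int]:
    """Number of internal nodes on the path from ``ancestor`` (inclusive) to
    each tip (tip excluded) — the per-species speciation-event count."""
    from .simulate import parse_tree, _node_key

    if isinstance(tree, str):
        tree = parse_tree(tree)
    nodes = {_node_key(node): node for node in tree.preorder_node_iter()}
    if ancestor not in nodes:
        raise ValueError(f"ancestor node {ancestor!r} not found in tree")
    anc = nodes[ancestor]
    out: dict[str, int] = {}
    for tip in tips:
        leaf = tree.find_node_with_taxon_label(tip)
        if leaf is None:
            raise ValueError(f"tip {tip!r} not found in tree")
        count = 0
        node = leaf.parent_node
        while node is not None:
            count += 1
            if node is anc:
                break
            node = node.parent_node
        else:
            raise ValueError(f"tip {tip!r} is not inside the clade of "
                             f"{ancestor!r}")
        out[tip] = count
    return out


def fisher_exact_greater(table: Sequence[Sequence[int]]) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 table: the upper
    hypergeometric tail P(X >= a) with the table's margins fixed."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    return float(sps.hypergeom.sf(a - 1, n, a + b, a + c))


def _overlaps_any(start: int, end: int,
                  sorted_starts: np.ndarray, sorted_ends: np.ndarray) -> bool:
    i = int(np.searchsorted(sorted_starts, end, side="left"))
    return bool((sorted_ends[:i] > start).any())


def peak_overlap_enrichment(solos: Sequence[SoloLTR],
                            peaks: Sequence[tuple[str, int, int]],
                            family_of_interest: str) -> EnrichmentTable:
    """One-sided Fisher exact test: are solo-LTRs of ``family_of_interest``
    enriched for >= 1 bp overlap with peaks, relative to other families?

    The p-value is the upper hypergeometric tail; the odds ratio gets a
    Haldane 0.5 correction when a cell is zero.
    """
    interest = [s for s in solos if s.family == family_of_interest]
    if not interest:
        raise ValueError(f"no solo-LTRs of family {family_of_interest!r}")
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end in peaks:
        by_scaffold.setdefault(scaffold, []).append((start, end))
    index = {}
    for scaffold, ivs in by_scaffold.items():
        ivs.sort()
        index[scaffold] = (np.array([a for a, _ in ivs]),
                           np.array([b for _, b in ivs]))

    def overlaps(solo: SoloLTR) -> bool:
        if solo.hit.scaffold not in index:
            return False
        starts, ends = index[solo.hit.scaffold]
        return _overlaps_any(solo.hit.start, solo.hit.end, starts, ends)

    a = sum(overlaps(s) for s in interest)
    b = len(interest) - a
    other = [s for s in solos if s.family != family_of_interest]
    c = sum(overlaps(s) for s in other)
    d = len(other) - c
    p = fisher_exact_greater(((a, b), (c, d)))
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentTable(((a, b), (c, d)), float(odds), p)


def flanking_genes(elements: Sequence[tuple[str, int, int]],
                   genes: Sequence[tuple[str, str, int, int]],
                   windows: Sequence[int] = (2_000, 5_000, 10_000)
                   ) -> dict[int, set[str]]:
    """Gene ids within each flanking window of any element.

    ``genes`` are (gene_id, scaffold, start, end); a gene qualifies for
    window w iff its distance to the nearest element is <= w (overlap is
    distance 0). Results are nested across increasing windows.
    """
    seen = set()
    for gene_id, *_ in genes:
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end in elements:
        by_scaffold.setdefault(scaffold, []).append((start, end))
    index = {}
    for scaffold, ivs in by_scaffold.items():
        ivs.sort()
        index[scaffold] = (np.array([a for a, _ in ivs]),
                           np.array([b for _, b in ivs]))

    out: dict[int, set[str]] = {w: set() for w in sorted(windows)}
    for gene_id, scaffold, gstart, gend in genes:
        if scaffold not in index:
            continue
        starts, ends = index[scaffold]
        # nearest element via the sorted start array
        i = int(np.searchsorted(starts, gend))
        distances = []
        if i < starts.size:
            distances.append(max(0, int(starts[i]) - gend))
        if i > 0:
            gaps = gstart - ends[:i]
            distances.append(int(max(0, gaps.min())))
        if not distances:
            continue
        nearest = min(distances)
        for w in out:
            if nearest <= w:
                out[w].add(gene_id)
    return out
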