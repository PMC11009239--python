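"""Cross-species sharing of solo-LTRs and population presence/absence.

A solo-LTR on the reference genome is "shared" when its interval is covered
by whole-genome-alignment blocks that also contain another species of the
clade of interest; otherwise it is species-specific. Shared elements are
attributed to the oldest ancestor node whose presence they force (parsimony:
presence in at least two child clades of a node implies presence in that
node's ancestor genome). At the population level, presence of an insertion
in an individual is called from read coverage over the reference interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .classify import SoloLTR


@dataclass(frozen=True)
class BlockRow:
    species: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class AlignmentBlock:
    rows: tuple[BlockRow, ...]

    def __init__(self, rows: Sequence[BlockRow]):
        object.__setattr__(self, "rows", tuple(rows))

    def species(self) -> set[str]:
        return {row.species for row in self.rows}

    def row_for(self, species: str) -> BlockRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


@dataclass
class AlignmentBlockSet:
    blocks: list[AlignmentBlock] = field(default_factory=list)
    reference: str | None = None


@dataclass
class SharingCall:
    solo_id: str
    status: str                      # "species_specific" | "shared"
    shared_with: frozenset[str]
    ancestor_attribution: str | None = None


def _covered_fraction(start: int, end: int,
                      intervals: list[tuple[int, int]]) -> float:
    """Fraction of [start, end) covered by the union of intervals."""
    if end <= start:
        return 0.0
    clipped = sorted((max(start, a), min(end, b)) for a, b in intervals
                     if min(end, b) > max(start, a))
    covered = 0
    cursor = start
    for a, b in clipped:
        a = max(a, cursor)
        if b > a:
            covered += b - a
            cursor = b
    return covered / (end - start)


def classify_sharing(solos: Sequence[SoloLTR], blocks: AlignmentBlockSet,
                     clade_species: set[str], min_overlap: float = 0.5,
                     reference: str | None = None) -> list[SharingCall]:
    """Per solo-LTR sharing status from alignment blocks.

    A species s joins ``shared_with`` iff blocks containing both the
    reference and s cover >= ``min_overlap`` of the solo interval
    (reference coordinates); the solo is shared iff shared_with is
    non-empty.
    """
    reference = reference or blocks.reference
    if reference is None:
        raise ValueError("a reference species is required")
    known = set(clade_species) | {reference}
    for block in blocks.blocks:
        unknown = block.species() - known
        if unknown:
            raise ValueError(f"alignment block references unknown species: "
                             f"{sorted(unknown)}")

    others = sorted(set(clade_species) - {reference})
    # reference-coordinate intervals of blocks containing each other species
    per_species: dict[str, dict[str, list[tuple[int, int]]]] = {
        s: {} for s in others}
    for block in blocks.blocks:
        ref_row = block.row_for(reference)
        if ref_row is None:
            continue
        for species in block.species() & set(others):
            per_species[species].setdefault(ref_row.scaffold, []).append(
                (ref_row.start, ref_row.end))

    calls = []
    for solo in solos:
        hit = solo.hit
        shared_with = frozenset(
            s for s in others
            if _covered_fraction(hit.start, hit.end,
                                 per_species[s].get(hit.scaffold, []))
            >= min_overlap)
        status = "shared" if shared_with else "species_specific"
        calls.append(SharingCall(solo.id, status, shared_with))
    return calls


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def attribute_ancestor(calls: Sequence[SharingCall], tree: "dendropy.Tree | str",
                       node_defs: Sequence[str], reference: str) -> list[SharingCall]:
    """Attribute each shared solo-LTR to the oldest listed ancestor node it
    forces: the oldest node N such that {reference} ∪ shared_with spans at
    least two distinct child clades of N. Shared calls forced by no listed
    node keep attribution None.
    """
    from .simulate import parse_tree, _node_key

    if isinstance(tree, str):
        tree = parse_tree(tree)
    nodes = {_node_key(node): node for node in tree.preorder_node_iter()}
    ref_leaf = tree.find_node_with_taxon_label(reference)
    if ref_leaf is None:
        raise ValueError(f"reference {reference!r} is not a tip of the tree")
    ref_path = []
    node = ref_leaf
    while node is not None:
        ref_path.append(node)
        node = node.parent_node
    for name in node_defs:
        if name not in nodes:
            raise ValueError(f"node {name!r} not found in tree")
        if nodes[name] not in ref_path:
            raise ValueError(f"node {name!r} is not on the path from "
                             f"{reference!r} to the root")
    # oldest (closest to root) first
    ordered = sorted(node_defs, key=lambda name: ref_path.index(nodes[name]),
                     reverse=True)
    child_clades = {name: [_leaf_labels(child)
                           for child in nodes[name].child_nodes()]
                    for name in ordered}

    out = []
    for call in calls:
        attribution = None
        if call.status == "shared":
            present = set(call.shared_with) | {reference}
            for name in ordered:
                spanned = sum(1 for clade in child_clades[name]
                              if present & clade)
                if spanned >= 2:
                    attribution = name
                    break
        out.append(replace(call, ancestor_attribution=attribution))
    return out


@dataclass
class PresenceMatrix:
    present: pd.DataFrame     # bool, solo-LTR id x individual
    breadth: pd.DataFrame     # fraction of element positions at >= min_depth
    mean_depth: pd.DataFrame


def call_presence(solos: Sequence[SoloLTR],
                  coverage_tracks: dict[str, dict[str, np.ndarray]],
                  min_breadth: float = 0.8, min_depth: float = 2
                  ) -> PresenceMatrix:
    """Presence of each solo-LTR in each individual from depth tracks:
    present iff >= ``min_breadth`` of the element's positions have depth
    >= ``min_depth``."""
    individuals = sorted(coverage_tracks)
    ids = [solo.id for solo in solos]
    present = pd.DataFrame(False, index=ids, columns=individuals)
    breadth = pd.DataFrame(0.0, index=ids, columns=individuals)
    mean_depth = pd.DataFrame(0.0, index=ids, columns=individuals)
    for ind in individuals:
        track = coverage_tracks[ind]
        for solo in solos:
            hit = solo.hit
            if hit.scaffold not in track:
                raise ValueError(f"individual {ind!r} has no coverage track "
                                 f"for scaffold {hit.scaffold!r}")
            depths = np.asarray(track[hit.scaffold][hit.start:hit.end])
            if depths.size != hit.length:
                raise ValueError(f"coverage track of {ind!r} does not span "
                                 f"{solo.id}")
            frac = float(np.mean(depths >= min_depth))
            breadth.at[solo.id, ind] = frac
            mean_depth.at[solo.id, ind] = float(depths.mean())
            present.at[solo.id, ind] = frac >= min_breadth
    return PresenceMatrix(present, breadth, mean_depth)


@dataclass
class IntersectionSummary:
    patterns: list[tuple[tuple[str, ...], int]]  # (individuals present, row count)
    polymorphic_count: int
    polymorphic_fraction: float


def intersection_counts(matrix: PresenceMatrix | pd.DataFrame,
                        min_size: int = 2) -> IntersectionSummary:
    """UpSet-style distinct-mode intersections: rows sharing one exact
    presence pattern are tallied; patterns with >= ``min_size`` rows are
    reported, largest first."""
    present = matrix.present if isinstance(matrix, PresenceMatrix) else matrix
    if present.empty:
        raise ValueError("presence matrix is empty")
    counts: dict[tuple[str, ...], int] = {}
    polymorphic = 0
    for _, row in present.iterrows():
        pattern = tuple(col for col in present.columns if row[col])
        counts[pattern] = counts.get(pattern, 0) + 1
        if 0 < len(pattern) < len(present.columns):
            polymorphic += 1
    patterns = sorted(((p, c) for p, c in counts.items() if c >= min_size),
                      key=lambda pc: (-pc[1], pc[0]))
    return IntersectionSummary(patterns, polymorphic,
                               polymorphic / len(present))
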