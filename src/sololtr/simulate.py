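"""Synthetic genomes with planted ERVs and solo-LTRs, with exact ground truth.

The generator emulates the biological process the pipeline detects: a full
endogenous retrovirus integrates as TSD + LTR + internal + LTR + TSD (the two
LTR copies identical at integration, the TSD a short duplication of host
sequence), and unequal homologous recombination between the two LTRs later
deletes the internal region plus one LTR, leaving a solo-LTR between the
original TSD copies.

Two divergence clocks are modelled, both Jukes-Cantor point substitutions
with no indels (truth coordinates stay exact):

* ``insertion_divergence`` separates integration events: each element's LTR
  derives from a family master mutated at this rate, so distinct elements of
  one family are themselves diverged (as real integrations of related
  proviral variants are) and reciprocal-best-hit pairing has a signal to
  work with.
* ``divergence`` is the post-integration clock: each planted copy (and each
  TSD copy) is independently mutated at this rate.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._alignment import revcomp
from .annotate import CandidateInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Raised when a planted element cannot be positioned in the genome."""


@dataclass
class SimConfig:
    genome_length: int = 500_000
    n_scaffolds: int = 5
    ltr_length: int = 300
    internal_length: int = 2_000
    n_full_erv: int = 30
    n_solo: int = 30
    tsd_length: int | None = None          # None: draw uniformly in [4, 6] per element
    divergence: float = 0.0                # substitutions/site per planted copy
    insertion_divergence: float = 0.15     # substitutions/site separating integration events
    family_labels: tuple[str, ...] = ("ERVK", "ERVL", "ERV1")
    seed: int = 0
    min_spacing: int = 50                  # bp kept free around every insertion point
    edge_margin: int = 50                  # bp kept free at scaffold ends

    def __post_init__(self) -> None:
        if not 100 <= self.ltr_length <= 1000:
            raise ValueError(f"ltr_length must be in [100, 1000], got {self.ltr_length}")
        if self.tsd_length is not None and not 4 <= self.tsd_length <= 6:
            raise ValueError(f"tsd_length must be in [4, 6], got {self.tsd_length}")
        for name in ("divergence", "insertion_divergence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 0.35:
                raise ValueError(f"{name} must be in [0, 0.35], got {value}")
        for name in ("genome_length", "n_scaffolds", "internal_length", "n_full_erv", "n_solo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if not self.family_labels:
            raise ValueError("family_labels must be non-empty")


@dataclass
class Element:
    """Ground-truth record of one planted element (0-based half-open coords)."""

    element_id: str
    kind: str                               # "full_erv" | "solo_ltr"
    scaffold: str
    strand: str
    family: str
    source_id: str                          # family master the allele derives from
    ltr_intervals: list[tuple[int, int]]    # one (solo) or two (full ERV), sorted
    internal_interval: tuple[int, int] | None
    tsd: str                                # TSD as planted (genome orientation)
    tsd_intervals: tuple[tuple[int, int], tuple[int, int]]
    allele: str                             # element-specific source LTR sequence
    origin_branch: str | None = None        # set by simulate_species_set

    @property
    def start(self) -> int:
        """Outer element start (leftmost LTR boundary)."""
        return self.ltr_intervals[0][0]

    @property
    def end(self) -> int:
        return self.ltr_intervals[-1][1]


@dataclass
class SimTruth:
    elements: list[Element] = field(default_factory=list)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    library: list[tuple[str, str, str]] = field(default_factory=list)  # (id, family, sequence)

    def by_kind(self, kind: str) -> list[Element]:
        return [e for e in self.elements if e.kind == kind]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Jukes-Cantor point substitutions: each site replaced with one of the
    other three bases with probability ``rate``."""
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _scaffold_names(n: int) -> list[str]:
    return [f"scaf{i + 1}" for i in range(n)]


def _split_lengths(total: int, n: int) -> list[int]:
    base = total // n
    lengths = [base] * n
    lengths[-1] += total - base * n
    return lengths


def _sample_points(rng: np.random.Generator, n_points: int, length: int,
                   spacing: int, margin: int, what: list[str]) -> list[int]:
    """Rejection-sample distinct insertion points with pairwise spacing."""
    points: list[int] = []
    low, high = margin, length - margin
    for name in what[:n_points]:
        if high <= low:
            raise PlacementError(f"scaffold too small to place element {name!r}")
        for _ in range(1000):
            p = int(rng.integers(low, high))
            if all(abs(p - q) >= spacing for q in points):
                points.append(p)
                break
        else:
            raise PlacementError(f"could not place element {name!r} after 1000 tries")
    return points


def _build_construct(element_id: str, kind: str, family: str, source_id: str,
                     allele: str, tsd: str, strand: str, internal_length: int,
                     divergence: float, rng: np.random.Generator):
    """Assemble the planted sequence and its element-relative intervals."""
    tsd_left = mutate(tsd, divergence, rng)
    tsd_right = mutate(tsd, divergence, rng)
    t, l = len(tsd), len(allele)
    if kind == "full_erv":
        ltr_a = mutate(allele, divergence, rng)
        ltr_b = mutate(allele, divergence, rng)
        internal = _random_seq(rng, internal_length)
        seq = tsd_left + ltr_a + internal + ltr_b + tsd_right
        ltrs = [(t, t + l), (t + l + internal_length, t + 2 * l + internal_length)]
        internal_iv = (t + l, t + l + internal_length)
    else:
        ltr_a = mutate(allele, divergence, rng)
        seq = tsd_left + ltr_a + tsd_right
        ltrs = [(t, t + l)]
        internal_iv = None
    total = len(seq)
    tsds = ((0, t), (total - t, total))
    if strand == "-":
        seq = revcomp(seq)
        ltrs = sorted((total - b, total - a) for a, b in ltrs)
        if internal_iv is not None:
            a, b = internal_iv
            internal_iv = (total - b, total - a)
        tsd = revcomp(tsd)
    return seq, Element(
        element_id=element_id, kind=kind, scaffold="", strand=strand,
        family=family, source_id=source_id, ltr_intervals=ltrs,
        internal_interval=internal_iv, tsd=tsd, tsd_intervals=tsds,
        allele=allele,
    )


def _shift_element(element: Element, offset: int) -> None:
    element.ltr_intervals = [(a + offset, b + offset) for a, b in element.ltr_intervals]
    if element.internal_interval is not None:
        a, b = element.internal_interval
        element.internal_interval = (a + offset, b + offset)
    (a1, b1), (a2, b2) = element.tsd_intervals
    element.tsd_intervals = ((a1 + offset, b1 + offset), (a2 + offset, b2 + offset))


def _family_masters(config: SimConfig, rng: np.random.Generator):
    return [(f"{family}_master", family, _random_seq(rng, config.ltr_length))
            for family in config.family_labels]


def _make_elements(config: SimConfig, rng: np.random.Generator,
                   kinds: list[str], masters, id_prefix: str = "elem"):
    """Draw per-element family, allele, TSD and strand; constructs come later."""
    specs = []
    for i, kind in enumerate(kinds):
        master_id, family, master_seq = masters[i % len(masters)]
        allele = mutate(master_seq, config.insertion_divergence, rng)
        tsd_len = config.tsd_length or int(rng.integers(4, 7))
        tsd = _random_seq(rng, tsd_len)
        strand = "+" if rng.random() < 0.5 else "-"
        specs.append((f"{id_prefix}{i + 1:04d}", kind, family, master_id, allele, tsd, strand))
    return specs


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Plant ``n_full_erv`` full ERVs and ``n_solo`` solo-LTRs in i.i.d.
    uniform-ACGT background scaffolds; returns (genome, exact truth).

    ``genome_length`` is the background length; planted constructs are
    inserted, so final scaffolds are longer by the total element length.
    """
    rng = np.random.default_rng(config.seed)
    masters = _family_masters(config, rng)
    names = _scaffold_names(config.n_scaffolds)
    bg_lengths = _split_lengths(config.genome_length, config.n_scaffolds)
    backgrounds = {name: _random_seq(rng, length) for name, length in zip(names, bg_lengths)}

    kinds = ["full_erv"] * config.n_full_erv + ["solo_ltr"] * config.n_solo
    specs = _make_elements(config, rng, kinds, masters)

    # assign scaffolds proportionally to background length, then sample points
    probs = np.array(bg_lengths, dtype=float) / config.genome_length
    assignment = [names[i] for i in rng.choice(len(names), size=len(specs), p=probs)]

    genome: dict[str, str] = {}
    truth = SimTruth(library=masters)
    for name, bg in backgrounds.items():
        local = [(spec, j) for j, spec in enumerate(specs) if assignment[j] == name]
        ids = [spec[0] for spec, _ in local]
        points = _sample_points(rng, len(local), len(bg), config.min_spacing,
                                config.edge_margin, ids)
        order = np.argsort(points)
        pieces, records = [], []
        prev, offset = 0, 0
        for idx in order:
            (eid, kind, family, src, allele, tsd, strand), _ = local[idx]
            p = points[idx]
            seq, element = _build_construct(eid, kind, family, src, allele, tsd,
                                            strand, config.internal_length,
                                            config.divergence, rng)
            pieces.append(bg[prev:p])
            offset += p - prev
            element.scaffold = name
            _shift_element(element, offset)
            records.append(element)
            pieces.append(seq)
            offset += len(seq)
            prev = p
        pieces.append(bg[prev:])
        genome[name] = "".join(pieces)
        truth.elements.extend(records)
        truth.scaffold_lengths[name] = len(genome[name])
    truth.elements.sort(key=lambda e: e.element_id)
    return genome, truth


def simulate_recombination(genome: dict[str, str], truth: SimTruth,
                           fraction: float, seed: int = 0
                           ) -> tuple[dict[str, str], SimTruth]:
    """Convert a random ``fraction`` of full ERVs into solo-LTRs in place:
    the internal region and the downstream LTR are deleted, one LTR remains
    between the original TSD copies, and all downstream truth coordinates
    shift accordingly."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    genome = dict(genome)
    truth = _copy.deepcopy(truth)
    full = truth.by_kind("full_erv")
    n_convert = round(fraction * len(full))
    if n_convert == 0:
        return genome, truth
    rng = np.random.default_rng(seed)
    chosen = {full[i].element_id
              for i in rng.choice(len(full), size=n_convert, replace=False)}

    deletions: dict[str, list[tuple[int, int]]] = {}
    for element in truth.elements:
        if element.element_id not in chosen:
            continue
        (a1, b1), (a2, b2) = element.ltr_intervals
        del_start, del_end = b1, b2  # internal region + downstream LTR copy
        deletions.setdefault(element.scaffold, []).append((del_start, del_end))
        element.kind = "solo_ltr"
        element.ltr_intervals = [(a1, b1)]
        element.internal_interval = None

    for scaffold, cuts in deletions.items():
        seq = genome[scaffold]
        for del_start, del_end in sorted(cuts, reverse=True):
            seq = seq[:del_start] + seq[del_end:]
            shift = del_end - del_start

            def move(x: int) -> int:
                return x - shift if x >= del_end else x

            for element in truth.elements:
                if element.scaffold != scaffold:
                    continue
                element.ltr_intervals = [(move(a), move(b)) for a, b in element.ltr_intervals]
                if element.internal_interval is not None:
                    element.internal_interval = tuple(map(move, element.internal_interval))
                element.tsd_intervals = tuple(
                    (move(a), move(b)) for a, b in element.tsd_intervals)
        genome[scaffold] = seq
        truth.scaffold_lengths[scaffold] = len(seq)
    return genome, truth


def simulate_population(truth: SimTruth, n_individuals: int,
                        polymorphic_fraction: float, depth: float, seed: int = 0):
    """Per-individual presence/absence of the solo-LTRs plus coverage tracks.

    A random ``polymorphic_fraction`` of solo-LTRs get Bernoulli(0.5)
    presence per individual (forced mixed); the rest are present in all.
    Coverage is Poisson(``depth``) per position everywhere except over
    absent elements, which are zero.

    Returns (presence: pandas.DataFrame [element x individual, bool],
    tracks: {individual: {scaffold: int16 depth array}}).
    """
    import pandas as pd

    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not 0.0 <= polymorphic_fraction <= 1.0:
        raise ValueError("polymorphic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    solos = truth.by_kind("solo_ltr")
    individuals = [f"ind{i + 1:02d}" for i in range(n_individuals)]
    presence = pd.DataFrame(True, index=[e.element_id for e in solos], columns=individuals)

    n_poly = round(polymorphic_fraction * len(solos))
    if n_poly:
        chosen = rng.choice(len(solos), size=n_poly, replace=False)
        for i in chosen:
            pattern = rng.random(n_individuals) < 0.5
            if n_individuals >= 2:
                for _ in range(100):
                    if pattern.any() and not pattern.all():
                        break
                    pattern = rng.random(n_individuals) < 0.5
                else:  # pragma: no cover - vanishingly unlikely
                    pattern[0], pattern[1] = True, False
            presence.loc[solos[i].element_id] = pattern

    tracks: dict[str, dict[str, np.ndarray]] = {}
    for ind in individuals:
        cov = {name: rng.poisson(depth, size=length).astype(np.int16)
               for name, length in truth.scaffold_lengths.items()}
        for element in solos:
            if not presence.at[element.element_id, ind]:
                start, end = element.ltr_intervals[0]
                cov[element.scaffold][start:end] = 0
        tracks[ind] = cov
    return presence, tracks


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return ",".join(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick tree: {exc}") from exc
    tree.is_rooted = True  # the analyses assume a rooted species tree
    return tree


def simulate_species_set(newick: str, branch_counts: dict[str, int],
                         config: SimConfig):
    """Plant solo-LTRs on tree branches; an element on branch B appears at
    orthologous positions in every tip below B.

    Branches are keyed by tip label (terminal), internal node label, or the
    comma-joined sorted tip labels of the clade when unlabeled.

    Returns (genomes, truths, blocks): per-tip genome dict, per-tip SimTruth
    with ``origin_branch`` set, and alignment blocks (exact bookkeeping; the
    shared background and every orthologous element interval each become one
    block listing the species that carry it).
    """
    from .trace import AlignmentBlock, AlignmentBlockSet, BlockRow

    tree = parse_tree(newick)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    nodes = {_node_key(node): node for node in tree.preorder_node_iter()}
    unknown = set(branch_counts) - set(nodes)
    if unknown:
        raise ValueError(f"branch keys not in tree: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    masters = _family_masters(config, rng)
    names = _scaffold_names(config.n_scaffolds)
    bg_lengths = _split_lengths(config.genome_length, config.n_scaffolds)
    backgrounds = {name: _random_seq(rng, length) for name, length in zip(names, bg_lengths)}

    branches, kinds = [], []
    for key in sorted(branch_counts):
        branches.extend([key] * branch_counts[key])
        kinds.extend(["solo_ltr"] * branch_counts[key])
    specs = _make_elements(config, rng, kinds, masters)
    carriers = [sorted(leaf.taxon.label for leaf in nodes[b].leaf_iter())
                for b in branches]

    probs = np.array(bg_lengths, dtype=float) / config.genome_length
    assignment = [names[i] for i in rng.choice(len(names), size=len(specs), p=probs)]
    points_by_scaffold: dict[str, list[tuple[int, int]]] = {}  # (point, spec index)
    for name, length in zip(names, bg_lengths):
        local = [j for j in range(len(specs)) if assignment[j] == name]
        pts = _sample_points(rng, len(local), length, config.min_spacing,
                             config.edge_margin, [specs[j][0] for j in local])
        points_by_scaffold[name] = sorted(zip(pts, local))

    genomes = {tip: {} for tip in tips}
    truths = {tip: SimTruth(library=masters) for tip in tips}
    blocks: list[AlignmentBlock] = []

    for name, bg in backgrounds.items():
        placed = points_by_scaffold[name]
        construct_len = {}
        per_tip_elements: dict[int, dict[str, Element]] = {}
        # per-tip assembly; every tip carrying an element gets its own mutated copy
        for tip in tips:
            pieces, prev, offset = [], 0, 0
            for p, j in placed:
                eid, kind, family, src, allele, tsd, strand = specs[j]
                if tip not in carriers[j]:
                    continue
                seq, element = _build_construct(eid, kind, family, src, allele, tsd,
                                                strand, config.internal_length,
                                                config.divergence, rng)
                construct_len[j] = len(seq)
                pieces.append(bg[prev:p])
                offset += p - prev
                element.scaffold = name
                element.origin_branch = branches[j]
                _shift_element(element, offset)
                per_tip_elements.setdefault(j, {})[tip] = element
                pieces.append(seq)
                offset += len(seq)
                prev = p
            pieces.append(bg[prev:])
            genomes[tip][name] = "".join(pieces)
            truths[tip].scaffold_lengths[name] = len(genomes[tip][name])
            truths[tip].elements.extend(
                per_tip_elements[j][tip] for _, j in placed if tip in carriers[j])

        # background blocks: segments between insertion points, present in all tips
        boundaries = [0] + [p for p, _ in placed] + [len(bg)]
        for a, b in zip(boundaries, boundaries[1:]):
            if b <= a:
                continue
            rows = []
            for tip in tips:
                shift = sum(construct_len[j] for p, j in placed
                            if p <= a and tip in carriers[j])
                rows.append(BlockRow(tip, name, a + shift, b + shift, "+"))
            blocks.append(AlignmentBlock(rows))
        # element blocks: the full construct interval in every carrying tip
        for p, j in placed:
            rows = []
            for tip in carriers[j]:
                element = per_tip_elements[j][tip]
                (a1, _), (_, b2) = element.tsd_intervals
                rows.append(BlockRow(tip, name, a1, b2, "+"))
            blocks.append(AlignmentBlock(rows))

    for tip in tips:
        truths[tip].elements.sort(key=lambda e: e.element_id)
    return genomes, truths, AlignmentBlockSet(blocks=blocks, reference=None)


def candidate_sets(truth: SimTruth, jitter: int = 0, seed: int = 0
                   ) -> tuple[list[CandidateInterval], list[CandidateInterval]]:
    """Emit the two candidate annotation sources the pipeline intersects.

    Both sources report every planted LTR interval, each independently
    expanded by up to ``jitter`` bp per side (0 = the sources agree exactly).
    """
    rng = np.random.default_rng(seed)
    out_a, out_b = [], []
    for element in truth.elements:
        length = truth.scaffold_lengths[element.scaffold]
        for start, end in element.ltr_intervals:
            for out, tag in ((out_a, "A"), (out_b, "B")):
                pad_l = int(rng.integers(0, jitter + 1)) if jitter else 0
                pad_r = int(rng.integers(0, jitter + 1)) if jitter else 0
                out.append(CandidateInterval(element.scaffold,
                                             max(0, start - pad_l),
                                             min(length, end + pad_r), tag))
    key = lambda c: (c.scaffold, c.start, c.end)
    return sorted(out_a, key=key), sorted(out_b, key=key)
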