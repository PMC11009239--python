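"""Scoring pipeline output against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotate import LTRHit
from .classify import LTRPair, SoloLTR
from .simulate import SimTruth


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the longer interval length."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0], b[1] - b[0])


def match_hits_to_truth(hits: Sequence[LTRHit], truth: SimTruth,
                        min_reciprocal: float = 0.95):
    """Map each planted LTR interval to the hit covering it.

    Returns (assignment: {(element_id, copy index) -> hit | None},
    unmatched_hits: hits overlapping no planted interval at the threshold).
    """
    assignment = {}
    used = set()
    for element in truth.elements:
        for copy_idx, interval in enumerate(element.ltr_intervals):
            found = None
            for hit in hits:
                if hit.scaffold != element.scaffold:
                    continue
                if reciprocal_overlap((hit.start, hit.end), interval) >= min_reciprocal:
                    found = hit
                    used.add(id(hit))
                    break
            assignment[(element.element_id, copy_idx)] = found
    unmatched = [h for h in hits if id(h) not in used]
    return assignment, unmatched


@dataclass
class ClassificationScore:
    n_elements: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_elements if self.n_elements else 1.0


def score_classification(pairs: Sequence[LTRPair], solos: Sequence[SoloLTR],
                         truth: SimTruth,
                         min_reciprocal: float = 0.95) -> ClassificationScore:
    """Element-level pair/solo accuracy.

    A planted full ERV is correct iff its two LTR copies are recovered and
    paired with each other; a planted solo-LTR is correct iff its copy is
    recovered and classified solo.
    """
    hits = [p.hit_left for p in pairs] + [p.hit_right for p in pairs] + \
           [s.hit for s in solos]
    assignment, _ = match_hits_to_truth(hits, truth, min_reciprocal)
    paired_partner = {}
    for pair in pairs:
        paired_partner[id(pair.hit_left)] = id(pair.hit_right)
        paired_partner[id(pair.hit_right)] = id(pair.hit_left)
    solo_ids = {id(s.hit) for s in solos}

    correct = 0
    for element in truth.elements:
        if element.kind == "full_erv":
            a = assignment.get((element.element_id, 0))
            b = assignment.get((element.element_id, 1))
            if (a is not None and b is not None
                    and paired_partner.get(id(a)) == id(b)):
                correct += 1
        else:
            a = assignment.get((element.element_id, 0))
            if a is not None and id(a) in solo_ids:
                correct += 1
    return ClassificationScore(len(truth.elements), correct)


def truth_formation_ratio(truth: SimTruth) -> float:
    """Planted solo bp over planted total LTR bp."""
    solo_bp = paired_bp = 0
    for element in truth.elements:
        bp = sum(b - a for a, b in element.ltr_intervals)
        if element.kind == "solo_ltr":
            solo_bp += bp
        else:
            paired_bp += bp
    total = solo_bp + paired_bp
    return solo_bp / total if total else float("nan")
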