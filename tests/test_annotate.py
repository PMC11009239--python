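import numpy as np
import pytest

from _oracles import brute_cluster_best, brute_intersections
from sololtr import (LTRHit, LTRLibrary, build_library, cluster_hits,
                     filter_scaffolds, intersect_candidates, scan_genome)
from sololtr._alignment import cluster_identity, revcomp
from sololtr.annotate import CandidateInterval, LibraryEntry
from sololtr.evaluation import match_hits_to_truth
from sololtr.simulate import mutate


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def hit(start, end, scaffold="s", strand="+", score=100.0, identity=90.0,
        library_id="q"):
    return LTRHit(scaffold, start, end, strand, library_id, "ERVK",
                  identity, 95.0, score)


class TestIntersectCandidates:
    def test_basic_overlap(self):
        out = intersect_candidates([CandidateInterval("s", 100, 600, "A")],
                                   [CandidateInterval("s", 300, 900, "B")])
        assert [(iv.scaffold, iv.start, iv.end) for iv in out] == [("s", 300, 600)]

    def test_short_overlap_rejected(self):
        out = intersect_candidates([CandidateInterval("s", 100, 180, "A")],
                                   [CandidateInterval("s", 100, 180, "B")])
        assert out == []

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            intersect_candidates([CandidateInterval("s", 500, 100, "A")], [])

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(42)
        def random_set(tag):
            out = []
            for _ in range(200):
                scaffold = f"s{rng.integers(1, 4)}"
                start = int(rng.integers(0, 50_000))
                out.append(CandidateInterval(scaffold, start,
                                             start + int(rng.integers(20, 1500)),
                                             tag))
            return out
        set_a, set_b = random_set("A"), random_set("B")
        result = intersect_candidates(set_a, set_b)
        expected = brute_intersections(set_a, set_b)
        assert [(iv.scaffold, iv.start, iv.end) for iv in result] == \
               [(iv.scaffold, iv.start, iv.end) for iv in expected]


class TestBuildLibrary:
    def test_identical_sequences_collapse(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 300)
        library = build_library([("a", "ERVK", seq), ("b", "ERVK", seq)])
        assert len(library) == 1

    def test_unrelated_sequences_both_kept(self):
        rng = np.random.default_rng(1)
        library = build_library([("a", "ERVK", random_seq(rng, 300)),
                                 ("b", "ERVL", random_seq(rng, 300))])
        assert len(library) == 2

    def test_out_of_range_lengths_rejected(self):
        rng = np.random.default_rng(2)
        library = build_library([("short", "X", random_seq(rng, 80)),
                                 ("long", "X", random_seq(rng, 1200)),
                                 ("ok", "X", random_seq(rng, 300))])
        assert [e.id for e in library] == ["ok"]

    def test_matches_exhaustive_oracle(self):
        """Planted 96%-identical duplicates: greedy retention equals the
        all-pairs oracle applying the same rule without early exit."""
        rng = np.random.default_rng(3)
        seqs = []
        for i in range(12):
            base = random_seq(rng, int(rng.integers(150, 500)))
            seqs.append((f"orig{i}", "ERVK", base))
            if i % 3 == 0:  # near-duplicate at ~96% identity
                seqs.append((f"dup{i}", "ERVK", mutate(base, 0.04, rng)))
        library = build_library(seqs)
        ordered = sorted(seqs, key=lambda s: (-len(s[2]), s[0]))
        retained = []
        for seq_id, family, seq in ordered:
            hits = []
            for rid, _, rseq in retained:
                ident, cov = cluster_identity(seq, rseq)
                hits.append(ident >= 95.0 and cov >= 0.9)
            if not any(hits):
                retained.append((seq_id, family, seq))
        assert [e.id for e in library] == [r[0] for r in retained]
        # at least one duplicate must actually have collapsed
        assert len(library) < len(seqs)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        seqs = [(f"s{i}", "ERVK", random_seq(rng, 200 + 40 * i))
                for i in range(6)]
        library = build_library(seqs)
        again = build_library([(e.id, e.family, e.sequence) for e in library])
        assert [e.id for e in again] == [e.id for e in library]

    def test_empty_input(self):
        assert len(build_library([])) == 0


class TestScanGenome:
    def test_exact_copy_perfect_hit(self):
        rng = np.random.default_rng(10)
        query = random_seq(rng, 300)
        genome = {"s": random_seq(rng, 5_000) + query + random_seq(rng, 5_000)}
        library = LTRLibrary([LibraryEntry("q", "ERVK", query)])
        hits = scan_genome(genome, library)
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.end) == (5_000, 5_300)
        assert best.identity == 100.0 and best.query_coverage == 100.0
        assert best.strand == "+"

    def test_reverse_strand_copy_found(self):
        rng = np.random.default_rng(11)
        query = random_seq(rng, 300)
        genome = {"s": random_seq(rng, 3_000) + revcomp(query)
                  + random_seq(rng, 3_000)}
        hits = scan_genome(genome, LTRLibrary([LibraryEntry("q", "ERVK", query)]))
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.end, best.strand) == (3_000, 3_300, "-")

    def test_heavily_mutated_copy_not_hit(self):
        """30% mutated copy sits below the 65% identity floor."""
        rng = np.random.default_rng(12)
        query = random_seq(rng, 300)
        copy = mutate(query, 0.30, rng)
        genome = {"s": random_seq(rng, 3_000) + copy + random_seq(rng, 3_000)}
        hits = scan_genome(genome, LTRLibrary([LibraryEntry("q", "ERVK", query)]))
        assert hits == []

    def test_background_false_positive_rate(self):
        """Empirical null: a 300 bp query against pure 50 kb background."""
        false_positives = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            query = random_seq(rng, 300)
            genome = {"s": random_seq(rng, 50_000)}
            hits = scan_genome(genome, LTRLibrary([LibraryEntry("q", "X", query)]))
            false_positives += len(hits)
        assert false_positives == 0, \
            f"observed false-positive rate {false_positives / 20:.2f} hits/genome"

    def test_recall_and_precision_on_planted_genome(self, sim100, discovery100):
        _, _, truth = sim100
        assignment, unmatched = match_hits_to_truth(discovery100.hits, truth)
        assert all(h is not None for h in assignment.values())  # recall 1.0
        assert unmatched == []                                  # precision 1.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(13)
        masters = [random_seq(rng, 250) for _ in range(2)]
        genome = {"s": "".join(
            random_seq(rng, 1_500) + mutate(masters[i % 2], 0.1, rng)
            for i in range(6)) + random_seq(rng, 1_500)}
        library = LTRLibrary([LibraryEntry(f"q{i}", "ERVK", m)
                              for i, m in enumerate(masters)])
        counts = {}
        for min_identity in (65, 80):
            for min_qcov in (80, 95):
                hits = scan_genome(genome, library, min_identity, min_qcov)
                counts[(min_identity, min_qcov)] = len(hits)
        assert counts[(80, 80)] <= counts[(65, 80)]
        assert counts[(65, 95)] <= counts[(65, 80)]
        assert counts[(80, 95)] <= min(counts[(80, 80)], counts[(65, 95)])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            scan_genome({}, LTRLibrary([LibraryEntry("q", "X", "ACGT" * 50)]))
        with pytest.raises(ValueError):
            scan_genome({"s": "ACGT" * 100}, LTRLibrary([]))


class TestClusterHits:
    def test_disjoint_hits_kept(self):
        hits = [hit(0, 100), hit(200, 300)]
        assert cluster_hits(hits) == sorted(hits, key=lambda h: h.start)

    def test_tie_break_score_then_identity(self):
        hits = [hit(0, 100, score=50, identity=99),
                hit(50, 150, score=80, identity=90),
                hit(90, 190, score=80, identity=95)]
        out = cluster_hits(hits)
        assert len(out) == 1
        assert (out[0].score, out[0].identity) == (80, 95)

    def test_output_is_antichain(self):
        rng = np.random.default_rng(20)
        hits = [hit(int(s), int(s) + int(rng.integers(50, 400)),
                    score=float(rng.integers(10, 100)))
                for s in rng.integers(0, 3_000, size=40)]
        out = cluster_hits(hits)
        for a in out:
            for b in out:
                if a is not b:
                    assert a.start >= b.end or b.start >= a.end

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            hits = [hit(int(s), int(s) + int(rng.integers(50, 400)),
                        scaffold=f"s{rng.integers(1, 3)}",
                        score=float(rng.integers(10, 100)),
                        identity=float(rng.integers(65, 100)))
                    for s in rng.integers(0, 2_000, size=15)]
            assert cluster_hits(hits) == brute_cluster_best(hits)


class TestFilterScaffolds:
    def test_boundary(self):
        hits = [hit(0, 100, scaffold="small"), hit(0, 100, scaffold="big")]
        lengths = {"small": 19_999, "big": 20_000}
        assert filter_scaffolds(hits, lengths) == [hits[1]]

    def test_empty(self):
        assert filter_scaffolds([], {}) == []

    def test_unknown_scaffold_error(self):
        with pytest.raises(ValueError, match="unknown scaffold"):
            filter_scaffolds([hit(0, 100, scaffold="mystery")], {"s": 30_000})
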