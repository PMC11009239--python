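import numpy as np
import pytest

from sololtr import (PlacementError, SimConfig, simulate_genome,
                     simulate_population, simulate_recombination,
                     simulate_species_set)
from sololtr._alignment import revcomp


def small_config(**kwargs):
    defaults = dict(genome_length=60_000, n_scaffolds=2, n_full_erv=4,
                    n_solo=4, seed=7)
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestSimulateGenome:
    def test_empty_case(self):
        genome, truth = simulate_genome(small_config(n_full_erv=0, n_solo=0))
        assert truth.elements == []
        assert sum(map(len, genome.values())) == 60_000

    def test_zero_divergence_copies_identical(self):
        genome, truth = simulate_genome(small_config())
        for element in truth.by_kind("full_erv"):
            seqs = [genome[element.scaffold][a:b]
                    for a, b in element.ltr_intervals]
            assert seqs[0] == seqs[1]

    def test_zero_divergence_copies_match_allele(self):
        """Every planted copy is an exact (possibly reverse-complemented)
        image of the element's source sequence."""
        genome, truth = simulate_genome(small_config())
        for element in truth.elements:
            for a, b in element.ltr_intervals:
                observed = genome[element.scaffold][a:b]
                if element.strand == "-":
                    observed = revcomp(observed)
                assert observed == element.allele

    def test_determinism(self):
        config = small_config()
        genome1, truth1 = simulate_genome(config)
        genome2, truth2 = simulate_genome(small_config())
        assert genome1 == genome2
        assert truth1.elements == truth2.elements

    def test_structure_invariants(self):
        genome, truth = simulate_genome(small_config())
        for element in truth.elements:
            length = truth.scaffold_lengths[element.scaffold]
            for a, b in element.ltr_intervals:
                assert 0 <= a < b <= length
            (a1, b1), (a2, b2) = element.tsd_intervals
            assert b1 == element.start and a2 == element.end  # TSDs adjacent
            tsd_left = genome[element.scaffold][a1:b1]
            tsd_right = genome[element.scaffold][a2:b2]
            assert tsd_left == tsd_right == element.tsd
            if element.kind == "full_erv":
                (l1, r1), (l2, r2) = element.ltr_intervals
                assert r1 <= l2 and element.internal_interval == (r1, l2)

    def test_placement_failure_names_element(self):
        config = small_config(genome_length=400, n_scaffolds=1,
                              n_full_erv=30, n_solo=0)
        with pytest.raises(PlacementError, match="elem"):
            simulate_genome(config)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(ltr_length=50)
        with pytest.raises(ValueError):
            SimConfig(tsd_length=8)
        with pytest.raises(ValueError):
            SimConfig(divergence=0.5)


class TestRecombination:
    def test_fraction_zero_is_identity(self):
        genome, truth = simulate_genome(small_config())
        genome2, truth2 = simulate_recombination(genome, truth, 0.0, seed=3)
        assert genome2 == genome
        assert truth2.elements == truth.elements

    def test_full_conversion_counts(self):
        genome, truth = simulate_genome(small_config(n_full_erv=3, n_solo=2))
        _, truth2 = simulate_recombination(genome, truth, 1.0, seed=3)
        assert len(truth2.by_kind("full_erv")) == 0
        assert len(truth2.by_kind("solo_ltr")) == 5

    def test_matches_string_surgery_oracle(self):
        """The recombined genome equals literal deletion of (internal +
        downstream LTR) from the original sequence, element by element."""
        genome, truth = simulate_genome(small_config(n_full_erv=5, n_solo=1))
        genome2, truth2 = simulate_recombination(genome, truth, 0.6, seed=9)
        converted = ({e.element_id for e in truth.by_kind("full_erv")}
                     & {e.element_id for e in truth2.by_kind("solo_ltr")})
        assert len(converted) == round(0.6 * 5)
        expected = dict(genome)
        for scaffold in expected:
            cuts = sorted(((e.ltr_intervals[0][1], e.ltr_intervals[1][1])
                           for e in truth.elements
                           if e.element_id in converted and e.scaffold == scaffold),
                          reverse=True)
            seq = expected[scaffold]
            for start, end in cuts:
                seq = seq[:start] + seq[end:]
            expected[scaffold] = seq
        assert genome2 == expected
        # coordinates in the shifted truth still point at the right bases
        for element in truth2.elements:
            (a1, b1) = element.tsd_intervals[0]
            assert genome2[element.scaffold][a1:b1] == element.tsd

    def test_converted_length_arithmetic(self):
        genome, truth = simulate_genome(small_config(n_full_erv=2, n_solo=0,
                                                     n_scaffolds=1))
        genome2, _ = simulate_recombination(genome, truth, 1.0, seed=0)
        removed = sum((e.internal_interval[1] - e.internal_interval[0])
                      + (e.ltr_intervals[1][1] - e.ltr_intervals[1][0])
                      for e in truth.elements)
        assert len(genome2["scaf1"]) == len(genome["scaf1"]) - removed


@pytest.fixture(scope="module")
def pop_truth():
    config = SimConfig(genome_length=900_000, n_scaffolds=2, n_full_erv=0,
                       n_solo=500, seed=5)
    _, truth = simulate_genome(config)
    return truth


@pytest.fixture(scope="module")
def species():
    config = SimConfig(genome_length=80_000, n_scaffolds=1,
                       n_full_erv=0, n_solo=0, seed=6)
    counts = {"A": 5, "B": 5, "C": 5, "AB": 5, "ROOT": 5}
    return simulate_species_set("((A,B)AB,C)ROOT;", counts, config)


class TestPopulation:
    def test_zero_fraction_all_present(self, sim100):
        _, _, truth = sim100
        presence, _ = simulate_population(truth, 4, 0.0, 10, seed=2)
        assert presence.values.all()

    def test_absent_elements_have_zero_coverage(self, sim100):
        _, _, truth = sim100
        presence, tracks = simulate_population(truth, 6, 0.5, 10, seed=2)
        solos = {e.element_id: e for e in truth.by_kind("solo_ltr")}
        absent = np.argwhere(~presence.values)
        assert len(absent) > 0
        for row, col in absent:
            element = solos[presence.index[row]]
            start, end = element.ltr_intervals[0]
            track = tracks[presence.columns[col]][element.scaffold]
            assert (track[start:end] == 0).all()

    def test_polymorphic_fraction_recovered(self, pop_truth):
        presence, _ = simulate_population(pop_truth, 10, 0.2, 5, seed=8)
        mixed = ((presence.values.any(axis=1))
                 & ~(presence.values.all(axis=1))).mean()
        # 500 elements: binomial 95% envelope around 0.2 is ~ +/- 0.035
        assert abs(mixed - 0.2) < 0.05

    def test_polymorphic_rows_are_mixed(self, pop_truth):
        presence, _ = simulate_population(pop_truth, 3, 1.0, 5, seed=8)
        assert presence.values.any(axis=1).all()
        assert (~presence.values).any(axis=1).all()


class TestSpeciesSet:
    def test_terminal_branch_only_in_its_tip(self, species):
        genomes, truths, blocks = species
        a_only = [e for e in truths["A"].elements if e.origin_branch == "A"]
        assert len(a_only) == 5
        b_ids = {e.element_id for e in truths["B"].elements}
        assert not any(e.element_id in b_ids for e in a_only)
        for element in a_only:
            for block in blocks.blocks:
                row = block.row_for("A")
                if row is None or len(block.species()) == 1:
                    continue
                overlap = (min(row.end, element.end)
                           - max(row.start, element.start))
                assert overlap <= 0, "terminal element mapped to another tip"

    def test_root_elements_everywhere(self, species):
        _, truths, blocks = species
        for tip in ("A", "B", "C"):
            roots = [e for e in truths[tip].elements if e.origin_branch == "ROOT"]
            assert len(roots) == 5
        root_ids = {e.element_id for e in truths["A"].elements
                    if e.origin_branch == "ROOT"}
        # every root element has one block aligning all three tips
        for element_id in root_ids:
            element = next(e for e in truths["A"].elements
                           if e.element_id == element_id)
            covering = [b for b in blocks.blocks
                        if b.species() == {"A", "B", "C"}
                        and b.row_for("A").start <= element.start
                        and b.row_for("A").end >= element.end]
            assert covering

    def test_orthologous_sequences_identical_at_zero_divergence(self, species):
        genomes, truths, _ = species
        by_id = {}
        for tip in ("A", "B", "C"):
            for element in truths[tip].elements:
                start, end = element.ltr_intervals[0]
                by_id.setdefault(element.element_id, []).append(
                    genomes[tip][element.scaffold][start:end])
        for seqs in by_id.values():
            assert len(set(seqs)) == 1

    def test_malformed_newick(self):
        with pytest.raises(ValueError, match="newick"):
            simulate_species_set("((A,B,C;", {"A": 1},
                                 SimConfig(n_full_erv=0, n_solo=0))
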