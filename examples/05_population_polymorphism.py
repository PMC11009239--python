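"""Call insertion polymorphism of solo-LTRs from per-individual coverage.

Recent insertions segregate in populations: an individual lacking the
insertion has no reads over the element interval. Presence is called per
element per individual (>= 80% of positions at depth >= 2) and the
resulting matrix is summarized UpSet-style by exact presence pattern.
"""

from sololtr import (SimConfig, call_presence, intersection_counts,
                     simulate_genome, simulate_population)
from sololtr.annotate import LTRHit
from sololtr.classify import SoloLTR

config = SimConfig(genome_length=400_000, n_scaffolds=1,
                   n_full_erv=0, n_solo=200, seed=31)
_, truth = simulate_genome(config)
presence_truth, tracks = simulate_population(
    truth, n_individuals=8, polymorphic_fraction=0.15, depth=20, seed=32)

solos = []
for element in truth.by_kind("solo_ltr"):
    start, end = element.ltr_intervals[0]
    solos.append(SoloLTR(hit=LTRHit(element.scaffold, start, end,
                                    element.strand, element.source_id,
                                    element.family, 100, 100, 0),
                         family=element.family))

matrix = call_presence(solos, tracks)
agreement = (matrix.present.values == presence_truth.values).mean()
summary = intersection_counts(matrix, min_size=2)

print(f"elements x individuals : {matrix.present.shape[0]} x "
      f"{matrix.present.shape[1]}")
print(f"call accuracy vs truth : {agreement:.2%}")
print(f"polymorphic solo-LTRs  : {summary.polymorphic_count} "
      f"({summary.polymorphic_fraction:.2%})")
print("largest presence patterns (count >= 2):")
for pattern, count in summary.patterns[:5]:
    print(f"  {count:4d} x present in {len(pattern)}/8: "
          f"{','.join(pattern) if pattern else '(absent in all)'}")

# ~15% of elements were planted polymorphic, and the coverage-based calls
# recover the planted matrix almost perfectly at 20x depth.
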