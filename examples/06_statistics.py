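"""The statistical toolkit: group comparison, correlation with speciation
depth, peak-overlap enrichment, and flanking-gene assignment.
"""

import numpy as np

from sololtr import (LTRHit, flanking_genes, peak_overlap_enrichment,
                     pearson_ci, speciation_depth, welch_t)
from sololtr.classify import SoloLTR
from sololtr.stats import GREATER

rng = np.random.default_rng(0)

# Do birds (high formation ratios) exceed mammals? Welch's one-sided t-test
# tolerates the unequal variances of the two groups.
birds = rng.normal(0.96, 0.02, size=30)
mammals = rng.normal(0.80, 0.08, size=12)
welch = welch_t(birds, mammals, side=GREATER)
print(f"Welch one-sided t-test: t={welch.t:.2f}, df={welch.df:.1f}, "
      f"p={welch.p:.2e}")

# Speciation depth: internal nodes from a named ancestor to each tip.
tree = "(((((A,B)N1,C)N2,D)N3,E)N4,F)ROOT;"
tips = ["A", "B", "C", "D", "E", "F"]
depths = speciation_depth(tree, "ROOT", tips)
print(f"speciation depths from ROOT: {depths}")

# Pearson correlation of solo-LTR load against speciation depth, with a
# Fisher-z 95% confidence interval.
load = np.array([depths[t] for t in tips]) * 40 + rng.normal(0, 15, size=6)
pearson = pearson_ci([depths[t] for t in tips], load)
print(f"Pearson r={pearson.r:.3f} CI=[{pearson.ci_low:.3f}, "
      f"{pearson.ci_high:.3f}] p={pearson.p:.3g}")

# Enrichment of one family's solo-LTRs in regulatory peaks (one-sided
# Fisher exact): ERVK solos placed inside peaks, ERVL solos outside.
def solo(start, family):
    return SoloLTR(hit=LTRHit("s", start, start + 300, "+", "q", family,
                              100, 100, 0), family=family)

solos = [solo(i * 10_000, "ERVK") for i in range(12)] \
    + [solo(500_000 + i * 10_000, "ERVL") for i in range(12)]
peaks = [("s", i * 10_000 + 100, i * 10_000 + 200) for i in range(9)]
enrich = peak_overlap_enrichment(solos, peaks, "ERVK")
print(f"peak overlap table {enrich.table}, odds ratio "
      f"{enrich.odds_ratio:.1f}, one-sided p={enrich.p:.4f}")

# Genes within 2/5/10 kb of peak-overlapping elements.
elements = [("s", 20_000, 20_300)]
genes = [("near", "s", 21_000, 22_000), ("mid", "s", 24_000, 26_000),
         ("far", "s", 29_000, 31_000), ("off", "s", 60_000, 61_000)]
for window, ids in sorted(flanking_genes(elements, genes).items()):
    print(f"genes within {window // 1000:2d} kb: {sorted(ids)}")
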