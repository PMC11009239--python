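# Methods

## The discovery model

A proviral insertion is `TSD – LTR – internal – LTR – TSD`; a solo-LTR is
`TSD – LTR – TSD`. Because the two LTRs of one provirus are identical at
integration and diverge together afterwards, each hit's closest relative in
the genome identifies its partner: pairing is a reciprocal-best-hit (RBH)
problem over hits on the same scaffold and strand. The pipeline assumes

* LTR lengths of 100–1000 bp (candidate intervals outside this range are
  discarded);
* proviral LTRs are direct repeats, so candidate partners must share a
  strand (opposite-strand neighbours are never paired);
* an inner gap (facing boundary to facing boundary) of at most 20 kb
  between the two LTRs of one provirus — a `distance_mode="span"` option
  measures outer span instead;
* a pairwise identity of at least 85% between true partners, while distinct
  integration events are less similar.

That last assumption is what makes RBH work on real genomes, and the
simulator reproduces it explicitly (see below).

## Alignment and identity

One scoring scheme is used everywhere: match +1, mismatch −2, gap open −5,
gap extension −2. Identity is matches over aligned columns, with internal
gap columns counted and terminal unaligned ends excluded. Concretely:

* **Scan hits** come from exact 11-mer seeds that nominate windows, each
  resolved by local alignment; identity is measured over the local
  alignment, query coverage as aligned query span / query length. Hits
  longer than 1.5× the query are discarded as pathological. A hit requires
  identity ≥ 65% and coverage ≥ 80%.
* **Pair identity** uses a global alignment of the two hit substrings
  (terminal gaps penalized, so the alignment spans both sequences) with
  identity counted over the aligned core, terminal-overhang columns
  excluded. Counting overhangs in the denominator would penalize pairs
  whose hit boundaries were trimmed a few bases differently by the
  scanner; letting the ends float freely would instead allow unrelated
  sequences to match over a short core. The span-then-exclude rule avoids
  both failure modes.
* **Library clustering** (95% redundancy threshold) measures identity over
  a local alignment of the shorter sequence against the longer and
  additionally requires the aligned region to cover ≥ 90% of the shorter
  sequence — the cd-hit-style rule; a forced global alignment would make
  the coverage requirement vacuous.

No e-values are computed; within an overlap cluster the best hit is chosen
by score, then identity, then the smaller start coordinate. This keeps the
ranking deterministic and reproducible.

## RBH extraction

A hit's best partner is the candidate with maximal pair identity (ties:
smaller inner gap, then smaller partner start). Mutual-best pairs are
extracted greedily in descending identity; extraction is repeated on the
remaining hits, which resolves chains (A↔B mutual while C's best is B:
A–B pair, and C may then pair with its next-best remaining candidate).
Because every tie is broken deterministically, the partition is invariant
under input order; the test suite asserts this by shuffling and by
comparison against a literal recompute-and-extract oracle.

## TSD verification

"Complete hits" are read strictly: the check passes iff some substring of
length 4–6 occurs exactly (no mismatches) in both the `flank_length` bp
immediately upstream of the element's left boundary and downstream of its
right boundary (for a pair, the outer boundaries of the two LTRs). The
longest motif is reported, leftmost in the upstream flank on ties. Elements
closer than one flank length to a scaffold edge are reported as unverifiable
(`reason="edge"`) rather than failed. Tolerance for decayed TSDs is
expressed only through the longer 15/20 bp windows, not through mismatch
allowances. Two random 10-mers share a 4-mer ≈ 15% of the time (the
acceptance script measures this empirical null), so a TSD is supporting
evidence, not a filter.

## The simulator

The generator emulates the process the pipeline detects, with exact
coordinate bookkeeping:

* **Background** is i.i.d. uniform ACGT — the simplest null that exercises
  the scanner's specificity. No isochore or repeat structure.
* **Substitutions only** (Jukes–Cantor point substitutions; no indels), so
  planted coordinates remain exact and multi-species alignments can be
  emitted from bookkeeping without running an aligner.
* **Two divergence clocks.** Each family has a master LTR;
  each element derives its own allele from the master at
  `insertion_divergence` (default 0.15 substitutions/site), and each
  planted copy (and each TSD copy) is then mutated at `divergence`
  (default 0). The first clock separates integration events — two elements
  of one family are ≈ 73% identical at the default, safely below the 85%
  pairing threshold — while the two copies of one element remain ≈ 100%
  (divergence 0) or ≈ 90% (divergence 0.05) identical. Without per-element
  alleles every same-family copy within 20 kb would pair at 100%, which is
  neither biological nor classifiable.
* **TSDs** are drawn uniformly at random per element, 4–6 bp, identical on
  both flanks at planting; post-integration `divergence` can break them,
  which deliberately exercises the checker's imperfection.
* **Placement** samples insertion points into the background with ≥ 50 bp
  spacing and a 50 bp edge margin (rejection sampling, bounded retries with
  a named-element failure). Elements never overlap or nest.
  `genome_length` is the background length; planted constructs are
  inserted, so scaffolds grow by the total element length.
* **Strand** is drawn uniformly per element; minus-strand elements are
  planted as the reverse complement of the whole construct.
* **Populations**: a chosen fraction of solo-LTRs is made polymorphic
  (Bernoulli(0.5) presence per individual, forced mixed); coverage is
  per-position Poisson at the configured depth, zeroed over absent
  elements. Coverage is generated directly — read mapping, mappability and
  paired-end effects are not modelled.
* **Species sets**: elements planted on a tree branch appear at
  orthologous positions in every descendant tip; the shared background and
  each orthologous element interval become alignment blocks listing
  exactly the species that carry them.

Consequently, passing tests demonstrate correctness of the algorithms under
clean conditions — exact arithmetic of the statistics, perfect recovery at
zero divergence, graceful degradation with divergence — but not robustness
to assembly gaps, nested or fragmented repeats, GC structure, indel
accumulation, or alignment error in real whole-genome alignments.

## Sharing, ancestors, presence

* A species joins a solo-LTR's `shared_with` set iff alignment blocks
  containing both the reference and that species cover ≥ `min_overlap`
  (default 0.5) of the solo interval; the solo is shared iff the set is
  non-empty. The per-species coverage rule keeps status and `shared_with`
  consistent by construction, and sharing is monotone in the threshold.
* A shared element is attributed to the oldest listed ancestor node N such
  that `{reference} ∪ shared_with` intersects at least two distinct child
  clades of N — the parsimony condition for presence in N's ancestral
  genome. Elements forced by no listed node keep attribution `None`.
* Population presence: present iff ≥ 80% of element positions have depth
  ≥ 2 (both thresholds exposed). Absence is purely coverage-defined;
  deletion alleles are not distinguished from reference-assembly gaps.
* Intersections are UpSet "distinct" semantics: rows sharing one exact
  presence pattern, reported when the pattern has ≥ 2 rows. A row is
  polymorphic iff it is neither all-present nor all-absent.

## Statistical primitives

Computed from their closed forms (tail probabilities from scipy's t,
normal and hypergeometric distributions):

* Welch's t: `t = (x̄ − ȳ) / sqrt(s²x/nx + s²y/ny)` with
  Welch–Satterthwaite degrees of freedom; the caller states the one-sided
  direction explicitly.
* Pearson r with p from `t = r·sqrt((n−2)/(1−r²))` and a 95% CI from
  Fisher's z ± z₀.₉₇₅/√(n−3) (the exact normal quantile, not 1.96, so the
  interval agrees with reference implementations to machine precision).
* One-sided Fisher exact p as the upper hypergeometric tail with margins
  fixed; odds ratios get a Haldane 0.5 correction when a cell is zero.
* Speciation depth counts internal nodes from the named ancestor
  (inclusive) to each tip (exclusive). The alternative (ancestor-exclusive)
  convention shifts every count by one and leaves correlations unchanged.
* Flanking genes: a gene qualifies at window w iff its distance to the
  nearest qualifying element is ≤ w, overlap counting as 0; the per-window
  sets are nested by construction.

No multiple-testing correction is applied inside these primitives.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale: end-to-end
recovery on a 500 kb genome with 30 intact ERVs + 30 solo-LTRs;
divergence robustness on ten 150 kb genomes (15 + 15) per divergence
level, scanned against the family-master library; sharing on a
three-species clade with 50 elements per branch; populations of 19
individuals over 500 elements at 20× depth. These sizes give stable
statistics (binomial error on recovery rates ≲ 2 percentage points) while
keeping a full run in minutes on one core.

All coordinates are 0-based half-open (BED convention) internally and in
every output. Seeded runs are bit-reproducible. A genome with no LTR bp at
all yields a NaN formation ratio with a warning rather than an error.

## Known limitations

* The scanner's seed length (11) bounds sensitivity: queries diverged
  beyond ~30% from every library entry may present no exact 11-mer and be
  missed before the identity floor applies — consistent with the 65%
  scan threshold, but a caveat for shorter queries.
* Nested or overlapping insertions are out of scope (the simulator's
  `nested` stress mode is not implemented; elements never overlap).
* Candidate annotation quality is an input contract: the pipeline
  intersects two sources but cannot recover LTRs neither source saw.
* Insertion dating by LTR–LTR divergence, proviral ORF annotation, and
  expression analyses are deliberately outside the package.
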