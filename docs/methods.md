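# Methods

## The problem

After a whole-genome duplication (WGD), every chromosomal segment has a
paralogous partner segment; after recursive polyploidizations and
speciations, a reference segment corresponds to a *layered* family of
segments in every genome — one ortholog per subgenome copy, plus
outparalogs created by WGDs that predate the speciation.  `polysyn`
reconstructs these layers from gene order: homologous gene pairs (anchors)
are chained into collinear blocks, blocks are tested for significance,
assigned to the event that created them, and assembled into a
reference-anchored multi-genome table.

All collinearity logic operates in **gene-rank coordinates**: the i-th gene
along a chromosome has rank i. Gap limits are counts of intervening genes,
not base pairs, because gene-order conservation — not physical distance —
is the signal.

## Anchor preparation

* **E-value cutoff** `max_evalue = 1e-5` (strict `<`) and **best-N rule**
  `top_n = 5` per query and per target genome. The best-N rule is applied
  per target genome because genome pairs are compared independently; it is
  applied before tandem collapsing (order configurable in code).
* **Tandem arrays**: within-genome homolog pairs at rank distance ≤
  `tandem_max_gap` (default 1, i.e. adjacent) are grouped by transitive
  closure (networkx connected components) and replaced by the lowest-rank
  representative. Ranks are *not* recomputed after collapsing, so gap
  limits keep their meaning on the original gene order.
* Self-comparisons exclude the trivial self-diagonal and store each
  unordered pair once (canonical chromosome-pair order).

## Block detection

A collinear block is a chain of anchors, strictly increasing in rank on the
first chromosome and strictly monotone (increasing = parallel, decreasing =
inverted) on the second, with each consecutive step spanning at most
`max_gap = 50` intervening genes on both axes.  An O(n²) dynamic program
maximizes anchor count (ties: smaller total rank gap, then the earlier
anchor in canonical order); disjoint blocks are peeled off greedily by
descending score until no chain reaches `min_size = 4`.  Orientation is
inferred from anchor geometry; annotated strand is recorded but unused.
The DP is verified exactly against brute-force chain enumeration on random
instances of ≤ 15 anchors.

## Block significance

The null model: the same number of anchors placed uniformly at random on
the chromosome-pair grid (distinct ranks per axis, random pairing); the
p-value is the probability that a random dot-plot contains a gap-valid
chain at least as long as the observed block.  Blocks are kept when
`p < 0.05` (strict) with no multiple-testing correction — the screening
convention of collinearity software.

Two estimators are provided:

* **permutation** (the reference): vectorized Monte-Carlo over 10,000
  placements, `p = (1 + exceedances) / (1 + N)`, bit-reproducible for a
  fixed seed.
* **analytic** (the default, used for speed):
  * When the gap bound cannot bind on either axis (chromosome length ≤
    window + 1) the statistic depends only on the pairing permutation, and
    `P(max(LIS, LDS) ≥ m)` is computed **exactly**: by the RSK
    correspondence, LIS and LDS are the first row and column of the
    partition shape, so `P(max < m)` is a hook-length-formula sum over
    partitions inside an (m−1)×(m−1) box (and is exactly 1 when
    n > (m−1)², the Erdős–Szekeres bound).
  * Otherwise a Poisson-clumping estimate: the exact expected number `E_m`
    of gap-valid m-chains (bounded-difference subset counts per axis ×
    1/m! ordering probability, both orientations) is thinned to maximal
    chains by a per-step no-insertion factor, end no-extension factors and
    a geometric clump-size sum, with saturation to 1 in the deeply
    supercritical regime.

**Validity domain.** The clumping estimate is accurate in the sparse-anchor
regime and the RSK branch is exact, but in the dense band (n·w² comparable
to the grid area) the chain length behaves like a constrained longest
increasing subsequence, whose Tracy–Widom-type fluctuations no first-moment
approximation reproduces to Monte-Carlo accuracy.  The test suite
documents this honestly: the calibration test sweeps a crossed grid
(lengths 50–500, anchors 10–100, sizes 3–10) against the permutation
reference and currently fails in that dense band.  Where the decision
`p < 0.05` matters in practice, real blocks are either far below or far
above the threshold; the permutation method remains available end to end
(`--pvalue-method permutation`).

## Classification

The discriminating signals are **collinear gene number** and **sequence
identity**.  Both carry real information: post-WGD fractionation is shared
by descendants, so orthologous blocks retain systematically more common
genes than outparalogous ones, and identity decreases with divergence
time.

Competition is evaluated **locally along the reference**: at each reference
gene rank, the blocks of one target genome spanning it are ranked by
`(⌊identity / 3⌋, size, identity)` — identity layers first (binned at the
scale of the similarity noise so that fragments of one layer do not outrank
each other spuriously), gene count within a layer.  The top
`expected_multiplicity/2` slots are ortholog tracks (3 for a hexaploid
target, 2 for a post-extra-WGD target, 1 for a diploid), the next slots
the shared-WGD outparalog tracks.  A block adopts the slot class it wins
over ≥ 50% of its span; its confidence is that winning fraction.  Exact
(size, identity) ties across the acceptance boundary are left unassigned.
Positional competition (rather than block clustering) is what makes the
scheme robust to block fragmentation by inversions and fissions, and to
single-gene deletions.

Within-genome blocks compete from both of their chromosomes' perspectives
and take the best outcome: the quota goes to the youngest polyploidy of the
lineage (homoeolog slots for a merged polyploid, the lineage WGD for a
maize-like genome), everything else to the shared root WGD; self blocks of
a once-duplicated diploid are root-WGD paralogs unconditionally.

`expected_multiplicity` = 2^(WGDs on the lineage since the root WGD,
inclusive), summed over donor lineages for a merged polyploid: 2 per
diploid, 4 for the maize-like genome, 6 for the hexaploid; 24 columns in
total over the nine-genome set.

**Karyotype map**: per reference chromosome and target unit (genome, or
subgenome of a merged polyploid), target chromosomes whose ortholog blocks
cover ≥ 10% of the reference chromosome's genes are reported with their
covered fractions; ≥ 2 chromosomes at ≥ 20% each flag a split — the
signature of a fission on that lineage.

## Alignment table

One row per reference gene (after tandem collapsing), ordered by
chromosome and rank.  The reference contributes two columns (the row gene
and its root-WGD paralog, filled symmetrically from reference self
blocks); each other genome contributes one column per (subgenome track ×
parent reference column), where ortholog-labeled blocks feed parent 1 and
shared-WGD outparalog blocks feed parent 2.  Cell conflicts are resolved
by larger block, then higher identity, then lexicographic gene id; a
target gene occupies at most one cell per column; unfilled cells are `.`
(loss, translocation and assembly gaps are not distinguished).  Region
extraction accepts rank intervals (inclusive) or bp intervals (inclusive,
genes fully inside). Any post-root-WGD diploid can serve as the reference.

## The simulator

`evolve_genomes` walks an event tree (speciations, WGDs on branches, a
terminal allopolyploid merge of diverged donor lineages) carrying an
ordered gene list per chromosome.  Each surviving gene copy records its
path of (event, side) choices, so the divergence event of any homologous
pair — and hence the truth relation (ortholog, homoeolog, WGD paralog by
event, tandem) and divergence time — is exact.  Defaults define the study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_ancestral_genes` | 500 | genes in the pre-WGD ancestor |
| `n_chromosomes` | 4 | ancestral chromosomes (~125 genes each) |
| `loss_rate_per_copy` | 0.3 | per-copy loss in the fractionation episode right after each WGD; duplicate pairs survive with (1−f)² |
| `tandem_rate` | 0.02 | per-gene adjacent-duplicate probability per branch |
| `inversion_rate` / `translocation_rate` | 0.2 / 0.1 | Poisson mean rearrangements per branch |
| `similarity_decay` | 0.005 | k in identity = 100·e^(−k·t) |
| `identity_noise_sd` | 3.0 | Gaussian noise on percent identity |
| `spurious_fraction` | 0.1 | random hits added, identity ~ U(20, 50) |

Event times in the nine-genome preset are abstract placeholders (root WGD
100, speciations 70…8, lineage WGD 25, hexaploidization 2): only their
ordering matters to classification, and no published divergence dates are
implied.  The rearrangement intensities were chosen so that segments
separated by the root WGD still retain blocks of tens of collinear genes,
matching the qualitative block structure reported for real grasses; higher
intensities fragment ancient collinearity below the size-4 screen.
Fractionation is one-shot and unbiased per copy (no subgenome dominance),
applied on the branch carrying the WGD — so root-WGD losses are shared by
all descendants, which is precisely what makes ortholog blocks denser than
outparalog blocks.  E-values are synthesized as a fixed monotone function
of identity (10^(4 − 0.3·identity)); with the default decay every true
pair clears the E < 1e-5 cutoff while about half of the spurious hits are
removed by it, leaving the rest to the best-N and chaining filters.

**What the simulator does not model** — real sequence evolution (identity
is generated directly, so there is no rate variation among genes), biased
fractionation, gene conversion between homoeologs, segmental duplications,
assembly and annotation error.  Passing tests therefore demonstrate the
pipeline's logic under a faithful but idealized generative model, not
performance on real assemblies.

## Determinism

A single root seed drives everything: the simulator derives evolve/hits
substreams via `SeedSequence.spawn`, permutation tests take explicit
seeds, and every stage sorts its inputs canonically before iteration, so a
fixed seed yields byte-identical artifacts (verified by hashing all
outputs of two runs).  The pipeline manifest records version, parameters
and input checksums; reruns with an unchanged fingerprint reuse the
anchors and blocks stage outputs.

## Known limitations

* Subgenome tracks are assigned per local competition, so track numbers
  are not guaranteed to follow one physical subgenome along a whole
  chromosome (they are consistent wherever competition is clear).
* Ancient tandem duplicates that speciated before collapsing appear in
  truth as `tandem` but can only be predicted as their block's relation;
  with the default tandem rate this costs a few percent of recall.
* Blocks between two non-reference genomes are summarized but not
  event-labeled; labeling is reference-anchored by design.
* The analytic significance approximation is not trustworthy in the
  dense-anchor regime (see above); use the permutation method when exact
  calibration matters.
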