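# Methods

This note documents the models, conventions and numerical choices behind
`lrrkit`, and what the synthetic-data tests do and do not demonstrate about
real genomes.

## Identification cascade

A candidate is a *family member* iff its protein carries **at least one
LRR-class and at least one kinase-class domain hit** surviving the E-value
filter. Choices:

- **E-value filter is strict** (`evalue < e_max`, default 1e-3): a hit at
  exactly 0.001 is removed.
- **Domain classes** come from a packaged accession→class table seeded with
  the five Pfam LRR-clan families (PF00560, PF13306, PF13516, PF13855,
  PF08263) and the two protein-kinase families (PF00069, PF07714). The table
  is user-overridable; unknown accessions classify as `other` and never make
  a gene a member.
- **Overlapping LRR hits are merged before counting.** Different LRR-clan
  profiles routinely tile the same repeat region; counting envelopes after
  interval-merging prevents one repeat block from being scored once per
  profile. Kinase hits are counted as-is, because tandem kinase domains are
  a real architecture worth reporting.
- **Similarity rescue** is modeled as an externally supplied candidate-id
  list that is unioned with the HMM-derived set and then subjected to the
  same architecture rule. Running an actual BLAST search is out of scope;
  the cascade's logic (union, then filter, with provenance recorded) is what
  is under test.
- **Tree pruning** removes members whose nearest labeled reference leaf
  exceeds a patristic-distance ceiling (default 1.0 substitutions/site,
  configurable). The published surveys delete "inaccurate sequences" by eye;
  an explicit, logged distance rule is the auditable stand-in. On p-distance
  trees all distances are < 1, so a meaningful ceiling there must be set
  below the between-subgroup plateau (the generator tests use 0.5, which
  cleanly separates members at ≤ 0.49 from planted outliers at ≈ 0.94).

## Distances, NJ, bootstrap, classification

- **p-distance**: mismatches over compared sites. Default gap handling is
  pairwise deletion; complete deletion is available. The generator emits
  indel-free alignments, where the two modes coincide.
- **Neighbor-joining** follows Saitou–Nei agglomeration. Join ties break to
  the smallest (i, j) index pair in current taxon order (row-major argmin),
  making the topology deterministic. Negative branch lengths are clamped to
  zero — the standard practice; on additive inputs no clamping ever
  triggers, and NJ provably reproduces the generating tree, which the tests
  verify to 1e-9 on random additive matrices.
- **Bootstrap** resamples alignment columns with replacement; each internal
  edge of the full-data tree is scored by the percentage of replicate trees
  containing the same bipartition. One `numpy` generator seeded once drives
  all replicates, so runs are reproducible. The conventional 1000 replicates
  is the library default; the pipeline default is 100, which on a
  ~64-taxon, 350-column family alignment runs in a few seconds and saturates
  the planted clades at 100% support.
- **Subgroup assignment**: a query leaf takes the label of the *smallest*
  bipartition side (support ≥ 50% by default) containing it and at least one
  reference, with all contained references agreeing on one label; otherwise
  it is unclassified. Both sides of every internal edge are candidate
  clades, as appropriate for an unrooted tree. Edges without a recorded
  support (e.g. a plain NJ tree) count as fully supported. The 24 subgroup
  labels and per-species reference counts are packaged as
  `data/subgroup_census.tsv`; LRR-I is carried as a single subgroup.

## Gene structure

Exons are counted on the **primary transcript** (explicit flag, else longest
CDS, ties to the lexicographically smallest transcript id — "first
transcript" is otherwise undefined in common annotation releases).
Per-subgroup summaries use the **sample (n−1) standard deviation**: the
published per-subgroup SD values that are uniquely reconstructable from
their n/min/max/mean are consistent with the sample convention (e.g.
{4,4,4,5} → 0.50 and {1,2,2} → 0.58), so that convention is fixed here.
One published singleton-ish row (n=2, SD printed as 1) is only consistent
with the population convention; we treat that as an inconsistency of the
printed table rather than grounds to mix conventions.

## Duplications and collinearity

- **Tandem rule**: family genes on one chromosome chain into a cluster while
  consecutive genes are within 200 kb; clusters need ≥ 2 members. Distance is
  measured end-to-start (start-to-start available). Intervening non-family
  genes are irrelevant to the rule. For non-nested gene layouts this
  consecutive chaining equals all-pairs single-linkage, which the tests
  assert against a connected-components oracle. Tandem *pairs* are counted
  as consecutive pairs (a 5-gene cluster contributes 4); all-pairs counting
  is available, since published pair/gene tallies do not disambiguate the
  convention.
- **Anchors**: all-vs-all Smith–Waterman (BLOSUM62, gap open −11 / extend
  −1) with a Karlin–Altschul E-value estimate; defaults `min_score=100`,
  `e_max=1e-6`. Random 200-aa protein pairs score far below the floor (a
  100-draw control keeps zero anchors), while duplicates at the planted
  divergences score thousands.
- **Blocks**: anchors map to (rank_a, rank_b) points per chromosome pair;
  the best strictly monotonic chain (per-step rank gap ≤ 25 on both sides,
  both orientations) is extracted by DP, removed, and the search repeated;
  chains shorter than `min_anchors=3` are discarded. Three is a deliberate
  desk-scale default (genome-scale tools commonly use 5); both knobs are
  exposed. Anchors internal to one tandem cluster are excluded before
  chaining in the pipeline, mirroring standard collinearity practice, so
  local duplications are not double-reported as segmental blocks.

## NG86 Ka/Ks and dating

- Site fractions: each of a codon's nine single-base changes contributes 1/3
  site; **changes creating stop codons count as nonsynonymous sites**.
  Substitutions between differing codons average over all orderings of the
  differing positions; **pathways through stop codons are excluded whenever
  a stop-free pathway exists** (all pathways are used otherwise). Both
  conventions are the common NG86 practice and are pinned by a brute-force
  enumeration oracle to 1e-9.
- Proportions are Jukes–Cantor corrected; p ≥ 3/4 sets the `saturated` flag
  and leaves the value undefined rather than extrapolating.
- Selection classes use strict inequalities around 1 (`neutral_band=0` by
  default, configurable).
- Dating: `T = Ks / (2γ)` with γ = 1.5×10⁻⁸ substitutions/site/year (the
  dicot nuclear-gene rate), reported in MYA; 1 Ks unit ↔ 33.3 MYA.
- Histograms use half-open bins `[k·w, (k+1)·w)` with a 1e-12 float guard so
  edge values land in the upper bin.

## Promoters

The promoter is the 2-kb genomic window upstream of the gene start (CDS
start selectable), reverse-complemented for minus-strand genes so position 1
is always the base farthest from the gene; windows truncate with a warning
at chromosome boundaries, and a gene at position 1 yields a flagged empty
sequence. The packaged 20-element library holds literature consensus strings
(W-box TTGACY, G-box CACGTG, as-1 TGACG, ABRE ACGTG, …) as editable IUPAC
patterns — an approximation, not a reproduction, of any database's
proprietary matrices. Overlapping occurrences all count; a palindromic match
is one locus, counted once.

## Expression

- Replicate condensation is the arithmetic mean per condition.
- Specificity: `τ = Σ_i (1 − x_i/x_max)/(N−1)`. A gene is *specific* when
  τ ≥ 0.8 and the set of conditions within 2× of the maximum is a proper
  subset of all conditions (those conditions are the call); *high* when not
  specific but the maximum exceeds 2× the row mean. No published criterion
  defines "specifically expressed", so all calls are explicitly
  criterion-relative and both thresholds are parameters. Note τ bounds what
  is callable: k conditions out of N can reach at most (N−k)/(N−1), so
  2-of-12 profiles (τ ≤ 10/11) are callable at τ ≥ 0.8 but 4-of-12 (τ ≤
  8/11) are not — the generator plants 2-condition (root + nodule) specific
  genes accordingly.
- Infection peaks: argmax over genotype×time condition means, ties to the
  earliest time then configured genotype order; called when the peak is
  ≥ 2× the baseline condition (untreated wild type), with infinite fold on a
  zero baseline.
- Heatmap ordering: average-linkage hierarchical clustering on Euclidean
  distances of log2(x+1) rows (row z-scoring available); deterministic, and
  a constant matrix returns input order.
- qPCR: 2^(−ΔΔCt) against a reference gene and calibrator sample, with
  replicate Ct values averaged first and per-replicate spread reported.

## Synthetic-data generator

The generator emulates the inputs of a family survey at desk scale, with a
single mandatory seed feeding every random draw:

- **Genome**: 3 chromosomes × 3 Mb (3 Mb rather than 2 keeps ~30 family
  "islands" separable by > 200 kb; the full bundle still builds in under ten
  seconds), ~160 background genes, 40 family genes, 2 of them on unplaced
  scaffolds, optional planted outliers. Family islands are spaced > 200 kb
  so the planted tandem clusters are exactly the detectable ones.
- **Sequences**: one random 350-aa ancestor per subgroup; members evolve
  from it by seeded codon substitution (`evolve_cds`), which plants
  `round(Ks·S)` synonymous and `round(ω·Ks·N)` nonsynonymous events with
  repeat hits allowed (so the Jukes–Cantor correction is the right
  estimator) and stop-creating changes rejected. Tandem-cluster members are
  chained duplications at Ks 0.15; segmental anchor pairs are duplications
  at Ks 0.6, ω = 0.2 throughout. All family/reference proteins share one
  length, so the emitted "alignment" is exact and indel-free — real
  alignments with indels and alignment error are *not* exercised, which is
  the main caveat on the phylogenetic results.
- **Domain hits**: members get 1–3 disjoint LRR envelopes (occasionally a
  second clan profile overlapping the first, to exercise interval merging)
  plus kinase hits (two genes carry two). Background decoys include
  LRR-only, kinase-only, above-threshold, and exactly-at-threshold hits.
- **Promoters**: 2–4 concrete library-element instances are written into
  each family promoter at non-overlapping offsets, strand-correctly. The
  truth counts come from an independent position-by-position scan of the
  final sequence, so incidental background matches are part of the truth,
  not noise.
- **Expression**: log-normal baselines (median ≈ 20); specific genes at 8×
  baseline in (root, nodule_10d) and ~0 elsewhere; 36 genes peaking at
  (skl, 12 h) with echoes in wild type and lyk3, 21 at (skl, 48 h); 6 genes
  double-positive; Gaussian replicate noise (SD 0.5) truncated at zero.
  Gaussian noise on abundances matches pre-normalized public matrices, not
  count data.
- A **self-check** verifies the truth tables against the emitted files
  (gene counts, CDS↔protein consistency, exon counts, alignment shape)
  before the bundle is returned.

Passing the generator-truth tests demonstrates that each algorithm
implements its stated rule exactly under clean, planted conditions. It does
not demonstrate robustness to annotation errors, alignment uncertainty,
partial domain hits, or platform-specific expression normalization.

## Known limitations

- MSA construction, HMM scanning and BLAST searches are consumed as inputs,
  never executed.
- NG86 is the only Ka/Ks estimator (no ML codon models, no codon-frequency
  corrections, no confidence intervals).
- The motif library is a consensus-string approximation; no enrichment
  statistics are computed.
- Collinearity works in rank space on gene orders; it does not infer
  whole-genome duplications or handle nested/overlapping gene models
  specially.
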