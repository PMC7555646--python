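# lrrkit

Genome-wide characterization of plant **LRR receptor-like kinase (LRR-RLK)
gene families**: identify family members from domain architecture, classify
them phylogenetically into the canonical 24 LRR-RLK subgroups, quantify gene
structure, detect and date tandem/segmental duplications, scan promoters for
cis-regulatory elements, and profile tissue and infection-time-course
expression.

LRR-RLKs are the largest subfamily of plant receptor-like kinases: an
extracellular leucine-rich-repeat region, a transmembrane segment, and an
intracellular kinase domain. Surveys of this family — in *Medicago
truncatula*, soybean, Arabidopsis and many other species — all follow the
same analysis skeleton, usually stitched together from web servers and
one-off scripts. `lrrkit` packages that skeleton as a tested, seedable
library plus CLI, and ships a synthetic-genome generator with machine-readable
planted truth so every stage can be validated offline.

## What it computes

- **Identification** — domain hits (hmmscan-style tables) filtered at
  E < 0.001, the architecture rule *≥1 LRR domain AND ≥1 kinase domain*,
  union with a similarity-rescue candidate set, and optional pruning of
  long-branch members by patristic distance to labeled references.
- **Classification** — p-distance (`p = mismatches / compared sites`),
  Saitou–Nei neighbor-joining on
  `Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, bootstrap supports by
  column resampling, and subgroup labels from the smallest well-supported
  clade anchored by references (RLK-Pelle_LRR-I … RLK-Pelle_LRR-XV).
- **Gene structure** — exon counts of the primary transcript, per-subgroup
  min/max/mean and sample (n−1) standard deviation.
- **Duplications** — tandem clusters under the 200-kb rule (consecutive
  family genes ≤ 200 kb apart), and collinear segmental blocks as
  maximum-score strictly monotonic anchor chains in gene-rank space
  (Smith–Waterman/BLOSUM62 anchors, dynamic-programming chaining).
- **Ka/Ks and dating** — Nei–Gojobori (NG86): per-codon synonymous site
  fractions by single-mutation enumeration, substitution counts averaged over
  all minimal mutational pathways, Jukes–Cantor correction
  `d = −(3/4)·ln(1 − (4/3)p)`, selection classes (Ka/Ks < 1 purifying,
  = 1 neutral, > 1 positive), and duplication ages `T = Ks / 2γ` with
  γ = 1.5×10⁻⁸ synonymous substitutions/site/year.
- **Promoters** — strand-correct 2-kb upstream extraction and IUPAC consensus
  scanning against a packaged 20-element library (G-box, W-box, as-1, ABRE,
  MBS, …), overlaps counted, palindromes deduplicated per locus.
- **Expression** — replicate means, tissue-specificity by
  `τ = Σ(1 − x_i/x_max)/(N−1)` with a fold rule, infection time-course peak
  calls (argmax with fold over the untreated wild-type baseline), hierarchical
  heatmap ordering, and qPCR 2^(−ΔΔCt) quantification.

## Worked example

Simulate a study-scale bundle (3 chromosomes, 200 genes, a planted 40-member
family) and run the full pipeline:

```bash
lrrkit simulate --seed 1 --outdir demo/bundle
# wrote bundle to demo/bundle (200 genes, 40 family)

lrrkit characterize --outdir demo/run \
  --domains demo/bundle/domains.tsv --proteins demo/bundle/proteins.fa \
  --alignment demo/bundle/alignment.fa \
  --reference-labels demo/bundle/reference_labels.tsv \
  --gff3 demo/bundle/genes.gff3 --cds demo/bundle/cds.fa \
  --genome demo/bundle/genome.fa --rescue demo/bundle/rescue_ids.txt \
  --tissues demo/bundle/tissues.tsv --infection demo/bundle/infection.tsv \
  --ct demo/bundle/ct.tsv --seed 1
# family size: 40
# report written to demo/run/report.json
```

The report (`demo/run/report.json`) then contains, among other sections:

```
family: {'n_members': 40, 'min_length': 350, 'max_length': 350, 'n_multi_kinase': 2}
dups:   {'n_tandem_clusters': 3, 'n_tandem_genes': 10, 'n_tandem_pairs': 7,
         'n_segmental_blocks': 2, 'n_segmental_pairs': 7,
         'chromosome_counts': {'chr1': 11, 'chr2': 15, 'chr3': 12}, 'n_unplaced': 2}
kaks:   {'n_pairs': 14, 'n_purifying': 14, 'n_positive': 0,
         'ratio_hist': {'0.10-0.20': 4, '0.20-0.30': 10},
         'mya_hist': {'0.0-5.0': 4, '5.0-10.0': 3, '15.0-20.0': 4, '20.0-25.0': 3}}
```

Reading: all 40 planted family members were identified (none of the 160
background genes leaked in); the three planted tandem clusters (2+3+5 genes,
7 consecutive pairs) and both collinear blocks (4+3 anchor pairs) were
recovered; the 14 duplicate pairs are all under purifying selection, with
tandem pairs dating young (planted Ks 0.15 ≈ 5 MYA) and segmental pairs older
(planted Ks 0.6 ≈ 20 MYA). The expression section recovers the planted
36-gene (skl, 12 h) infection-response set and the 6 genes that are both
root/nodule-specific and skl-12 h responders.

Every stage is also importable directly (`lrrkit.identify`, `lrrkit.phylo`,
`lrrkit.kaks`, …) and operates on plain FASTA/GFF3/TSV files.

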