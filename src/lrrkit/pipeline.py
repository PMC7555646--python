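"""End-to-end orchestration: identify -> classify -> structure ->
duplications -> Ka/Ks -> promoters -> expression, with per-stage outputs
and a collated report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import expression as expr
from . import identify, kaks, phylo, promoter, structure, synteny
from . import io as lio

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and per-stage parameters for a characterization run.

    Optional inputs (genome, expression matrices, Ct table) may be None:
    the corresponding stage is skipped with a logged notice.
    """

    outdir: Path
    domains: Path
    proteins: Path
    alignment: Path
    reference_labels: Path
    gff3: Path
    cds: Path | None = None
    genome: Path | None = None
    rescue: Path | None = None
    tissues: Path | None = None
    infection: Path | None = None
    ct: Path | None = None
    # parameters
    seed: int = 0
    e_max: float = 1e-3
    bootstrap_reps: int = 100
    min_support: float = 50.0
    max_gap: int = 200_000
    min_score: float = 100.0
    anchor_e_max: float = 1e-6
    min_anchors: int = 3
    max_rank_gap: int = 25
    gamma: float = 1.5e-8
    tau_min: float = 0.8
    fold_min: float = 2.0
    baseline_condition: str = "A17:0"
    ct_reference: str = "reference"
    ct_calibrator: str = "A17_0h"
    report: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {"seed": cfg.seed, "e_max": cfg.e_max,
                                   "bootstrap_reps": cfg.bootstrap_reps}}

    # ---- identification ----
    hits = lio.read_domain_hits(cfg.domains)
    kept = identify.filter_domain_hits(hits, cfg.e_max)
    proteins = lio.fasta_dict(lio.read_fasta(cfg.proteins, alphabet="protein"))
    calls = identify.call_architectures(kept, proteins)
    hmm_set = {h.gene_id for h in kept if h.domain_class == "LRR" and h.gene_id in calls}
    rescue_set: set[str] = set()
    if cfg.rescue and Path(cfg.rescue).exists():
        rescue_set = {
            line.strip() for line in Path(cfg.rescue).read_text().splitlines() if line.strip()
        }
    family = identify.merge_candidates(hmm_set, rescue_set, calls)
    identify.family_table(family).to_csv(out / "family.tsv", sep="\t", index=False)
    identify.removed_table(family).to_csv(out / "removed.tsv", sep="\t", index=False)
    report["family"] = identify.summarize_family(family)

    # ---- classification ----
    aln = lio.read_fasta(cfg.alignment, alphabet="protein")
    ref_df = pd.read_csv(cfg.reference_labels, sep="\t")
    ref_labels = dict(zip(ref_df["leaf"], ref_df["subgroup"]))
    aln_ids = {r.id for r in aln}
    missing = [m for m in family.members if m not in aln_ids]
    if missing:
        raise RuntimeError(f"classification: {missing[0]} missing from alignment")
    tree = phylo.bootstrap_supports(aln, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
    lio.write_newick(tree, out / "family_tree.nwk")
    assignments = phylo.assign_subgroups(tree, ref_labels, cfg.min_support)
    assignments = [a for a in assignments if a.gene_id in set(family.members)]
    phylo.assignment_table(assignments).to_csv(out / "subgroups.tsv", sep="\t", index=False)
    subgroup_counts: dict[str, int] = {}
    for a in assignments:
        key = a.subgroup if a.status == "assigned" else "unclassified"
        subgroup_counts[key] = subgroup_counts.get(key, 0) + 1
    report["subgroup_counts"] = subgroup_counts

    # ---- gene structure ----
    annotation = lio.read_gff3(cfg.gff3)
    counts = structure.exon_counts(annotation, family)
    stats = structure.subgroup_stats(counts, assignments)
    structure.stats_table(stats).to_csv(out / "structure.tsv", sep="\t", index=False)
    pd.Series(counts, name="exon_count").rename_axis("gene_id").to_csv(
        out / "exon_counts.tsv", sep="\t"
    )
    report["structure"] = {
        "min_exons": min(counts.values()),
        "max_exons": max(counts.values()),
    }

    # ---- duplications ----
    clusters = synteny.detect_tandem_clusters(family.members, annotation, cfg.max_gap)
    with open(out / "tandem_clusters.tsv", "w") as fh:
        fh.write("chrom\tmembers\tspan_bp\tn_pairs\n")
        for c in clusters:
            fh.write(f"{c.chrom}\t{','.join(c.members)}\t{c.span}\t{c.n_pairs}\n")
    family_proteins = [proteins[g] for g in family.members]
    anchors = synteny.find_anchor_pairs(
        family_proteins, min_score=cfg.min_score, e_max=cfg.anchor_e_max
    )
    # anchors inside one tandem cluster describe local, not segmental, events
    in_cluster: set[tuple[str, str]] = set()
    for c in clusters:
        for i, a in enumerate(c.members):
            for b in c.members[i + 1 :]:
                in_cluster.add((min(a, b), max(a, b)))
    seg_anchors = [a for a in anchors if (a.gene_a, a.gene_b) not in in_cluster]
    blocks = synteny.detect_collinear_blocks(
        seg_anchors, annotation, cfg.min_anchors, cfg.max_rank_gap
    )
    with open(out / "blocks.tsv", "w") as fh:
        fh.write("chrom_a\tchrom_b\torientation\tn_anchors\tanchors\n")
        for b in blocks:
            pairs = ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors)
            fh.write(f"{b.chrom_a}\t{b.chrom_b}\t{b.orientation}\t{len(b.anchors)}\t{pairs}\n")
    synteny.write_links(blocks, annotation, annotation, out / "links.tsv")
    synteny.write_family_bed(annotation, family.members, out / "family.bed")
    cmap = synteny.chromosome_map(annotation, family.members, clusters)
    report["duplications"] = {
        "n_tandem_clusters": len(clusters),
        "n_tandem_genes": sum(len(c.members) for c in clusters),
        "n_tandem_pairs": synteny.tandem_pair_count(clusters),
        "n_segmental_blocks": len(blocks),
        "n_segmental_pairs": sum(len(b.anchors) for b in blocks),
        "chromosome_counts": cmap["counts"],
        "n_unplaced": len(cmap["unplaced"]),
    }

    # ---- Ka/Ks dating ----
    if cfg.cds and Path(cfg.cds).exists():
        cds = lio.fasta_dict(lio.read_fasta(cfg.cds, alphabet="dna"))
        kcfg = kaks.KaKsConfig(gamma=cfg.gamma)
        pairs: list[tuple[str, str, str]] = []
        for c in clusters:
            for a, b in zip(c.members, c.members[1:]):
                pairs.append((a, b, "tandem"))
        for blk in blocks:
            for anc in blk.anchors:
                pairs.append((anc.gene_a, anc.gene_b, "segmental"))
        results = []
        kinds = []
        for a, b, kind in pairs:
            aln_pair = kaks.codon_align(proteins[a].seq, proteins[b].seq, cds[a], cds[b])
            results.append(kaks.ng86_kaks(aln_pair, kcfg))
            kinds.append(kind)
        ktab = kaks.kaks_table(results)
        ktab["kind"] = kinds
        ktab.to_csv(out / "kaks.tsv", sep="\t", index=False)
        ratios = [r.ratio for r in results if r.ratio is not None]
        times = [r.t_mya for r in results if r.t_mya is not None]
        report["kaks"] = {
            "n_pairs": len(results),
            "n_purifying": sum(1 for r in results if r.selection == "purifying"),
            "n_positive": sum(1 for r in results if r.selection == "positive"),
            "ratio_hist": {f"{lo:.2f}-{hi:.2f}": n
                           for (lo, hi), n in kaks.histogram(ratios, kcfg.bin_width).items()},
            "mya_hist": {f"{lo:.1f}-{hi:.1f}": n
                         for (lo, hi), n in kaks.histogram(times, 5.0).items()},
        }
    else:
        log.info("kaks stage skipped: no CDS input")

    # ---- promoters ----
    if cfg.genome and Path(cfg.genome).exists():
        genome = lio.fasta_dict(lio.read_fasta(cfg.genome, alphabet="dna"))
        library = promoter.load_motif_library()
        hits_per_gene = {}
        for gid in family.members:
            prom = promoter.extract_upstream(genome, annotation[gid])
            if not prom.seq:
                continue
            hits_per_gene[gid] = promoter.scan_elements(prom, library, gene_id=gid)
        counts_df = promoter.element_count_table(hits_per_gene, library)
        counts_df.to_csv(out / "promoter_counts.tsv", sep="\t")
        report["promoters"] = {
            "element_totals": counts_df.sum(axis=0).to_dict(),
        }
    else:
        log.info("promoter stage skipped: no genome input")

    # ---- expression ----
    if cfg.tissues and Path(cfg.tissues).exists():
        tissues = lio.read_expression_tsv(cfg.tissues)
        means = expr.replicate_means(tissues)
        spec = expr.specificity_calls(means, cfg.tau_min, cfg.fold_min)
        spec_ids = sorted(s.gene_id for s in spec if s.mode == "specific")
        order = expr.heatmap_order(means)
        means.values.loc[order].to_csv(out / "tissue_means.tsv", sep="\t")
        report["expression_tissues"] = {
            "n_specific": len(spec_ids),
            "specific_ids": spec_ids,
        }
    else:
        spec_ids = []
        log.info("tissue expression stage skipped")

    if cfg.infection and Path(cfg.infection).exists():
        infection = lio.read_expression_tsv(cfg.infection)
        imeans = expr.replicate_means(infection)
        peaks = expr.peak_time_calls(imeans, cfg.baseline_condition, cfg.fold_min)
        peak_df = pd.DataFrame(
            [{"gene_id": p.gene_id, "peak": p.peak_condition,
              "fold": p.fold_over_baseline, "called": p.called} for p in peaks]
        )
        peak_df.to_csv(out / "infection_peaks.tsv", sep="\t", index=False)
        skl12 = sorted(p.gene_id for p in peaks if p.called and p.peak_condition == "skl:12")
        double = sorted(set(skl12) & set(spec_ids))
        report["expression_infection"] = {
            "n_skl12_peak": len(skl12),
            "n_double_positive": len(double),
            "double_positive": double,
        }
    else:
        log.info("infection expression stage skipped")

    if cfg.ct and Path(cfg.ct).exists():
        ct = lio.read_ct_table(cfg.ct)
        ddct = expr.delta_delta_ct(ct, cfg.ct_reference, cfg.ct_calibrator)
        ddct.to_csv(out / "qpcr.tsv", sep="\t", index=False)
        report["qpcr"] = {"n_rows": len(ddct)}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
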