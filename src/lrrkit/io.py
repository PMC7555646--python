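"""Readers and writers for the formats the pipeline consumes and emits.

FASTA goes through Biopython, GFF3 through gffutils, trees through
dendropy; everything is validated into the types of :mod:`lrrkit.models`.
"""

from __future__ import annotations

import logging
import re
from importlib import resources as _ilres
from pathlib import Path

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .models import (
    DNA_ALPHABET,
    Annotation,
    DomainHit,
    ExpressionMatrix,
    GeneModel,
    SequenceRecord,
    TranscriptModel,
)

log = logging.getLogger(__name__)

_ACC_VERSION_RE = re.compile(r"\.\d+$")


# ---------------------------------------------------------------------------
# FASTA


def _guess_alphabet(seq: str) -> str:
    letters = {c.upper() for c in seq} - {"-"}
    return "dna" if letters <= DNA_ALPHABET else "protein"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated records.

    Raises on an empty file, duplicate ids, or residues outside the IUPAC
    alphabet (auto-detected per record unless ``alphabet`` is given).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").upper()
        ab = alphabet or _guess_alphabet(seq)
        records.append(SequenceRecord(rec.id, seq, ab))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def fasta_dict(records: list[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {r.id: r for r in records}


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> Annotation:
    """Parse a GFF3 annotation into gene/transcript models.

    Coordinates stay 1-based inclusive. Chromosome lengths come from
    ``##sequence-region`` pragmas when present, else from the maximum
    feature end (with a logged warning).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_lengths[parts[1]] = int(parts[3])

    annotation = Annotation(chrom_lengths=chrom_lengths)
    gene_ids = set()
    for gene_feat in db.features_of_type("gene"):
        gene_ids.add(gene_feat.id)
        gene = GeneModel(
            gene_id=gene_feat.id,
            chrom=gene_feat.seqid,
            strand=gene_feat.strand,
            start=gene_feat.start,
            end=gene_feat.end,
        )
        for mrna in db.children(gene_feat, featuretype="mRNA", order_by="start"):
            tx = TranscriptModel(tx_id=mrna.id)
            tx.is_primary = mrna.attributes.get("is_primary", ["false"])[0] == "true"
            for exon in db.children(mrna, featuretype="exon", order_by="start"):
                if exon.start < gene.start or exon.end > gene.end:
                    raise ValueError(
                        f"exon {exon.start}-{exon.end} of {mrna.id} lies outside "
                        f"gene span of {gene.gene_id}"
                    )
                tx.exons.append((exon.start, exon.end))
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                tx.cds.append((cds.start, cds.end))
            gene.transcripts.append(tx)
        annotation.add(gene)

    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            raise ValueError(f"mRNA {mrna.id} has no gene parent")

    for chrom in annotation.chromosomes():
        if chrom not in chrom_lengths:
            log.warning(
                "no ##sequence-region for %s; using max feature end as length", chrom
            )
    return annotation


def select_primary_transcript(gene: GeneModel) -> TranscriptModel:
    """The representative transcript of a gene.

    Preference order: the explicitly flagged primary transcript, else the
    longest CDS, ties broken by lexicographically smallest transcript id.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    flagged = [t for t in gene.transcripts if t.is_primary]
    if flagged:
        return flagged[0]
    return min(gene.transcripts, key=lambda t: (-t.cds_length(), t.tx_id))


# ---------------------------------------------------------------------------
# Domain hit tables


def normalize_accession(acc: str) -> str:
    """Strip a trailing version suffix: PF00560.31 -> PF00560. Idempotent."""
    return _ACC_VERSION_RE.sub("", acc)


def load_domain_class_map() -> dict[str, str]:
    """The packaged accession -> {LRR, kinase} map (user-overridable)."""
    text = _ilres.files("lrrkit.data").joinpath("domain_classes.tsv").read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc, cls = line.split("\t")[:2]
        mapping[acc] = cls
    return mapping


def read_domain_hits(
    path: str | Path, class_map: dict[str, str] | None = None
) -> list[DomainHit]:
    """Read a whitespace-delimited domain-hit table.

    Columns (5+; extras ignored): target gene id, domain accession,
    full-sequence E-value, envelope from, envelope to. ``#`` lines are
    comments. Unknown accessions become domain_class "other".
    """
    class_map = class_map if class_map is not None else load_domain_class_map()
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns")
            try:
                gene_id = fields[0]
                acc = normalize_accession(fields[1])
                evalue = float(fields[2])
                env_start = int(fields[3])
                env_end = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row ({exc})") from None
            hits.append(
                DomainHit(
                    gene_id=gene_id,
                    domain_acc=acc,
                    evalue=evalue,
                    env_start=env_start,
                    env_end=env_end,
                    domain_class=class_map.get(acc, "other"),
                )
            )
    return hits


def write_domain_hits(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id accession evalue env_start env_end\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.domain_acc}\t{h.evalue:.3g}\t{h.env_start}\t{h.env_end}\n")


# ---------------------------------------------------------------------------
# Expression matrices (two-row header: condition, replicate)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    sample_ids = [f"{cond}.r{rep}" for cond, rep in df.columns]
    meta = pd.DataFrame(
        {
            "condition": [cond for cond, _ in df.columns],
            "replicate": [int(rep) for _, rep in df.columns],
        },
        index=sample_ids,
    )
    values = df.copy()
    values.columns = sample_ids
    return ExpressionMatrix(values, meta)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.columns = pd.MultiIndex.from_arrays(
        [matrix.sample_meta["condition"], matrix.sample_meta["replicate"]]
    )
    df.to_csv(path, sep="\t")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format qPCR Ct table with columns gene, sample, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Trees


def read_newick(path: str | Path) -> dendropy.Tree:
    # underscores are literal in our gene ids, not space stand-ins
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    )
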