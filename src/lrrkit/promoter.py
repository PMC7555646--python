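"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2-kb genomic stretch upstream of a gene, taken
strand-correctly (reverse-complemented for minus-strand genes) so that
position 1 of the returned sequence is the base farthest from the gene.
Elements are IUPAC consensus strings from a packaged, editable library.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .models import GeneModel, SequenceRecord

log = logging.getLogger(__name__)

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass
class MotifDef:
    name: str
    pattern: str  # IUPAC nucleotide consensus
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC characters {sorted(bad)}")


@dataclass
class CisElementHit:
    gene_id: str
    motif: str
    offset: int  # 1-based in the upstream sequence; 1 = farthest from gene
    strand: str  # "+" | "-"


def load_motif_library(path: str | Path | None = None) -> list[MotifDef]:
    """The packaged 20-element library, or a user TSV (name, pattern, strands)."""
    if path is None:
        text = _ilres.files("lrrkit.data").joinpath("motifs.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs: list[MotifDef] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, pattern, both = line.split("\t")[:3]
        motifs.append(MotifDef(name, pattern.upper(), both.strip().lower() == "true"))
    return motifs


def extract_upstream(
    genome: dict[str, SequenceRecord],
    gene: GeneModel,
    length: int = 2000,
    anchor: str = "gene_start",
) -> SequenceRecord:
    """The upstream promoter of a gene, oriented 5'->3' toward the gene.

    ``anchor`` chooses the reference point: the gene feature start
    (default) or, with "cds_start", the translation start of the primary
    transcript when CDS intervals are present. Truncated at chromosome
    boundaries with a logged warning; a gene at the chromosome edge gets
    a zero-length sequence (seq set to a single N flag is avoided; the
    caller sees seq == "").
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom].seq

    s, e = gene.start, gene.end
    if anchor == "cds_start" and gene.transcripts:
        cds = sorted(
            iv for tx in gene.transcripts if tx.is_primary or len(gene.transcripts) == 1
            for iv in tx.cds
        )
        if cds:
            if gene.strand == "+":
                s = cds[0][0]
            else:
                e = cds[-1][1]

    if gene.strand == "+":
        lo = max(1, s - length)
        hi = s - 1
        seq = chrom_seq[lo - 1 : hi] if hi >= lo else ""
    else:
        lo = e + 1
        hi = min(len(chrom_seq), e + length)
        raw = chrom_seq[lo - 1 : hi] if hi >= lo else ""
        seq = str(Seq(raw).reverse_complement())

    if len(seq) < length:
        log.warning(
            "promoter of %s truncated to %d bp at chromosome boundary",
            gene.gene_id,
            len(seq),
        )
    if seq:
        return SequenceRecord(f"{gene.gene_id}_upstream", seq, "dna")
    # zero-length promoter (gene at the chromosome edge): flagged, not an error
    rec = SequenceRecord.__new__(SequenceRecord)
    rec.id = f"{gene.gene_id}_upstream"
    rec.seq = ""
    rec.alphabet = "dna"
    return rec


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        exp = IUPAC_DNA[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def scan_elements(
    promoter: SequenceRecord,
    library: list[MotifDef],
    gene_id: str | None = None,
) -> list[CisElementHit]:
    """Every occurrence of every library motif, overlaps included.

    Minus-strand matches are located by scanning the reverse complement
    and mapping back; a palindromic motif matching the same stretch on
    both strands is counted once (plus strand kept).
    """
    if not library:
        raise ValueError("empty motif library")
    gene_id = gene_id or promoter.id
    seq = promoter.seq.upper()
    n = len(seq)
    hits: list[CisElementHit] = []
    for motif in library:
        if n < len(motif.pattern):
            continue
        rx = _iupac_regex(motif.pattern)
        plus_spans = set()
        for m in rx.finditer(seq):
            offset = m.start() + 1
            plus_spans.add(offset)
            hits.append(CisElementHit(gene_id, motif.name, offset, "+"))
        if motif.both_strands:
            rc = _revcomp(seq)
            w = len(motif.pattern)
            for m in rx.finditer(rc):
                # map reverse-complement position to forward offset
                offset = n - (m.start() + w) + 1
                if offset in plus_spans:
                    continue  # palindromic match, already counted
                hits.append(CisElementHit(gene_id, motif.name, offset, "-"))
    hits.sort(key=lambda h: (h.motif, h.offset, h.strand))
    return hits


def element_count_table(
    hits_per_gene: dict[str, list[CisElementHit]],
    library: list[MotifDef],
) -> pd.DataFrame:
    """Genes x elements occurrence-count matrix; column sums = family tallies."""
    names = [m.name for m in library]
    rows = {}
    for gene_id, hits in hits_per_gene.items():
        counts = dict.fromkeys(names, 0)
        for h in hits:
            counts[h.motif] += 1
        rows[gene_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    if df.empty:
        df = pd.DataFrame(columns=names, dtype=int)
    return df.fillna(0).astype(int)
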