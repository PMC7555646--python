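"""Shared in-memory types for the LRR-RLK characterization pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); any
half-open arithmetic is internal to the operation that needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DNA_ALPHABET = set("ACGTUNRYSWKMBDHV-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str
    alphabet: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.seq, start=1):
            if ch.upper() not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} residue {ch!r} at position {pos} "
                    f"in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """One transcript: exon and CDS intervals, 1-based inclusive."""

    tx_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    is_primary: bool = False

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GeneModel:
    """A gene locus with its transcripts."""

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class Annotation:
    """A genome annotation: genes keyed by id plus chromosome lengths.

    Chromosome length falls back to the maximum feature end seen on that
    chromosome when no explicit length was provided.
    """

    def __init__(
        self,
        genes: dict[str, GeneModel] | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ) -> None:
        self.genes: dict[str, GeneModel] = dict(genes or {})
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def chromosomes(self) -> list[str]:
        chroms = {g.chrom for g in self.genes.values()} | set(self.chrom_lengths)
        return sorted(chroms)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        """Genes on one chromosome, sorted by start then id."""
        sel = [g for g in self.genes.values() if g.chrom == chrom]
        sel.sort(key=lambda g: (g.start, g.gene_id))
        return sel

    def ranks(self, chrom: str) -> dict[str, int]:
        """0-based positional index of each gene along a chromosome."""
        return {g.gene_id: i for i, g in enumerate(self.genes_on(chrom))}

    def chrom_length(self, chrom: str) -> int:
        if chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        ends = [g.end for g in self.genes.values() if g.chrom == chrom]
        if not ends:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return max(ends)


@dataclass
class DomainHit:
    """One profile-HMM domain match on a protein."""

    gene_id: str
    domain_acc: str
    evalue: float
    env_start: int
    env_end: int
    domain_class: str = "other"  # "LRR" | "kinase" | "other"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.gene_id}/{self.domain_acc}: negative E-value")
        if self.env_start > self.env_end:
            raise ValueError(
                f"{self.gene_id}/{self.domain_acc}: envelope start > end"
            )


class ExpressionMatrix:
    """Genes x samples abundance matrix with per-sample condition/replicate.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``sample_meta`` is indexed by sample id with columns ``condition`` and
    ``replicate``.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame) -> None:
        if values.isna().any().any():
            raise ValueError("expression matrix contains NaN")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        if list(values.columns) != list(sample_meta.index):
            raise ValueError("sample metadata does not match matrix columns")
        if sample_meta["condition"].isna().any():
            raise ValueError("every sample needs a condition label")
        self.values = values
        self.sample_meta = sample_meta

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        seen: list[str] = []
        for c in self.sample_meta["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def replicate_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {c: [] for c in self.conditions()}
        for sample, row in self.sample_meta.iterrows():
            groups[row["condition"]].append(sample)
        return groups
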