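"""Nei-Gojobori (NG86) Ka/Ks estimation and duplication dating.

Synonymous/nonsynonymous site fractions are computed per codon by
enumerating the nine single-base changes; substitutions between
differing codons are counted by equal-weight averaging over all minimal
mutational pathways. Proportions are Jukes-Cantor corrected
(d = -3/4 ln(1 - 4/3 p)), and duplication ages follow the molecular
clock T = Ks / (2 gamma) with gamma the synonymous divergence rate for
dicot nuclear genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .models import SequenceRecord

_TABLE = unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, None for a stop."""
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


@dataclass
class KaKsConfig:
    """Clock and calling parameters for duplication dating.

    gamma: substitutions/synonymous site/year (default 1.5e-8, the dicot
    nuclear rate). neutral_band: half-width of the Ka/Ks interval around 1
    called neutral (0 = strict inequalities). bin_width: histogram bin.
    """

    gamma: float = 1.5e-8
    neutral_band: float = 0.0
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.neutral_band < 0:
            raise ValueError("neutral_band must be >= 0")


@dataclass
class CodonAlignment:
    """A gap-free pair of in-frame codon sequences."""

    id_a: str
    id_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon sequences differ in length")
        if len(self.codons_a) % 3 != 0 or len(self.codons_a) < 3:
            raise ValueError("codon sequence length must be a positive multiple of 3")
        for seq, sid in ((self.codons_a, self.id_a), (self.codons_b, self.id_b)):
            for k in range(0, len(seq), 3):
                if seq[k : k + 3] in _STOPS:
                    raise ValueError(f"internal stop codon in {sid}")

    def n_codons(self) -> int:
        return len(self.codons_a) // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.codons_a[k : k + 3], self.codons_b[k : k + 3])
            for k in range(0, len(self.codons_a), 3)
        ]


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    ka: float | None
    ks: float | None
    ratio: float | None
    selection: str  # purifying | neutral | positive | undefined
    t_mya: float | None
    saturated: bool


def codon_align(
    protein_a: str,
    protein_b: str,
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its coding sequences.

    Each amino-acid column maps to the corresponding codon; columns gapped
    in either row are dropped. The CDS must be exactly 3x the ungapped
    protein length (trim the terminal stop first).
    """
    if len(protein_a) != len(protein_b):
        raise ValueError("aligned proteins differ in length")
    for prot, cds in ((protein_a, cds_a), (protein_b, cds_b)):
        ungapped = prot.replace("-", "")
        if len(cds.seq) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length of {cds.id} ({len(cds.seq)}) is not 3x the "
                f"ungapped protein length ({len(ungapped)})"
            )
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for col_a, col_b in zip(protein_a, protein_b):
        if col_a != "-" and col_b != "-":
            out_a.append(cds_a.seq[3 * ia : 3 * ia + 3])
            out_b.append(cds_b.seq[3 * ib : 3 * ib + 3])
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
    # codons containing ambiguity codes are dropped pairwise
    kept_a, kept_b = [], []
    for ca, cb in zip(out_a, out_b):
        if set(ca) <= set(_BASES) and set(cb) <= set(_BASES):
            kept_a.append(ca)
            kept_b.append(cb)
    return CodonAlignment(cds_a.id, cds_b.id, "".join(kept_a), "".join(kept_b))


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Each of the nine single-base changes contributes 1/3 of a site;
    changes creating a stop codon count as nonsynonymous.
    """
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon}")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str, skip_stop_paths: bool = True):
    """(syn, nonsyn) substitution counts between two codons.

    Averages over all orderings of the differing positions; pathways
    passing through a stop codon are excluded when any stop-free pathway
    exists (all pathways are used otherwise).
    """
    diff = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        syn = nonsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                return None
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    paths = [walk(order) for order in permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid or not skip_stop_paths:
        # fall back to counting through stops, treating those steps as nonsyn
        valid = []
        for order in permutations(diff):
            cur = codon_a
            syn = nonsyn = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if cur not in _STOPS and nxt not in _STOPS and translate_codon(
                    cur
                ) == translate_codon(nxt):
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            valid.append((syn, nonsyn))
    s = sum(p[0] for p in valid) / len(valid)
    n = sum(p[1] for p in valid) / len(valid)
    return s, n


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction; None when out of domain (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(aln: CodonAlignment, cfg: KaKsConfig | None = None) -> KaKsResult:
    """NG86 Ka/Ks for one codon-aligned pair, with clock dating."""
    cfg = cfg or KaKsConfig()
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for ca, cb in aln.codon_pairs():
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        ps, pn = pathway_counts(ca, cb)
        sd += ps
        nd += pn

    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    saturated = ks is None or ka is None

    ratio: float | None = None
    if not saturated and ks is not None and ks > 0:
        ratio = ka / ks
    selection = classify_selection(ratio, cfg)
    t_mya = divergence_time(ks, cfg) if ks is not None else None
    return KaKsResult(
        gene_a=aln.id_a,
        gene_b=aln.id_b,
        ka=ka,
        ks=ks,
        ratio=ratio,
        selection=selection,
        t_mya=t_mya,
        saturated=saturated,
    )


def classify_selection(ratio: float | None, cfg: KaKsConfig | None = None) -> str:
    """purifying below 1-band, positive above 1+band, neutral between."""
    cfg = cfg or KaKsConfig()
    if ratio is None:
        return "undefined"
    if ratio < 1.0 - cfg.neutral_band:
        return "purifying"
    if ratio > 1.0 + cfg.neutral_band:
        return "positive"
    return "neutral"


def divergence_time(ks: float, cfg: KaKsConfig | None = None) -> float:
    """Age of a duplication in MYA: T = Ks / (2 gamma)."""
    cfg = cfg or KaKsConfig()
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return ks / (2.0 * cfg.gamma) / 1e6


def histogram(values: list[float], bin_width: float) -> dict[tuple[float, float], int]:
    """Half-open binning [k*w, (k+1)*w); edge values go to the upper bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = {}
    for v in values:
        idx = int(math.floor(v / bin_width))
        # float-safe edge handling: a value at (idx+1)*w belongs upstairs
        if (idx + 1) * bin_width <= v + 1e-12:
            idx += 1
        counts[idx] = counts.get(idx, 0) + 1
    return {
        (k * bin_width, (k + 1) * bin_width): counts[k] for k in sorted(counts)
    }


def kaks_table(results: list[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "ka": r.ka,
                "ks": r.ks,
                "ratio": r.ratio,
                "selection": r.selection,
                "t_mya": r.t_mya,
                "saturated": r.saturated,
            }
            for r in results
        ]
    )
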