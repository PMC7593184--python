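"""Divergence among the three mitogenomes.

Aligns three near-identical mitochondrial genomes, calls SNPs and
indels, partitions SNPs by the haplotype they are unique to,
classifies coding SNPs as synonymous or nonsynonymous under the
invertebrate mitochondrial genetic code (NCBI table 5), and computes
pairwise nucleotide diversity (pi).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .constants import INVERTEBRATE_MITO_TABLE

__all__ = [
    "CdsFeature",
    "MitoGenome",
    "DivergenceSummary",
    "align_genomes",
    "call_variants",
    "classify_substitutions",
    "pairwise_pi",
    "summarize_divergence",
]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding gene, 0-based half-open coordinates on the genome."""

    gene: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad CDS coordinates for {self.gene}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class MitoGenome:
    """A mitogenome sequence with CDS annotations."""

    id: str
    sequence: str
    cds: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        for c in self.cds:
            if c.end > len(self.sequence):
                raise ValueError(f"CDS {c.gene} extends beyond sequence of {self.id}")
            if (c.end - c.start) % 3 != 0:
                raise ValueError(f"CDS {c.gene} length not divisible by 3 in {self.id}")


def _merge_pairwise(ref: str, others: list[str]) -> list[str]:
    """Anchor-based multiple alignment of near-identical sequences.

    Each sequence is globally aligned to the reference with affine gap
    costs; the pairwise alignments are merged on reference coordinates
    (insertions relative to the reference become gap columns in every
    other row). Adequate at the ~1% divergence of conspecific
    mitogenomes; not a general MSA.
    """

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1

    L = len(ref)
    # per other-sequence: base aligned to each ref position ('-' if deleted)
    # and insertion strings keyed by the ref position they precede
    subs, inss = [], []
    for s in others:
        aln = aligner.align(ref, s)[0]
        ref_blocks, s_blocks = aln.aligned
        sub = ["-"] * L
        ins: dict[int, str] = {}
        prev_r_end = 0
        prev_s_end = 0
        for (r0, r1), (s0, s1) in zip(ref_blocks, s_blocks):
            if s0 > prev_s_end:  # insertion in s before ref position r0
                ins[r0] = ins.get(r0, "") + s[prev_s_end:s0]
            for k in range(r1 - r0):
                sub[r0 + k] = s[s0 + k]
            prev_r_end, prev_s_end = r1, s1
        if prev_s_end < len(s):
            ins[L] = ins.get(L, "") + s[prev_s_end:]
        subs.append(sub)
        inss.append(ins)

    rows = [[] for _ in range(1 + len(others))]
    ref_col_of: list[int] = []  # alignment column of each ref position
    for i in range(L + 1):
        ins_len = max((len(d.get(i, "")) for d in inss), default=0)
        if ins_len:
            for k, d in enumerate(inss):
                chunk = d.get(i, "").ljust(ins_len, "-")
                rows[k + 1].append(chunk)
            rows[0].append("-" * ins_len)
        if i < L:
            ref_col_of.append(sum(len(c) for c in rows[0]))
            rows[0].append(ref[i])
            for k, sub in enumerate(subs):
                rows[k + 1].append(sub[i])
    aligned = ["".join(r) for r in rows]
    return aligned, ref_col_of


@dataclass
class Msa:
    """Alignment of the three genomes, anchored on the first."""

    genomes: list[MitoGenome]
    rows: list[str]  # aligned sequences, equal length, '-' gaps
    ref_col_of: list[int]  # alignment column of each reference position

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]


def align_genomes(genomes: list[MitoGenome], pre_aligned: bool = False) -> Msa:
    """Align three mitogenomes (or accept a pre-aligned FASTA trio)."""

    if len(genomes) != 3:
        raise ValueError("need exactly 3 genomes")
    seqs = [g.sequence for g in genomes]
    if pre_aligned:
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("pre-aligned sequences must have equal length")
        ref_col_of = [j for j, ch in enumerate(seqs[0]) if ch != "-"]
        return Msa(genomes=genomes, rows=seqs, ref_col_of=ref_col_of)
    lengths = [len(s) for s in seqs]
    for s in seqs[1:]:
        ratio = len(s) / lengths[0]
        if not 0.9 <= ratio <= 1.1:
            raise ValueError(
                f"sequence length ratio {ratio:.2f} outside [0.9, 1.1]: not homologous mitogenomes"
            )
    rows, ref_col_of = _merge_pairwise(seqs[0], seqs[1:])
    return Msa(genomes=genomes, rows=rows, ref_col_of=ref_col_of)


def call_variants(msa: Msa) -> pd.DataFrame:
    """SNP and indel calls from the alignment.

    A column with >= 2 distinct bases and no gap is one SNP site
    (multi-state columns still count as one site). A maximal run of gap
    columns in one row is a single indel event. Each SNP is assigned a
    partition: the haplotype it is unique to (one sequence differing
    from the two identical others) or 'all_distinct' for three-state
    columns.
    """

    ids = [g.id for g in msa.genomes]
    rows = []
    gap_open = [False, False, False]
    indel_events = 0
    for j in range(msa.n_cols):
        col = msa.column(j)
        gaps = [b == "-" for b in col]
        if any(gaps):
            for k in range(3):
                if gaps[k] and not gap_open[k]:
                    indel_events += 1
                gap_open[k] = gaps[k]
            continue
        gap_open = [False, False, False]
        states = set(col)
        if len(states) == 1:
            continue
        if len(states) == 3:
            partition = "all_distinct"
        else:
            counts = {b: col.count(b) for b in states}
            minority = min(counts, key=counts.get)
            partition = ids[col.index(minority)]
        rows.append(
            {
                "column": j,
                "ref_pos": _ref_pos_at(msa, j),
                **{f"allele_{ids[k]}": col[k] for k in range(3)},
                "partition": partition,
                "type": "snp",
            }
        )
    variants = pd.DataFrame(rows)
    variants.attrs["indel_events"] = indel_events
    return variants


def _ref_pos_at(msa: Msa, col: int) -> int:
    """Reference position of an alignment column (-1 inside ref gaps)."""

    i = int(np.searchsorted(msa.ref_col_of, col))
    if i < len(msa.ref_col_of) and msa.ref_col_of[i] == col:
        return i
    return -1


def _gene_at(genome: MitoGenome, pos: int) -> CdsFeature | None:
    for c in genome.cds:
        if c.start <= pos < c.end:
            return c
    return None


def classify_substitutions(variants: pd.DataFrame, msa: Msa) -> pd.DataFrame:
    """Synonymous/nonsynonymous classification of coding SNPs.

    Each SNP falling in an annotated CDS of the reference genome is
    classified in its codon context: for every pair of haplotypes that
    differ at the site, the two codons (read through the alignment, so
    other substitutions in the same codon are honored) are translated
    with the invertebrate mitochondrial code; the site is nonsynonymous
    if any differing pair encodes different amino acids. A substitution
    creating a premature stop is nonsynonymous and flagged.
    """

    ref = msa.genomes[0]
    out = []
    for rec in variants.itertuples(index=False):
        if rec.ref_pos < 0:
            continue
        feat = _gene_at(ref, rec.ref_pos)
        if feat is None:
            continue
        offset = rec.ref_pos - feat.start
        codon_index = offset // 3 if feat.strand == "+" else (feat.end - 1 - rec.ref_pos) // 3
        if feat.strand == "+":
            c0 = feat.start + 3 * codon_index
            codon_pos = [c0, c0 + 1, c0 + 2]
        else:
            c0 = feat.end - 3 * (codon_index + 1)
            codon_pos = [c0, c0 + 1, c0 + 2]
        cols = [msa.ref_col_of[p] for p in codon_pos]
        aas = []
        premature_stop = False
        for row in msa.rows:
            codon = "".join(row[c] for c in cols)
            if "-" in codon:
                aas.append(None)
                continue
            if feat.strand == "-":
                codon = str(Seq(codon).reverse_complement())
            aa = str(Seq(codon).translate(table=INVERTEBRATE_MITO_TABLE))
            if aa == "*" and codon_index < (feat.end - feat.start) // 3 - 1:
                premature_stop = True
            aas.append(aa)
        alleles = [getattr(rec, f"allele_{g.id}") for g in msa.genomes]
        nonsyn = False
        for a, b in itertools.combinations(range(3), 2):
            if alleles[a] != alleles[b] and aas[a] is not None and aas[b] is not None:
                if aas[a] != aas[b]:
                    nonsyn = True
        out.append(
            {
                "column": rec.column,
                "ref_pos": rec.ref_pos,
                "gene": feat.gene,
                "partition": rec.partition,
                "effect": "nonsynonymous" if nonsyn else "synonymous",
                "premature_stop": premature_stop,
            }
        )
    coding = pd.DataFrame(out)
    if not coding.empty and coding["premature_stop"].any():
        n = int(coding["premature_stop"].sum())
        warnings.warn(f"{n} substitution(s) create a premature stop codon")
    return coding


def pairwise_pi(msa: Msa, region: str = "whole") -> dict[tuple[str, str], float]:
    """Pairwise nucleotide diversity: differing / total aligned non-gap sites.

    ``region='pcg_only'`` restricts to alignment columns inside the
    reference genome's annotated protein-coding genes.
    """

    if region not in ("whole", "pcg_only"):
        raise ValueError(f"unknown region {region!r}")
    cols = range(msa.n_cols)
    if region == "pcg_only":
        ref = msa.genomes[0]
        keep = np.zeros(len(ref.sequence), dtype=bool)
        for c in ref.cds:
            keep[c.start : c.end] = True
        cols = [msa.ref_col_of[p] for p in np.flatnonzero(keep)]
        if not cols:
            raise ValueError("empty region: no annotated protein-coding genes")
    ids = [g.id for g in msa.genomes]
    out = {}
    for a, b in itertools.combinations(range(3), 2):
        ra, rb = msa.rows[a], msa.rows[b]
        diff = total = 0
        for j in cols:
            if ra[j] == "-" or rb[j] == "-":
                continue
            total += 1
            diff += ra[j] != rb[j]
        if total == 0:
            raise ValueError("empty region: no aligned non-gap sites")
        out[(ids[a], ids[b])] = diff / total
    return out


@dataclass
class DivergenceSummary:
    """Headline divergence numbers for the three mitogenomes."""

    snp_total: int
    indel_total: int
    snp_pcg: int
    synonymous: int
    nonsynonymous: int
    per_gene: pd.DataFrame  # gene, synonymous, nonsynonymous
    partition_counts: dict[str, int]
    pairwise_pi: dict[tuple[str, str], float]


def summarize_divergence(
    genomes: list[MitoGenome], pre_aligned: bool = False, pi_region: str = "whole"
) -> DivergenceSummary:
    """Align, call, classify, and summarize in one step."""

    msa = align_genomes(genomes, pre_aligned=pre_aligned)
    variants = call_variants(msa)
    coding = classify_substitutions(variants, msa)
    if coding.empty:
        per_gene = pd.DataFrame(columns=["gene", "synonymous", "nonsynonymous"])
        syn = nonsyn = 0
    else:
        per_gene = (
            coding.groupby("gene")["effect"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["synonymous", "nonsynonymous"], fill_value=0)
            .reset_index()
        )
        syn = int((coding["effect"] == "synonymous").sum())
        nonsyn = int((coding["effect"] == "nonsynonymous").sum())
    partition = (
        variants["partition"].value_counts().to_dict() if not variants.empty else {}
    )
    return DivergenceSummary(
        snp_total=len(variants),
        indel_total=int(variants.attrs.get("indel_events", 0)),
        snp_pcg=len(coding),
        synonymous=syn,
        nonsynonymous=nonsyn,
        per_gene=per_gene,
        partition_counts=partition,
        pairwise_pi=pairwise_pi(msa, region=pi_region),
    )
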