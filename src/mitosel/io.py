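"""Readers and writers for the pipeline's tab-separated tables and config.

All tables are UTF-8, tab-delimited, with a header row. Schemas:

- design:     line_id, nuclear, thermal, eve, tech, generations
- counts:     sample_id, gene, haplotype, reads [, is_control]
- phenotypes: line_id, line_type, nuclear, sex, generation, fertile_eggs
              [, adjusted_eggs]
- frequencies: line_id, BRA, CAL, YEM

Config files are plain ``key = value`` text; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from Bio import SeqIO

from .constants import HAPLOTYPES
from .divergence import CdsFeature, MitoGenome

__all__ = [
    "read_design",
    "read_counts",
    "read_phenotypes",
    "read_frequencies",
    "write_tsv",
    "read_genomes",
    "PipelineConfig",
    "read_config",
]


def _read_tsv(path, required: set[str], name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ValueError(f"could not parse {name} table {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} table {path} is missing column(s): {sorted(missing)}")
    return df


def read_design(path) -> pd.DataFrame:
    df = _read_tsv(path, {"line_id", "nuclear", "thermal", "eve", "tech", "generations"}, "design")
    if df["line_id"].duplicated().any():
        dupes = df.loc[df["line_id"].duplicated(), "line_id"].tolist()
        raise ValueError(f"duplicate line_id(s) in design table: {dupes}")
    return df


def read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path, {"sample_id", "gene", "haplotype", "reads"}, "read-count")
    bad = set(df["haplotype"]) - set(HAPLOTYPES)
    if bad:
        raise ValueError(f"unknown haplotype(s) in count table: {sorted(bad)}")
    if "is_control" not in df.columns:
        df["is_control"] = False
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(
        path, {"line_id", "line_type", "nuclear", "sex", "generation", "fertile_eggs"}, "phenotype"
    )
    if "adjusted_eggs" not in df.columns:
        df["adjusted_eggs"] = df["fertile_eggs"].where(
            df["sex"] != "female", df["fertile_eggs"] / 2.0
        )
    return df


def read_frequencies(path) -> pd.DataFrame:
    df = _read_tsv(path, {"line_id", *HAPLOTYPES}, "frequency")
    return df.set_index("line_id")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _parse_annotation(path) -> dict[str, list[CdsFeature]]:
    """CDS annotations from GFF3 or a 4/5-column TSV (1-based closed coords)."""

    path = Path(path)
    per_seq: dict[str, list[CdsFeature]] = {}
    if path.suffix.lower() in (".gff", ".gff3"):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2].upper() != "CDS":
                    continue
                seqid, _, _, start, end, _, strand, _, attrs = parts[:9]
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                gene = attr.get("gene") or attr.get("Name") or attr.get("ID") or "unknown"
                per_seq.setdefault(seqid, []).append(
                    CdsFeature(gene=gene, start=int(start) - 1, end=int(end), strand=strand)
                )
    else:
        df = _read_tsv(path, {"gene", "start", "end", "strand"}, "annotation")
        seq_col = "seqid" if "seqid" in df.columns else None
        for rec in df.itertuples(index=False):
            seqid = getattr(rec, "seqid") if seq_col else "*"
            per_seq.setdefault(seqid, []).append(
                CdsFeature(
                    gene=rec.gene, start=int(rec.start) - 1, end=int(rec.end), strand=rec.strand
                )
            )
    return per_seq


def read_genomes(fasta_path, annot_path=None) -> list[MitoGenome]:
    """Mitogenomes from FASTA plus optional GFF3/TSV CDS annotations."""

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    annot = _parse_annotation(annot_path) if annot_path else {}
    genomes = []
    for rec in records:
        cds = annot.get(rec.id, annot.get("*", []))
        genomes.append(MitoGenome(id=rec.id, sequence=str(rec.seq), cds=list(cds)))
    return genomes


@dataclass
class PipelineConfig:
    """Paths and knobs of the full pipeline run."""

    design: str | None = None
    counts: str | None = None
    phenotypes: str | None = None
    genomes_fasta: str | None = None
    genomes_annot: str | None = None
    out_dir: str = "mitosel_out"
    alpha: float = 0.05
    n_perm: int = 9_999
    n_boot: int = 9_999
    seed: int = 1
    deterministic_mode: bool = False
    eq1_mode: str = "per_generation"
    pi_region: str = "whole"
    genomes_pre_aligned: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99 or self.n_boot < 100 or self.seed < 0:
            raise ValueError("n_perm, n_boot must be positive (and not tiny); seed non-negative")
        if self.eq1_mode not in ("per_generation", "one_step"):
            raise ValueError(f"unknown eq1_mode {self.eq1_mode!r}")
        if self.pi_region not in ("whole", "pcg_only"):
            raise ValueError(f"unknown pi_region {self.pi_region!r}")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_config(path) -> PipelineConfig:
    """Parse a plain ``key = value`` config file; unknown keys are rejected."""

    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = value
    typed = {}
    for key, value in kwargs.items():
        default = getattr(PipelineConfig(), key)
        if isinstance(default, bool):
            if value.lower() not in _BOOL:
                raise ValueError(f"config key {key!r}: expected boolean, got {value!r}")
            typed[key] = _BOOL[value.lower()]
        elif isinstance(default, int):
            typed[key] = int(value)
        elif isinstance(default, float):
            typed[key] = float(value)
        else:
            typed[key] = value
    return PipelineConfig(**typed)
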