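"""Haplotype-frequency estimation from pool-seq read counts.

Control samples with exactly known composition (1/3 each) are used to
screen the 13 protein-coding genes for mapping/procedural bias with
per-gene goodness-of-fit chi-square tests, FDR-adjusted within each
control sample. Frequencies in experimental samples are then the
unweighted mean of per-gene read proportions over the retained genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import HAPLOTYPES

__all__ = [
    "BiasTestResult",
    "FrequencyEstimates",
    "test_gene_bias",
    "estimate_frequencies",
    "gene_consistency",
]


def _count_matrix(counts: pd.DataFrame, sample: str, gene: str) -> np.ndarray:
    sub = counts[(counts["sample_id"] == sample) & (counts["gene"] == gene)]
    obs = sub.set_index("haplotype")["reads"].reindex(HAPLOTYPES).fillna(0)
    return obs.to_numpy(dtype=float)


def _validate_counts(counts: pd.DataFrame) -> None:
    required = {"sample_id", "gene", "haplotype", "reads"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"read-count table is missing columns: {sorted(missing)}")
    if (counts["reads"] < 0).any():
        raise ValueError("read counts must be non-negative")
    if counts.duplicated(["sample_id", "gene", "haplotype"]).any():
        raise ValueError("duplicate (sample, gene, haplotype) entries in read-count table")


@dataclass
class BiasTestResult:
    """Outcome of the control-sample gene-bias screen."""

    table: pd.DataFrame  # columns: gene, sample_id, chi2, df, p, q
    retained: list[str]
    flagged: list[str]
    excluded: list[str] = field(default_factory=list)  # zero-read genes
    alpha: float = 0.05


def test_gene_bias(
    controls: pd.DataFrame,
    expected=(1 / 3, 1 / 3, 1 / 3),
    alpha: float = 0.05,
) -> BiasTestResult:
    """Chi-square goodness-of-fit bias screen on control samples.

    For each gene in each control sample the observed haplotype read
    counts are tested against the expected proportions (df = 2);
    p-values are Benjamini-Hochberg adjusted across genes within each
    control sample. A gene is retained only if its adjusted Q exceeds
    ``alpha`` in every control sample — i.e. a gene significant in any
    control sample is flagged as biased and dropped.
    """

    _validate_counts(controls)
    expected = np.asarray(expected, dtype=float)
    if abs(expected.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    samples = sorted(controls["sample_id"].unique())
    if not samples:
        raise ValueError("need at least one control sample")
    genes = sorted(controls["gene"].unique())

    rows = []
    excluded: set[str] = set()
    for sample in samples:
        tested = []
        for gene in genes:
            obs = _count_matrix(controls, sample, gene)
            total = obs.sum()
            if total == 0:
                excluded.add(gene)
                continue
            chi2, p = stats.chisquare(obs, f_exp=total * expected)
            tested.append({"gene": gene, "sample_id": sample, "chi2": chi2, "df": 2, "p": p})
        if not tested:
            continue
        pvals = np.array([r["p"] for r in tested])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(tested, qvals):
            r["q"] = q
        rows.extend(tested)

    table = pd.DataFrame(rows)
    if excluded:
        warnings.warn(
            f"genes with zero control reads excluded from the screen: {sorted(excluded)}"
        )
    retained, flagged = [], []
    for gene in genes:
        if gene in excluded:
            continue
        qs = table.loc[table["gene"] == gene, "q"]
        (retained if (qs > alpha).all() else flagged).append(gene)
    return BiasTestResult(
        table=table,
        retained=retained,
        flagged=flagged,
        excluded=sorted(excluded),
        alpha=alpha,
    )


@dataclass
class FrequencyEstimates:
    """Per-sample haplotype frequencies and their per-gene components."""

    freq: pd.DataFrame  # index sample_id, columns BRA, CAL, YEM
    per_gene: pd.DataFrame  # columns sample_id, gene, BRA, CAL, YEM
    genes_used: list[str]
    consistency_r: float | None = None


def estimate_frequencies(samples: pd.DataFrame, genes_used: list[str]) -> FrequencyEstimates:
    """Mean of per-gene read proportions over the retained genes.

    Per gene, the proportion of reads mapping to each haplotype; per
    sample, the unweighted arithmetic mean of those per-gene proportion
    vectors (renormalized against floating-point drift). Genes with no
    reads in a particular sample are dropped for that sample with a
    warning; a sample with no reads in any retained gene is an error.
    """

    _validate_counts(samples)
    if not genes_used:
        raise ValueError("genes_used must be non-empty")
    sub = samples[samples["gene"].isin(genes_used)]
    missing = set(genes_used) - set(sub["gene"])
    if missing:
        raise ValueError(f"genes_used not present in table: {sorted(missing)}")

    wide = (
        sub.pivot_table(
            index=["sample_id", "gene"],
            columns="haplotype",
            values="reads",
            aggfunc="sum",
            fill_value=0,
        )
        .reindex(columns=HAPLOTYPES, fill_value=0)
        .astype(float)
    )
    totals = wide.sum(axis=1)
    zero = totals == 0
    if zero.any():
        dropped = wide.index[zero].tolist()
        warnings.warn(f"gene(s) with zero reads dropped per sample: {dropped}")
        wide = wide[~zero]
        totals = totals[~zero]
    props = wide.div(totals, axis=0)

    per_gene = props.reset_index()
    freq = props.groupby(level="sample_id").mean()
    empty = set(sub["sample_id"].unique()) - set(freq.index)
    if empty:
        raise ValueError(f"sample(s) with zero reads across all retained genes: {sorted(empty)}")
    freq = freq.div(freq.sum(axis=1), axis=0)
    return FrequencyEstimates(freq=freq, per_gene=per_gene, genes_used=list(genes_used))


def gene_consistency(estimates: FrequencyEstimates) -> float:
    """Mean pairwise Pearson correlation of per-gene estimates across samples.

    For each haplotype and each pair of genes, the per-gene frequency
    estimates are correlated across samples; the mean over gene pairs
    and haplotypes is returned as a diagnostic of how consistently the
    genes measure the same underlying composition. Pairs involving a
    constant column are undefined and are excluded with a warning.
    """

    per_gene = estimates.per_gene
    genes = sorted(per_gene["gene"].unique())
    samples = sorted(per_gene["sample_id"].unique())
    if len(samples) < 3 or len(genes) < 2:
        raise ValueError("need >=3 samples and >=2 genes for a consistency estimate")

    mats = {
        g: per_gene[per_gene["gene"] == g]
        .set_index("sample_id")[list(HAPLOTYPES)]
        .reindex(samples)
        for g in genes
    }
    rs = []
    n_skipped = 0
    for g1, g2 in itertools.combinations(genes, 2):
        for hap in HAPLOTYPES:
            x = mats[g1][hap].to_numpy()
            y = mats[g2][hap].to_numpy()
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                n_skipped += 1
                continue
            rs.append(stats.pearsonr(x, y)[0])
    if n_skipped:
        warnings.warn(f"{n_skipped} gene-pair/haplotype correlations undefined and skipped")
    if not rs:
        raise ValueError("no defined gene-pair correlations")
    return float(np.mean(rs))
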