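"""End-to-end driver: frequencies -> fitness -> ANOVA -> PLS (-> divergence)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import fitness_pca, per_haplotype_anova, permutation_test, rm_anova
from .constants import HAPLOTYPES
from .divergence import summarize_divergence
from .fitness import fitness_table, test_selection
from .io import (
    PipelineConfig,
    read_counts,
    read_design,
    read_genomes,
    read_phenotypes,
    write_tsv,
)
from .pls import bootstrap_pls, compute_delta_w, pls_first_dimension
from .poolseq import estimate_frequencies, gene_consistency, test_gene_bias

__all__ = ["run_pipeline", "selftest"]


def _cross_reference(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    samples = set(counts.loc[~counts["is_control"], "sample_id"])
    lines = set(design["line_id"])
    orphans = sorted(samples - lines)
    if orphans:
        rows = counts.index[counts["sample_id"].isin(orphans)].tolist()[:5]
        raise ValueError(
            f"sample(s) in counts but not in design: {orphans} (first rows: {rows})"
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the configured inputs allow; write report + TSVs.

    Returns the report dict (also written as ``report.json`` in
    ``config.out_dir``).
    """

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "eq1_mode": config.eq1_mode,
    }

    if not (config.design and config.counts):
        raise ValueError("pipeline requires at least design and counts tables")
    design = read_design(config.design)
    counts = read_counts(config.counts)
    _cross_reference(counts, design)

    controls = counts[counts["is_control"]]
    if controls.empty:
        raise ValueError("no control samples (is_control column) in the count table")
    bias = test_gene_bias(controls, alpha=config.alpha)
    write_tsv(bias.table, out / "gene_bias_tests.tsv")
    report["gene_filter"] = {
        "retained": bias.retained,
        "flagged": bias.flagged,
        "excluded": bias.excluded,
    }

    experimental = counts[~counts["is_control"]]
    est = estimate_frequencies(experimental, bias.retained)
    est.consistency_r = gene_consistency(est)
    freq = est.freq.rename_axis("line_id")
    write_tsv(freq.reset_index(), out / "haplotype_frequencies.tsv")
    report["frequencies"] = {
        "n_samples": int(len(freq)),
        "genes_used": est.genes_used,
        "gene_consistency_r": est.consistency_r,
    }

    fit = fitness_table(freq, design, mode=config.eq1_mode)
    write_tsv(fit, out / "fitness.tsv")
    sel = test_selection(fit, n_boot=config.n_boot, seed=config.seed)
    report["selection"] = {
        "mean_W": sel.summary["mean_W"].to_dict(),
        "ci": {
            h: [sel.summary.loc[h, "ci_low"], sel.summary.loc[h, "ci_high"]]
            for h in HAPLOTYPES
        },
        "t_vs_1": sel.summary["t"].to_dict(),
        "p_vs_1": sel.summary["p"].to_dict(),
        "tukey": sel.tukey.to_dict("records"),
        "overall_F": sel.overall_F,
        "overall_df": list(sel.overall_df),
        "overall_p": sel.overall_p,
    }

    W = fit.pivot(index="line_id", columns="haplotype", values="W")[list(HAPLOTYPES)]
    pcs = fitness_pca(W)
    rm = rm_anova(pcs, design)
    perm = permutation_test(pcs, design, n_perm=config.n_perm, seed=config.seed)
    between = rm.between.merge(perm[["source", "p_rand"]], on="source", how="left")
    write_tsv(between, out / "anova_between.tsv")
    write_tsv(rm.within, out / "anova_within.tsv")
    report["anova"] = {
        "eigenvalues": pcs.eigenvalues.tolist(),
        "variance_explained_pc12": float(pcs.variance_explained.sum()),
        "between": between.to_dict("records"),
    }
    per_hap = per_haplotype_anova(W, design)
    for hap, table in per_hap.items():
        write_tsv(table, out / f"anova_{hap}.tsv")
    report["per_haplotype_anova"] = {
        hap: table.to_dict("records") for hap, table in per_hap.items()
    }

    if config.phenotypes:
        phen = read_phenotypes(config.phenotypes)
        dw = compute_delta_w(phen)
        lines = [l for l in dw.index if l in W.index]
        if len(lines) >= 4:
            df_table = fit.pivot(index="line_id", columns="haplotype", values="delta_f")
            X = df_table.loc[lines, list(HAPLOTYPES)].rename(
                columns={h: f"delta_f_{h}" for h in HAPLOTYPES}
            )
            Y = dw.loc[lines, ["delta_w_male", "delta_w_female"]]
            pls = pls_first_dimension(X, Y)
            boot = bootstrap_pls(X, Y, n_boot=config.n_boot, seed=config.seed)
            write_tsv(boot.table, out / "pls_loadings.tsv")
            report["pls"] = {
                "n_lines": len(lines),
                "covariance_explained": pls.covariance_explained,
                "covariance_explained_ci": list(boot.covariance_explained_ci),
                "loadings": boot.table.to_dict("records"),
                "n_dropped": boot.n_dropped,
            }
        else:
            report["pls"] = {"skipped": f"only {len(lines)} lines with complete data"}

    if config.genomes_fasta:
        genomes = read_genomes(config.genomes_fasta, config.genomes_annot)
        summary = summarize_divergence(
            genomes, pre_aligned=config.genomes_pre_aligned, pi_region=config.pi_region
        )
        report["divergence"] = {
            "snp_total": summary.snp_total,
            "indel_total": summary.indel_total,
            "snp_pcg": summary.snp_pcg,
            "synonymous": summary.synonymous,
            "nonsynonymous": summary.nonsynonymous,
            "partition_counts": summary.partition_counts,
            "pairwise_pi": {f"{a}/{b}": v for (a, b), v in summary.pairwise_pi.items()},
        }
        write_tsv(summary.per_gene, out / "divergence_per_gene.tsv")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def selftest(out_dir: str = "mitosel_selftest", seed: int = 1) -> dict:
    """Simulate a full experiment, write its tables, and analyze them.

    A smoke test of the whole chain: every invariant violation in any
    stage raises, and the resulting report is returned.
    """

    from .io import write_tsv as _w
    from .simulate import simulate_experiment, synthetic_mitogenomes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_experiment(seed=seed)
    _w(bundle.design, out / "design.tsv")
    _w(bundle.counts, out / "counts.tsv")
    _w(bundle.phenotypes, out / "phenotypes.tsv")
    genomes, _ = synthetic_mitogenomes(seed=seed)
    with open(out / "genomes.fasta", "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n{g.sequence}\n")
    annot = pd.DataFrame(
        [
            {"gene": c.gene, "start": c.start + 1, "end": c.end, "strand": c.strand}
            for c in genomes[0].cds
        ]
    )
    _w(annot, out / "annotation.tsv")
    config = PipelineConfig(
        design=str(out / "design.tsv"),
        counts=str(out / "counts.tsv"),
        phenotypes=str(out / "phenotypes.tsv"),
        genomes_fasta=str(out / "genomes.fasta"),
        genomes_annot=str(out / "annotation.tsv"),
        out_dir=str(out / "results"),
        n_perm=999,
        n_boot=999,
        seed=seed,
    )
    report = run_pipeline(config)
    comp = np.array([bundle.true_compositions[l] for l in bundle.design["line_id"]])
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)
    return report
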