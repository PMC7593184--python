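"""Relative fitness and per-generation frequency change from end-point data.

Under constant haplotype fitness the selection recursion

    p_i(t+1) = p_i(t) W_i / sum_j p_j(t) W_j

iterated for t generations has the closed form
``p_i(t) = p_i(0) W_i^t / sum_j p_j(0) W_j^t``, so the per-generation
relative fitness implied by an observed start/end frequency pair is

    W_i  propto  (p_i(t) / p_i(0))^(1/t),

normalized here so that initial mean fitness ``sum_i p_i(0) W_i`` is 1.
The average per-generation frequency change is simply
``delta_f_i = (p_i(t) - p_i(0)) / t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._bootstrap import bc_percentile_ci
from .constants import HAPLOTYPES

__all__ = [
    "relative_fitness",
    "delta_f",
    "forward_iterate",
    "fitness_table",
    "test_selection",
    "SelectionTestReport",
]


def _as_comp(x, name) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError(f"{name} must have 3 components")
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a frequency vector summing to 1, got {x}")
    return x


def forward_iterate(f_start, w, t: int) -> np.ndarray:
    """Iterate the selection recursion t generations (no drift)."""

    p = _as_comp(f_start, "f_start")
    w = np.asarray(w, dtype=float)
    for _ in range(t):
        p = p * w
        p = p / p.sum()
    return p


def relative_fitness(f_end, f_start, t: int, mode: str = "per_generation") -> np.ndarray:
    """Per-haplotype relative fitness W from end-point frequencies.

    ``mode='per_generation'`` (default) solves the t-fold iterated
    recursion: W_i proportional to (f_end_i/f_start_i)^(1/t),
    normalized so initial mean fitness is 1. ``mode='one_step'``
    treats the whole experiment as a single generation (ignores t
    beyond the caller's bookkeeping), provided for sensitivity
    analysis.

    A haplotype observed at frequency 0 at the end point gets W = 0
    with a warning (haplotype lost — a real outcome of drift).
    """

    f_end = _as_comp(f_end, "f_end")
    f_start = _as_comp(f_start, "f_start")
    if np.any(f_start <= 0):
        raise ValueError("f_start components must be strictly positive")
    if t < 1:
        raise ValueError("t must be >= 1")
    if mode not in ("per_generation", "one_step"):
        raise ValueError(f"unknown mode {mode!r}")

    ratio = f_end / f_start
    if np.any(f_end == 0):
        lost = [HAPLOTYPES[i] for i in np.flatnonzero(f_end == 0)]
        warnings.warn(f"haplotype(s) lost (end frequency 0): {lost}; returning W = 0")
    if mode == "per_generation":
        r = ratio ** (1.0 / t)
    else:
        r = ratio
    return r / float(f_start @ r)


def delta_f(f_end, f_start, t: int) -> np.ndarray:
    """Average per-generation frequency change (f_end - f_start) / t."""

    f_end = _as_comp(f_end, "f_end")
    f_start = _as_comp(f_start, "f_start")
    if t < 1:
        raise ValueError("t must be >= 1")
    return (f_end - f_start) / t


def fitness_table(
    freqs: pd.DataFrame,
    design: pd.DataFrame,
    f_start=(1 / 3, 1 / 3, 1 / 3),
    mode: str = "per_generation",
) -> pd.DataFrame:
    """Per-line W and delta_f from a frequency table and a design table.

    ``freqs`` is indexed by line_id with columns BRA, CAL, YEM;
    ``design`` supplies generations elapsed per line. Returns a long
    table (line_id, haplotype, W, delta_f, t).
    """

    gens = design.set_index("line_id")["generations"]
    missing = set(freqs.index) - set(gens.index)
    if missing:
        raise ValueError(f"lines missing from design table: {sorted(missing)}")
    f0 = np.asarray(f_start, dtype=float)
    rows = []
    for line_id, row in freqs.iterrows():
        t = int(gens[line_id])
        f_end = row[list(HAPLOTYPES)].to_numpy(dtype=float)
        w = relative_fitness(f_end, f0, t, mode=mode)
        df_ = delta_f(f_end, f0, t)
        for h, hap in enumerate(HAPLOTYPES):
            rows.append(
                {"line_id": line_id, "haplotype": hap, "W": w[h], "delta_f": df_[h], "t": t}
            )
    return pd.DataFrame(rows)


@dataclass
class SelectionTestReport:
    """Replicate-line tests for selection on haplotypes."""

    summary: pd.DataFrame  # per haplotype: mean_W, ci_low, ci_high, t, p
    tukey: pd.DataFrame  # pairwise haplotype comparisons
    overall_F: float  # line-blocked one-way F across haplotypes
    overall_df: tuple[int, int]
    overall_p: float
    n_boot: int


def test_selection(
    fitness: pd.DataFrame, n_boot: int = 9_999, seed: int | None = None
) -> SelectionTestReport:
    """Does mean relative fitness differ among haplotypes and from 1?

    Lines are the unit of replication. Per haplotype: the mean W over
    lines with a bias-corrected percentile bootstrap CI (lines
    resampled with replacement) and a one-sample t-test of H0: W = 1.
    Pairwise haplotype contrasts use Tukey's HSD. The overall test is a
    one-way ANOVA of haplotype with line as a block (the within-line
    comparison the replicated design supports).
    """

    wide = fitness.pivot(index="line_id", columns="haplotype", values="W")[list(HAPLOTYPES)]
    n = len(wide)
    if n < 3:
        raise ValueError("need at least 3 lines")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small; CIs will be unstable")
    rng = np.random.default_rng(seed)
    W = wide.to_numpy()

    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = W[idx].mean(axis=1)  # (n_boot, 3)
    rows = []
    for h, hap in enumerate(HAPLOTYPES):
        mean_w = float(W[:, h].mean())
        lo, hi = bc_percentile_ci(mean_w, boot_means[:, h])
        sd = W[:, h].std(ddof=1)
        if sd == 0:
            tstat, p = (0.0, 1.0) if mean_w == 1.0 else (np.inf, 0.0)
        else:
            tstat, p = stats.ttest_1samp(W[:, h], 1.0)
        rows.append(
            {
                "haplotype": hap,
                "mean_W": mean_w,
                "ci_low": lo,
                "ci_high": hi,
                "t": float(tstat),
                "p": float(p),
            }
        )
    summary = pd.DataFrame(rows).set_index("haplotype")

    centered = W - W.mean(axis=1, keepdims=True)
    ss_hap = n * np.sum((centered.mean(axis=0)) ** 2)
    ss_resid = np.sum((centered - centered.mean(axis=0)) ** 2)
    df_hap, df_resid = 2, 2 * (n - 1)
    if ss_resid <= 1e-30:
        overall_F, overall_p = (0.0, 1.0) if ss_hap <= 1e-30 else (np.inf, 0.0)
    else:
        overall_F = (ss_hap / df_hap) / (ss_resid / df_resid)
        overall_p = float(stats.f.sf(overall_F, df_hap, df_resid))

    if np.allclose(W.std(axis=0, ddof=1), 0) and np.allclose(W, W[0]):
        tukey_rows = [
            {"pair": f"{a} vs {b}", "statistic": 0.0, "p": 1.0}
            for i, a in enumerate(HAPLOTYPES)
            for b in HAPLOTYPES[i + 1 :]
        ]
    else:
        res = stats.tukey_hsd(W[:, 0], W[:, 1], W[:, 2])
        tukey_rows = [
            {
                "pair": f"{HAPLOTYPES[i]} vs {HAPLOTYPES[j]}",
                "statistic": float(res.statistic[i, j]),
                "p": float(res.pvalue[i, j]),
            }
            for i in range(3)
            for j in range(i + 1, 3)
        ]
    tukey = pd.DataFrame(tukey_rows)
    return SelectionTestReport(
        summary=summary,
        tukey=tukey,
        overall_F=float(overall_F),
        overall_df=(df_hap, df_resid),
        overall_p=overall_p,
        n_boot=n_boot,
    )
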