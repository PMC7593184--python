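"""Linking haplotype-frequency change to reproductive-fitness change.

Sex-specific change in relative lifetime reproductive success,
``delta_W = W33 - W3`` with W measured relative to the fittest control
genotype (the CAL pure line), is related to the per-generation
haplotype frequency changes ``delta_f`` by partial least squares:
the first pair of latent variables maximizes the covariance between
the (standardized) delta_f block and delta_W block. Inference on the
loadings uses a line-resampling bootstrap with axis-reversal (sign)
correction and bias-corrected percentile confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._bootstrap import bc_percentile_ci

__all__ = [
    "compute_delta_w",
    "pls_first_dimension",
    "bootstrap_pls",
    "PLSResult",
    "PLSBootstrap",
]


def compute_delta_w(
    phenotypes: pd.DataFrame,
    reference_nuclear: str = "California",
) -> pd.DataFrame:
    """Per mix line and sex: relative fitness at both generations and its change.

    ``W_g(line, sex)`` is the line's mean adjusted egg count at
    generation g divided by the reference pure line's mean at the same
    sex and generation (pure lines of ``reference_nuclear`` background,
    replicates averaged); ``delta_w = W33 - W3``. Female assays must
    already carry halved counts in ``adjusted_eggs``. Lines missing any
    sex x generation cell are excluded with a warning.
    """

    required = {"line_id", "line_type", "sex", "generation", "adjusted_eggs"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table is missing columns: {sorted(missing)}")
    gens = sorted(phenotypes["generation"].unique())
    if len(gens) != 2:
        raise ValueError(f"need exactly 2 assay generations, got {gens}")
    g_early, g_late = gens

    ref = phenotypes[
        (phenotypes["line_type"] == "pure")
        & (phenotypes["nuclear"] == reference_nuclear)
    ]
    if ref.empty:
        raise ValueError(f"no pure reference line with nuclear background {reference_nuclear!r}")
    ref_means = ref.groupby(["sex", "generation"])["adjusted_eggs"].mean()
    if (ref_means <= 0).any() or len(ref_means) < 4:
        raise ValueError("reference line must have positive mean counts in all 4 sex x generation cells")

    mix = phenotypes[phenotypes["line_type"] == "mix"]
    cell_means = mix.groupby(["line_id", "sex", "generation"])["adjusted_eggs"].mean()
    rows = []
    for line_id in sorted(mix["line_id"].unique()):
        rec = {"line_id": line_id}
        ok = True
        for sex in ("female", "male"):
            try:
                w3 = cell_means[(line_id, sex, g_early)] / ref_means[(sex, g_early)]
                w33 = cell_means[(line_id, sex, g_late)] / ref_means[(sex, g_late)]
            except KeyError:
                ok = False
                break
            rec[f"w3_{sex}"] = w3
            rec[f"w33_{sex}"] = w33
            rec[f"delta_w_{sex}"] = w33 - w3
        if ok:
            rows.append(rec)
        else:
            warnings.warn(f"line {line_id!r} missing a sex x generation cell; excluded")
    if not rows:
        raise ValueError("no mix line has complete assay coverage")
    return pd.DataFrame(rows).set_index("line_id")


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (M - M.mean(axis=0)) / sd


def _first_dimension_core(Xv: np.ndarray, Yv: np.ndarray):
    """(u, v, cov_explained) of the first PLS-SVD dimension, or None if degenerate."""

    sx = Xv.std(axis=0, ddof=1)
    sy = Yv.std(axis=0, ddof=1)
    if np.any(sx == 0) or np.any(sy == 0):
        return None
    Xs = (Xv - Xv.mean(axis=0)) / sx
    Ys = (Yv - Yv.mean(axis=0)) / sy
    C = Xs.T @ Ys / (len(Xv) - 1)
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    total = float(np.sum(S**2))
    if total <= 1e-300:
        return None
    return U[:, 0], Vt[0], float(S[0] ** 2 / total)


@dataclass
class PLSResult:
    """First PLS dimension of the standardized delta_f / delta_W blocks."""

    x_loadings: pd.Series  # per delta_f column (unit-norm weight vector)
    y_loadings: pd.Series  # per delta_W column
    covariance_explained: float  # first squared singular value / total
    singular_values: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    degenerate: bool = False


def pls_first_dimension(X: pd.DataFrame, Y: pd.DataFrame) -> PLSResult:
    """First pair of latent variables maximizing block covariance.

    Both blocks are mean-centered and scaled to unit variance; the
    loadings are the first left/right singular vectors of the
    cross-covariance matrix X'Y/(n-1), equivalent to the first
    dimension of PLS-SVD. ``covariance_explained`` is the first squared
    singular value over the sum of all squared singular values. The
    joint sign is fixed so the largest-magnitude X loading is positive.
    """

    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of lines")
    if len(X) < 4:
        raise ValueError("need at least 4 lines")
    Xs = _standardize(X.to_numpy(dtype=float))
    Ys = _standardize(Y.to_numpy(dtype=float))
    C = Xs.T @ Ys / (len(X) - 1)
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    total = float(np.sum(S**2))
    if total <= 1e-300:
        warnings.warn("rank-0 cross-covariance: no covariation between blocks")
        return PLSResult(
            x_loadings=pd.Series(np.zeros(X.shape[1]), index=X.columns),
            y_loadings=pd.Series(np.zeros(Y.shape[1]), index=Y.columns),
            covariance_explained=0.0,
            singular_values=S,
            x_scores=np.zeros(len(X)),
            y_scores=np.zeros(len(X)),
            degenerate=True,
        )
    u, v = U[:, 0], Vt[0]
    if u[np.argmax(np.abs(u))] < 0:
        u, v = -u, -v
    return PLSResult(
        x_loadings=pd.Series(u, index=X.columns),
        y_loadings=pd.Series(v, index=Y.columns),
        covariance_explained=float(S[0] ** 2 / total),
        singular_values=S,
        x_scores=Xs @ u,
        y_scores=Ys @ v,
    )


@dataclass
class PLSBootstrap:
    """Bootstrap inference for the first-dimension loadings."""

    table: pd.DataFrame  # block, variable, loading, se, t, p, ci_low, ci_high
    n_boot: int
    n_dropped: int
    covariance_explained_ci: tuple[float, float]


def bootstrap_pls(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PLSBootstrap:
    """Line-resampling bootstrap of the first PLS dimension.

    Lines are resampled with replacement and the first dimension is
    re-estimated per replicate. Axis-reversal correction: a replicate's
    loadings (both blocks jointly) are sign-flipped when their dot
    product with the point-estimate loading vector is negative. The
    loading SE is the bootstrap standard deviation, t = estimate/SE
    with p from a t distribution on n_lines - 1 df, and the CI is the
    bias-corrected percentile interval. Replicates with a degenerate
    resample (constant column or rank-0 cross-covariance) are dropped
    and counted.
    """

    if n_boot < 1000:
        warnings.warn(f"n_boot={n_boot} below the recommended 1000")
    point = pls_first_dimension(X, Y)
    ref = np.concatenate([point.x_loadings.to_numpy(), point.y_loadings.to_numpy()])
    n = len(X)
    rng = np.random.default_rng(seed)
    Xv, Yv = X.to_numpy(dtype=float), Y.to_numpy(dtype=float)

    boot_loadings = []
    boot_cov = []
    n_dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        core = _first_dimension_core(Xv[idx], Yv[idx])
        if core is None:
            n_dropped += 1
            continue
        u, v, cov_expl = core
        vec = np.concatenate([u, v])
        if vec @ ref < 0:
            vec = -vec
        boot_loadings.append(vec)
        boot_cov.append(cov_expl)
    if n_dropped > 0.1 * n_boot:
        warnings.warn(f"{n_dropped}/{n_boot} bootstrap replicates degenerate and dropped")
    B = np.asarray(boot_loadings)
    if B.size == 0:
        raise ValueError("all bootstrap replicates degenerate")

    names = [("X", c) for c in X.columns] + [("Y", c) for c in Y.columns]
    rows = []
    df_t = n - 1
    for j, (block, var) in enumerate(names):
        est = ref[j]
        se = float(B[:, j].std(ddof=1))
        if se == 0:
            tstat, p = (np.inf if est != 0 else 0.0), (0.0 if est != 0 else 1.0)
        else:
            tstat = est / se
            p = float(2 * stats.t.sf(abs(tstat), df_t))
        lo, hi = bc_percentile_ci(est, B[:, j], alpha=alpha)
        rows.append(
            {
                "block": block,
                "variable": var,
                "loading": est,
                "se": se,
                "t": float(tstat),
                "p": p,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    cov_ci = bc_percentile_ci(point.covariance_explained, np.asarray(boot_cov), alpha=alpha)
    return PLSBootstrap(
        table=pd.DataFrame(rows),
        n_boot=n_boot,
        n_dropped=n_dropped,
        covariance_explained_ci=cov_ci,
    )
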