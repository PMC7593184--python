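"""Compositional analysis of relative-fitness matrices.

The three haplotypes' relative fitnesses sum to a constant per line
(zero-sum constraint of compositional data), so the lines x 3 fitness
matrix has rank 2. A PCA on the correlation matrix reduces it to two
orthogonal axes (W_PC1, W_PC2) that jointly carry 100% of the
variance; thermal-regime, nuclear-background and interaction effects
are then tested in the between-subjects stratum of a repeated-measures
ANOVA (the two PC responses being the non-focal within-subject factor),
with Type III sums of squares on the unbalanced realized design, and
with permutation p-values obtained by shuffling whole lines across
treatments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from .constants import HAPLOTYPES

__all__ = [
    "FitnessPCScores",
    "RMAnovaResult",
    "fitness_pca",
    "rm_anova",
    "permutation_test",
    "per_haplotype_anova",
    "FactorialAnova",
]


# ---------------------------------------------------------------------------
# PCA on the correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class FitnessPCScores:
    """Scores and loadings of the fitness-matrix PCA."""

    scores: pd.DataFrame  # index line_id, columns PC1, PC2
    eigenvalues: np.ndarray  # all 3, descending
    loadings: pd.DataFrame  # index haplotype, columns PC1, PC2
    variance_explained: np.ndarray  # fractions for PC1, PC2


def fitness_pca(W: pd.DataFrame) -> FitnessPCScores:
    """PCA of the per-line fitness matrix, based on the correlation matrix.

    ``W`` is indexed by line_id with columns BRA, CAL, YEM. Columns are
    standardized, the 3x3 correlation matrix is eigendecomposed, and the
    first two components are retained; because rows satisfy the zero-sum
    constraint, the third eigenvalue is numerically zero and PC1 + PC2
    describe 100% of the variance. Sign convention: the
    largest-magnitude loading of each component is positive.
    """

    X = W[list(HAPLOTYPES)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 lines for a PCA")
    sd = X.std(axis=0, ddof=1)
    zero_var = [HAPLOTYPES[i] for i in np.flatnonzero(sd == 0)]
    if zero_var:
        raise ValueError(f"zero-variance fitness column(s): {zero_var}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    for k in range(2):
        if eigvec[np.argmax(np.abs(eigvec[:, k])), k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = Z @ eigvec[:, :2]
    return FitnessPCScores(
        scores=pd.DataFrame(scores, index=W.index, columns=["PC1", "PC2"]),
        eigenvalues=eigval,
        loadings=pd.DataFrame(eigvec[:, :2], index=list(HAPLOTYPES), columns=["PC1", "PC2"]),
        variance_explained=eigval[:2] / eigval.sum(),
    )


# ---------------------------------------------------------------------------
# Type III factorial ANOVA (sum-to-zero coding)
# ---------------------------------------------------------------------------


def _effect_codes(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""

    idx = {lv: i for i, lv in enumerate(levels)}
    k = len(levels)
    X = np.zeros((len(labels), k - 1))
    for r, lab in enumerate(labels):
        i = idx[lab]
        if i < k - 1:
            X[r, i] = 1.0
        else:
            X[r, :] = -1.0
    return X


def _rss_projector(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis Q of X; RSS(y|X) = y.y - ||Q'y||^2."""

    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


class FactorialAnova:
    """Fixed-effects factorial ANOVA with Type III sums of squares.

    Factors use sum-to-zero coding, so each term's SS is the increase
    in residual SS when its columns are dropped from the full model —
    the Type III convention appropriate for the unbalanced realized
    design. Supports one or two factors (with interaction).
    """

    def __init__(self, factors: dict[str, np.ndarray], interaction: bool = True):
        if not 1 <= len(factors) <= 2:
            raise ValueError("supports 1 or 2 factors")
        self.factor_names = list(factors)
        self.n = len(next(iter(factors.values())))
        blocks: dict[str, np.ndarray] = {}
        levels = {}
        for name, labels in factors.items():
            labels = np.asarray(labels)
            if len(labels) != self.n:
                raise ValueError("factor label vectors differ in length")
            levels[name] = sorted(pd.unique(labels).tolist())
            blocks[name] = _effect_codes(labels, levels[name])
        if len(factors) == 2 and interaction:
            a, b = self.factor_names
            cols = [
                blocks[a][:, i] * blocks[b][:, j]
                for i in range(blocks[a].shape[1])
                for j in range(blocks[b].shape[1])
            ]
            blocks[f"{a} x {b}"] = np.column_stack(cols)
            # empty-cell check: interaction needs every cell occupied
            fa, fb = (np.asarray(factors[a]), np.asarray(factors[b]))
            empty = [
                (la, lb)
                for la in levels[a]
                for lb in levels[b]
                if not np.any((fa == la) & (fb == lb))
            ]
            if empty:
                raise ValueError(f"empty design cell(s): {empty}")
            thin = [
                (la, lb)
                for la in levels[a]
                for lb in levels[b]
                if np.sum((fa == la) & (fb == lb)) < 2
            ]
            if thin:
                warnings.warn(f"design cell(s) with fewer than 2 lines: {thin}")
        self.blocks = blocks
        self.sources = list(blocks)
        intercept = np.ones((self.n, 1))
        X_full = np.column_stack([intercept] + [blocks[s] for s in self.sources])
        self._q_full = _rss_projector(X_full)
        self.df_err = self.n - self._q_full.shape[1]
        if self.df_err < 1:
            raise ValueError("no residual degrees of freedom")
        self._q_reduced = {}
        self.df_source = {}
        for s in self.sources:
            X_red = np.column_stack(
                [intercept] + [blocks[o] for o in self.sources if o != s]
            )
            self._q_reduced[s] = _rss_projector(X_red)
            self.df_source[s] = blocks[s].shape[1]
        self._q_no_intercept = _rss_projector(
            np.column_stack([blocks[s] for s in self.sources])
        )

    def _rss(self, y: np.ndarray, q: np.ndarray) -> float:
        return float(y @ y - (q.T @ y) @ (q.T @ y))

    def f_stats(self, y: np.ndarray) -> dict[str, tuple[float, float]]:
        """Per source: (SS, F)."""

        y = np.asarray(y, dtype=float)
        rss_full = max(self._rss(y, self._q_full), 0.0)
        ms_err = rss_full / self.df_err
        out = {}
        for s in self.sources:
            ss = max(self._rss(y, self._q_reduced[s]) - self._rss(y, self._q_full), 0.0)
            if ms_err <= 1e-300:
                f = 0.0 if ss <= 1e-300 else np.inf
            else:
                f = (ss / self.df_source[s]) / ms_err
            out[s] = (ss, f)
        return out

    def intercept_test(self, y: np.ndarray) -> tuple[float, float]:
        """Type III SS and F for the grand mean (used in the within stratum)."""

        y = np.asarray(y, dtype=float)
        rss_full = max(self._rss(y, self._q_full), 0.0)
        ss = max(self._rss(y, self._q_no_intercept) - rss_full, 0.0)
        ms_err = rss_full / self.df_err
        f = (ss / 1.0) / ms_err if ms_err > 1e-300 else (0.0 if ss <= 1e-300 else np.inf)
        return ss, f

    def table(self, y: np.ndarray, intercept_label: str | None = None) -> pd.DataFrame:
        y = np.asarray(y, dtype=float)
        rows = []
        if intercept_label is not None:
            ss, f = self.intercept_test(y)
            rows.append(
                {
                    "source": intercept_label,
                    "df": 1,
                    "SS": ss,
                    "MS": ss,
                    "F": f,
                    "p": float(stats.f.sf(f, 1, self.df_err)),
                }
            )
        for s, (ss, f) in self.f_stats(y).items():
            df_s = self.df_source[s]
            rows.append(
                {
                    "source": s,
                    "df": df_s,
                    "SS": ss,
                    "MS": ss / df_s,
                    "F": f,
                    "p": float(stats.f.sf(f, df_s, self.df_err)),
                }
            )
        rss_full = max(self._rss(y, self._q_full), 0.0)
        rows.append(
            {
                "source": "Error",
                "df": self.df_err,
                "SS": rss_full,
                "MS": rss_full / self.df_err,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _aligned(design: pd.DataFrame, index) -> pd.DataFrame:
    d = design.set_index("line_id") if "line_id" in design.columns else design
    missing = set(index) - set(d.index)
    if missing:
        raise ValueError(f"lines missing from design table: {sorted(missing)}")
    return d.loc[list(index)]


def _engine_for(design: pd.DataFrame, index) -> FactorialAnova:
    d = _aligned(design, index)
    return FactorialAnova(
        {"Thermal regime": d["thermal"].to_numpy(), "Nuclear background": d["nuclear"].to_numpy()}
    )


@dataclass
class RMAnovaResult:
    """Between- and within-subjects strata of the repeated-measures ANOVA."""

    between: pd.DataFrame
    within: pd.DataFrame


def rm_anova(scores: FitnessPCScores, design: pd.DataFrame) -> RMAnovaResult:
    """Repeated-measures ANOVA of the two PC responses.

    The two PC scores per line are the (non-focal) within-subject
    factor. The focal between-subjects stratum tests thermal regime,
    nuclear background and their interaction on the per-line mean of
    the two responses (Type III SS, sum-to-zero coding); with 23 lines
    this leaves 23 - 6 = 17 error df. The within stratum (reported for
    completeness) applies the same model to the per-line PC1 - PC2
    contrast.
    """

    engine = _engine_for(design, scores.scores.index)
    y_between = scores.scores.mean(axis=1).to_numpy()
    between = engine.table(y_between)
    y_within = (scores.scores["PC1"] - scores.scores["PC2"]).to_numpy() / np.sqrt(2)
    within = engine.table(y_within, intercept_label="PC axis")
    within["source"] = within["source"].map(
        lambda s: s if s in ("PC axis", "Error") else f"PC axis x {s}"
    )
    return RMAnovaResult(between=between, within=within)


def per_haplotype_anova(W: pd.DataFrame, design: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Separate two-way fixed-effects ANOVA of each haplotype's W."""

    engine = _engine_for(design, W.index)
    out = {}
    for hap in HAPLOTYPES:
        y = W[hap].to_numpy(dtype=float)
        if y.std(ddof=1) == 0:
            raise ValueError(f"zero-variance fitness column: {hap}")
        out[hap] = engine.table(y)
    return out


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


def _n_distinct_labelings(labels: list) -> int:
    counts = pd.Series(labels).value_counts()
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


_FACTOR_NAMES = {"thermal": "Thermal regime", "nuclear": "Nuclear background"}


def permutation_test(
    scores,
    design: pd.DataFrame,
    n_perm: int = 9_999,
    seed: int | None = None,
    factors: tuple[str, ...] = ("thermal", "nuclear"),
) -> pd.DataFrame:
    """Permutation p-values for the between-subjects ANOVA sources.

    Whole lines (the unit of replication) are reassigned to treatments
    uniformly at random, unrestricted across both factors, and each
    source's F is recomputed; p_rand = (1 + #{F_perm >= F_obs}) /
    (n_perm + 1). When the design admits no more than ``n_perm``
    distinct line-to-treatment assignments, all of them are enumerated
    and the p-value is exact (#{F >= F_obs} / #assignments, the
    identity assignment included).
    """

    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(scores, FitnessPCScores):
        y = scores.scores.mean(axis=1).to_numpy()
        index = scores.scores.index
    else:
        y = np.asarray(scores, dtype=float)
        index = design["line_id"] if "line_id" in design.columns else design.index
    d = _aligned(design, index)
    labels = {
        _FACTOR_NAMES.get(f, f): d[f].to_numpy() for f in factors
    }
    engine = FactorialAnova(labels)
    obs = {s: f for s, (_, f) in engine.f_stats(y).items()}

    joint = list(zip(*labels.values()))
    n_distinct = _n_distinct_labelings(joint)
    counts = {s: 0 for s in engine.sources}
    if n_distinct <= n_perm:
        total = 0
        for arrangement in multiset_permutations(joint):
            eng_p = FactorialAnova(
                {
                    name: np.array([a[k] for a in arrangement])
                    for k, name in enumerate(labels)
                }
            )
            fs = eng_p.f_stats(y)
            for s in engine.sources:
                if fs[s][1] >= obs[s] - 1e-12:
                    counts[s] += 1
            total += 1
        p_rand = {s: counts[s] / total for s in engine.sources}
        n_used = total
        exact = True
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            y_perm = rng.permutation(y)
            fs = engine.f_stats(y_perm)
            for s in engine.sources:
                if fs[s][1] >= obs[s] - 1e-12:
                    counts[s] += 1
        p_rand = {s: (1 + counts[s]) / (n_perm + 1) for s in engine.sources}
        n_used = n_perm
        exact = False
    return pd.DataFrame(
        [
            {"source": s, "F_obs": obs[s], "p_rand": p_rand[s], "n_perm": n_used, "exact": exact}
            for s in engine.sources
        ]
    )
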