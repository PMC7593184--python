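"""Compositional PCA and factorial/permutation inference."""

import numpy as np
import pandas as pd
import pytest

from mitosel.anova import (
    FactorialAnova,
    fitness_pca,
    per_haplotype_anova,
    permutation_test,
    rm_anova,
)
from mitosel.simulate import full_design


def random_zero_sum_W(rng, n=23, scale=0.01):
    """Fitness matrices whose rows sum to a constant (3), like real W."""

    dev = rng.normal(0, scale, size=(n, 3))
    dev -= dev.mean(axis=1, keepdims=True)
    W = 1.0 + dev
    return pd.DataFrame(W, columns=["BRA", "CAL", "YEM"], index=[f"L{i}" for i in range(n)])


class TestFitnessPca:
    def test_zero_sum_geometry(self):
        rng = np.random.default_rng(0)
        pcs = fitness_pca(random_zero_sum_W(rng))
        assert pcs.eigenvalues[2] < 1e-9
        assert pcs.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(pcs.scores.mean(axis=0), 0, atol=1e-9)

    def test_eigenvalues_match_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        W = pd.DataFrame(
            rng.normal(size=(4, 3)), columns=["BRA", "CAL", "YEM"], index=list("abcd")
        )
        pcs = fitness_pca(W)
        Z = (W - W.mean()) / W.std(ddof=1)
        oracle = PCA(n_components=3).fit(Z.to_numpy())
        # sklearn's explained_variance_ is the covariance eigenvalue of Z,
        # i.e. the correlation-matrix eigenvalue
        assert np.allclose(pcs.eigenvalues, oracle.explained_variance_, atol=1e-10)
        for k in range(2):
            v = oracle.components_[k]
            got = pcs.loadings.iloc[:, k].to_numpy()
            assert np.allclose(got, v, atol=1e-8) or np.allclose(got, -v, atol=1e-8)

    def test_identical_rows_error(self):
        W = pd.DataFrame(np.ones((5, 3)), columns=["BRA", "CAL", "YEM"])
        with pytest.raises(ValueError, match="zero-variance"):
            fitness_pca(W)

    def test_column_relabeling_leaves_f_invariant(self):
        rng = np.random.default_rng(2)
        W = random_zero_sum_W(rng)
        design = full_design()
        W.index = design["line_id"]
        perm_W = W[["CAL", "YEM", "BRA"]]
        perm_W.columns = ["BRA", "CAL", "YEM"]
        f1 = rm_anova(fitness_pca(W), design).between.set_index("source")["F"]
        f2 = rm_anova(fitness_pca(perm_W), design).between.set_index("source")["F"]
        assert np.allclose(f1.dropna(), f2.dropna(), atol=1e-9)


class TestTypeIIIAnova:
    def _toy(self, rng, n=23):
        design = full_design()
        y = rng.normal(size=len(design))
        return design, y

    def test_matches_statsmodels_type3_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        design, y = self._toy(rng)
        eng = FactorialAnova(
            {
                "Thermal regime": design["thermal"].to_numpy(),
                "Nuclear background": design["nuclear"].to_numpy(),
            }
        )
        table = eng.table(y).set_index("source")

        df = design.assign(y=y)
        model = smf.ols(
            "y ~ C(thermal, Sum) * C(nuclear, Sum)", data=df
        ).fit()
        oracle = sm.stats.anova_lm(model, typ=3)
        assert table.loc["Thermal regime", "F"] == pytest.approx(
            oracle.loc["C(thermal, Sum)", "F"], rel=1e-9
        )
        assert table.loc["Nuclear background", "F"] == pytest.approx(
            oracle.loc["C(nuclear, Sum)", "F"], rel=1e-9
        )
        assert table.loc["Thermal regime x Nuclear background", "F"] == pytest.approx(
            oracle.loc["C(thermal, Sum):C(nuclear, Sum)", "F"], rel=1e-9
        )
        assert table.loc["Error", "df"] == len(design) - 6

    def test_balanced_design_hand_partitioned(self):
        # balanced 2x3 with r=4: SS computed from cell/marginal means
        rng = np.random.default_rng(4)
        levels_a = np.repeat(["hot", "cold"], 12)
        levels_b = np.tile(np.repeat(["B1", "B2", "B3"], 4), 2)
        y = rng.normal(size=24)
        eng = FactorialAnova({"A": levels_a, "B": levels_b})
        table = eng.table(y).set_index("source")

        grand = y.mean()
        ss_a = sum(
            12 * (y[levels_a == a].mean() - grand) ** 2 for a in ("hot", "cold")
        )
        ss_b = sum(
            8 * (y[levels_b == b].mean() - grand) ** 2 for b in ("B1", "B2", "B3")
        )
        ss_cells = 0.0
        for a in ("hot", "cold"):
            for b in ("B1", "B2", "B3"):
                m = (levels_a == a) & (levels_b == b)
                ss_cells += 4 * (y[m].mean() - grand) ** 2
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((y[(levels_a == a) & (levels_b == b)]
              - y[(levels_a == a) & (levels_b == b)].mean()) ** 2).sum()
            for a in ("hot", "cold")
            for b in ("B1", "B2", "B3")
        )
        assert table.loc["A", "SS"] == pytest.approx(ss_a, abs=1e-9)
        assert table.loc["B", "SS"] == pytest.approx(ss_b, abs=1e-9)
        assert table.loc["A x B", "SS"] == pytest.approx(ss_ab, abs=1e-9)
        assert table.loc["Error", "SS"] == pytest.approx(ss_err, abs=1e-9)
        f_a = (ss_a / 1) / (ss_err / 18)
        assert table.loc["A", "F"] == pytest.approx(f_a, abs=1e-9)

    def test_balanced_type3_equals_sequential(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        design = full_design(missing_lines=())  # balanced 24-line design
        y = rng.normal(size=24)
        eng = FactorialAnova(
            {
                "Thermal regime": design["thermal"].to_numpy(),
                "Nuclear background": design["nuclear"].to_numpy(),
            }
        )
        table = eng.table(y).set_index("source")
        df = design.assign(y=y)
        seq = sm.stats.anova_lm(
            smf.ols("y ~ C(thermal, Sum) * C(nuclear, Sum)", data=df).fit(), typ=1
        )
        assert table.loc["Thermal regime", "SS"] == pytest.approx(
            seq.loc["C(thermal, Sum)", "sum_sq"], abs=1e-9
        )
        assert table.loc["Nuclear background", "SS"] == pytest.approx(
            seq.loc["C(nuclear, Sum)", "sum_sq"], abs=1e-9
        )

    def test_empty_cell_is_error(self):
        design = full_design()
        drop = design[
            (design["thermal"] == "35C") & (design["nuclear"] == "Brazil")
        ].index
        broken = design.drop(drop)
        with pytest.raises(ValueError, match="empty design cell"):
            FactorialAnova(
                {
                    "Thermal regime": broken["thermal"].to_numpy(),
                    "Nuclear background": broken["nuclear"].to_numpy(),
                }
            )

    def test_rm_anova_error_df_and_strata(self):
        rng = np.random.default_rng(6)
        design = full_design()
        W = random_zero_sum_W(rng)
        W.index = design["line_id"]
        res = rm_anova(fitness_pca(W), design)
        between = res.between.set_index("source")
        assert between.loc["Error", "df"] == 17
        assert {"Thermal regime", "Nuclear background"} < set(between.index)
        assert "PC axis" in set(res.within["source"])

    def test_per_haplotype_tables(self):
        rng = np.random.default_rng(7)
        design = full_design()
        W = random_zero_sum_W(rng)
        W.index = design["line_id"]
        tables = per_haplotype_anova(W, design)
        assert set(tables) == {"BRA", "CAL", "YEM"}
        for t in tables.values():
            assert t.set_index("source").loc["Error", "df"] == 17
        W_const = W.copy()
        W_const["CAL"] = 1.0
        with pytest.raises(ValueError, match="CAL"):
            per_haplotype_anova(W_const, design)


class TestPermutation:
    def test_constant_response_p_one(self):
        design = full_design()
        y = np.zeros(len(design))
        out = permutation_test(y, design, n_perm=199, seed=0)
        assert (out["p_rand"] == 1).all()

    def test_exact_enumeration_matches_brute_force(self):
        # 4 lines, one factor with 2+2 labels: 6 distinct labelings
        from itertools import permutations

        design = pd.DataFrame(
            {
                "line_id": ["a", "b", "c", "d"],
                "thermal": ["23C", "23C", "35C", "35C"],
            }
        )
        y = np.array([0.3, -0.1, 1.2, 0.8])
        out = permutation_test(y, design, n_perm=999, seed=0, factors=("thermal",))
        assert bool(out["exact"].iloc[0])
        assert out["n_perm"].iloc[0] == 6

        # brute-force oracle over all 24 raw permutations of labels
        labels = design["thermal"].to_numpy()

        def f_stat(lab):
            eng = FactorialAnova({"Thermal regime": np.asarray(lab)})
            return eng.f_stats(y)["Thermal regime"][1]

        f_obs = f_stat(labels)
        fs = [f_stat(p) for p in set(permutations(labels))]
        p_expected = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert out["p_rand"].iloc[0] == pytest.approx(p_expected, abs=1e-12)

    def test_sampled_p_close_to_parametric_under_null(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        design = full_design()
        eng = FactorialAnova(
            {
                "Thermal regime": design["thermal"].to_numpy(),
                "Nuclear background": design["nuclear"].to_numpy(),
            }
        )
        diffs = []
        for s in range(40):
            y = rng.normal(size=len(design))
            out = permutation_test(y, design, n_perm=299, seed=s).set_index("source")
            fs = eng.f_stats(y)
            for src, (_, f) in fs.items():
                p_param = stats.f.sf(f, eng.df_source[src], eng.df_err)
                diffs.append(out.loc[src, "p_rand"] - p_param)
        assert abs(np.mean(diffs)) < 0.02

    def test_p_rand_bounds(self):
        rng = np.random.default_rng(9)
        design = full_design()
        y = rng.normal(size=len(design))
        out = permutation_test(y, design, n_perm=199, seed=1)
        assert ((out["p_rand"] > 0) & (out["p_rand"] <= 1)).all()
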