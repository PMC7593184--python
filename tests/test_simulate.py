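"""Synthetic-data generator: trajectories, pool-seq counts, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosel.constants import HAPLOTYPES, NATIVE_HAPLOTYPE
from mitosel.simulate import (
    SimulationParams,
    full_design,
    line_rng,
    simulate_control_samples,
    simulate_experiment,
    simulate_lrs,
    simulate_poolseq_counts,
    simulate_wf_trajectory,
)

UNIFORM = np.full(3, 1.0 / 3.0)


def closed_form(f0, w, t):
    """Independent oracle: f_i(t) = f_i(0) W_i^t / sum_j f_j(0) W_j^t."""

    f0, w = np.asarray(f0, float), np.asarray(w, float)
    num = f0 * w**t
    return num / num.sum()


class TestWrightFisherTrajectory:
    def test_neutral_deterministic_identity(self, det_params):
        traj = simulate_wf_trajectory(UNIFORM, np.ones(3), 36, det_params)
        assert traj.shape == (37, 3)
        assert np.allclose(traj, 1 / 3, atol=1e-12)

    def test_deterministic_matches_closed_form(self, det_params):
        w = np.array([1.02, 1.00, 0.98])
        traj = simulate_wf_trajectory(UNIFORM, w, 20, det_params)
        assert np.allclose(traj[-1], [0.4712, 0.3171, 0.2117], atol=1e-4)
        for t in range(21):
            assert np.allclose(traj[t], closed_form(UNIFORM, w, t), atol=1e-12)

    def test_deterministic_closed_form_random_fitness(self, det_params):
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = rng.uniform(0.9, 1.1, size=3)
            f0 = rng.dirichlet(np.ones(3))
            t = int(rng.integers(1, 40))
            traj = simulate_wf_trajectory(f0, w, t, det_params)
            assert np.allclose(traj[-1], closed_form(f0, w, t), atol=1e-12)

    def test_drift_variance_matches_binomial_oracle(self, params):
        # one generation of neutral drift: Var(p) = p(1-p)/n_females
        rng = np.random.default_rng(11)
        n_rep = 8_000
        finals = np.array(
            [simulate_wf_trajectory(UNIFORM, np.ones(3), 1, params, rng)[-1] for _ in range(n_rep)]
        )
        expected_var = (1 / 3) * (2 / 3) / params.n_females
        var = finals.var(axis=0)
        # chi-square MC error on a variance estimate: sd ~ var * sqrt(2/n)
        assert np.allclose(var, expected_var, rtol=6 * np.sqrt(2 / n_rep))
        se = np.sqrt(expected_var / n_rep)
        assert np.allclose(finals.mean(axis=0), 1 / 3, atol=4 * se)

    def test_t_zero_returns_start_only(self, params):
        traj = simulate_wf_trajectory(UNIFORM, np.ones(3), 0, params)
        assert traj.shape == (1, 3)

    def test_nonpositive_fitness_rejected(self, params):
        with pytest.raises(ValueError, match="positive"):
            simulate_wf_trajectory(UNIFORM, [1.0, 0.0, 1.0], 5, params)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), t=st.integers(1, 50))
    def test_compositions_always_sum_to_one(self, seed, t):
        params = SimulationParams(seed=seed)
        rng = np.random.default_rng(seed)
        traj = simulate_wf_trajectory(UNIFORM, [1.02, 1.0, 0.97], t, params, rng)
        assert np.all(traj >= 0)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-9)


class TestPoolseqCounts:
    def test_degenerate_composition_all_reads_one_haplotype(self, params):
        counts = simulate_poolseq_counts([1.0, 0.0, 0.0], params, np.random.default_rng(0))
        by_hap = counts.groupby("haplotype")["reads"].sum()
        assert by_hap["CAL"] == by_hap["YEM"] == 0
        assert by_hap["BRA"] > 0

    def test_bias_shifts_expected_read_share(self):
        # composition (0.5, 0.3, 0.2) with 2x bias on haplotype 1 in every
        # gene: expected share of hap 1 = (0.5*2)/(0.5*2 + 0.3 + 0.2) = 2/3
        bias = np.ones((13, 3))
        bias[:, 0] = 2.0
        params = SimulationParams(bias_factors=bias, seed=0)
        rng = np.random.default_rng(1)
        shares = []
        for i in range(200):
            c = simulate_poolseq_counts(
                [0.5, 0.3, 0.2], params, rng, skip_pool=True
            )
            tot = c.groupby("haplotype")["reads"].sum()
            shares.append(tot["BRA"] / tot.sum())
        assert abs(np.mean(shares) - 2 / 3) < 0.005

    def test_unbiased_control_proportions_average_one_third(self, params):
        rng = np.random.default_rng(2)
        props = []
        for _ in range(100):
            c = simulate_poolseq_counts(UNIFORM, params, rng, skip_pool=True)
            tot = c.groupby("haplotype")["reads"].sum()
            props.append((tot / tot.sum()).reindex(list(HAPLOTYPES)).to_numpy())
        assert np.allclose(np.mean(props, axis=0), 1 / 3, atol=0.01)

    def test_zero_coverage_warns_and_returns_empty(self):
        params = SimulationParams(total_reads=0.0)
        with pytest.warns(UserWarning, match="zero coverage"):
            out = simulate_poolseq_counts(UNIFORM, params)
        assert out.empty

    def test_deterministic_mode_counts_are_exact_expectations(self, det_params):
        c = simulate_poolseq_counts([0.5, 0.3, 0.2], det_params)
        per_gene = c.pivot(index="gene", columns="haplotype", values="reads")
        props = per_gene.div(per_gene.sum(axis=1), axis=0)[list(HAPLOTYPES)]
        assert np.allclose(props.to_numpy(), [0.5, 0.3, 0.2], atol=1e-12)


class TestControlSamples:
    def test_zero_controls_is_an_error(self, params):
        with pytest.raises(ValueError):
            simulate_control_samples(0, params)

    def test_controls_flagged_and_complete(self, params):
        c = simulate_control_samples(3, params)
        assert c["is_control"].all()
        assert c["sample_id"].nunique() == 3
        assert set(c["gene"]) == set(params.genes)


class TestLrsGenerator:
    def _lines(self):
        return pd.DataFrame(
            [
                {"line_id": "mixA", "line_type": "mix", "nuclear": "California"},
                {"line_id": "mixB", "line_type": "mix", "nuclear": "California"},
                {"line_id": "California-pure", "line_type": "pure", "nuclear": "California"},
            ]
        )

    def test_female_eggs_halved(self):
        phen = simulate_lrs(self._lines(), {}, None, n_assays=5, seed=0)
        females = phen[phen["sex"] == "female"]
        males = phen[phen["sex"] == "male"]
        assert np.allclose(females["adjusted_eggs"], females["fertile_eggs"] / 2)
        assert np.allclose(males["adjusted_eggs"], males["fertile_eggs"])

    def test_null_generator_equal_group_means(self):
        phen = simulate_lrs(self._lines(), {}, None, n_assays=400, line_sd=0.0, seed=1)
        means = np.log(
            phen.groupby("line_id")["adjusted_eggs"].mean()
        )
        assert means.max() - means.min() < 0.1

    def test_planted_cal_effect_recovered(self):
        # CAL effect +0.2 on the log scale; a line at CAL frequency 0.5
        # outproduces one at 1/3, detectable by a two-sample comparison
        comps = {("mixA", 3): np.array([0.25, 0.5, 0.25]), ("mixA", 33): np.array([0.25, 0.5, 0.25])}
        phen = simulate_lrs(
            self._lines(),
            {"CAL": 0.2},
            comps,
            n_assays=100,
            line_sd=0.0,
            residual_sd=0.1,
            seed=2,
        )
        from scipy.stats import ttest_ind

        # compare log counts within each sex x generation cell so the
        # shared sex/generation shifts do not inflate the variance
        logs = phen.assign(log_eggs=np.log(phen["adjusted_eggs"].clip(lower=0.5)))
        diffs, pvals = [], []
        for (_, _), cell in logs.groupby(["sex", "generation"]):
            a = cell.loc[cell["line_id"] == "mixA", "log_eggs"]
            b = cell.loc[cell["line_id"] == "mixB", "log_eggs"]
            diffs.append(a.mean() - b.mean())
            pvals.append(ttest_ind(a, b, alternative="greater").pvalue)
        # planted difference: 0.2 * (0.5 - 1/3) on the log scale
        assert abs(np.mean(diffs) - 0.2 / 6) < 0.02
        assert min(pvals) < 1e-3


class TestExperimentBundle:
    def test_same_seed_identical_outputs(self):
        b1 = simulate_experiment(seed=7, n_assays=3)
        b2 = simulate_experiment(seed=7, n_assays=3)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        pd.testing.assert_frame_equal(b1.phenotypes, b2.phenotypes)
        assert b1.counts.to_csv() == b2.counts.to_csv()  # byte-identical

    def test_design_and_line_streams(self):
        design = full_design()
        assert len(design) == 23
        assert len(full_design(missing_lines=())) == 24
        assert (
            design.groupby("thermal")["generations"].nunique() == 1
        ).all()
        r1 = line_rng(1, "a").integers(0, 1 << 30)
        r2 = line_rng(1, "a").integers(0, 1 << 30)
        r3 = line_rng(1, "b").integers(0, 1 << 30)
        assert r1 == r2 != r3

    def test_bundle_compositions_valid(self):
        b = simulate_experiment(seed=3, n_assays=2)
        for comp in b.true_compositions.values():
            assert abs(comp.sum() - 1) < 1e-9
        mix_samples = set(b.counts.loc[~b.counts["is_control"], "sample_id"])
        assert mix_samples == set(b.design["line_id"])
        natives = {NATIVE_HAPLOTYPE[n] for n in b.design["nuclear"]}
        assert natives <= set(HAPLOTYPES)
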