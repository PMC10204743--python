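"""fp metric, KS tests, AMMI decomposition, RDPI and validation metrics."""

import numpy as np
import pandas as pd
import pytest

from alaem.stats import (AMMI, HEADLINE_PAIRS, ammi_fit,
                         fraction_perpendicular, gollob_df, ks_two_sample,
                         ks_uniform, rdpi, rdpi_table, validation_metrics)
from alaem.synthetic import (FpTableSpec, rank_one_interaction,
                             simulate_fp_table)


class TestFractionPerpendicular:
    def test_counting(self):
        rec = fraction_perpendicular([50, 70, 80, 10], 45)
        assert rec.fp == pytest.approx(0.75)
        assert rec.n_leaves == 4

    def test_all_parallel_gives_zero(self):
        assert fraction_perpendicular([0, 0, 0], 45).fp == 0.0

    def test_strict_inequality_at_threshold(self):
        assert fraction_perpendicular([45.0, 46.0], 45).fp == pytest.approx(0.5)

    def test_monotone_in_threshold(self, rng):
        a = rng.uniform(0, 90, 200)
        assert (fraction_perpendicular(a, 60).fp
                <= fraction_perpendicular(a, 45).fp)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fraction_perpendicular([], 45)
        with pytest.raises(ValueError):
            fraction_perpendicular([95.0], 45)


class TestKS:
    def test_single_observation_at_midpoint(self):
        # ECDF jumps 0 -> 1 at 45; sup distance to x/90 is 0.5 on both sides
        res = ks_uniform([45.0])
        assert res.statistic == pytest.approx(0.5)
        assert res.mode == "one_sample_uniform"

    def test_point_mass_at_boundary(self):
        res = ks_uniform([90.0] * 10)
        assert res.statistic == pytest.approx(1.0)

    def test_identical_samples_give_zero(self):
        a = [10.0, 20.0, 30.0]
        res = ks_two_sample(a, a)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_one(self):
        res = ks_two_sample([10, 20], [70, 80])
        assert res.statistic == pytest.approx(1.0)

    def test_two_sample_matches_brute_force_ecdf_sup(self):
        a = np.arange(1.0, 51.0)
        b = np.arange(26.0, 76.0)
        res = ks_two_sample(a, b)
        grid = np.concatenate([a, b])
        sup = max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in grid)
        assert sup == pytest.approx(0.5)
        assert res.statistic == pytest.approx(sup)

    def test_one_sample_consistent_with_two_sample_vs_dense_grid(self):
        a = np.array([5.0, 30.0, 33.0, 80.0, 88.0])
        grid = np.linspace(0, 90, 20001)[1:]    # ~uniform reference sample
        d1 = ks_uniform(a).statistic
        d2 = ks_two_sample(a, grid).statistic
        assert d2 == pytest.approx(d1, abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_uniform([])
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [])


class TestAMMI:
    @staticmethod
    def simulated_5x4(noise_sd=0.0, seed=0, replicates=1, lam=0.3):
        inter = rank_one_interaction(
            lam, b=[2.0, 1.0, 0.0, -1.0, -2.0], z=[1.5, 0.5, -0.5, -1.5])
        return FpTableSpec(mu=0.45,
                           g_effects=[0.06, 0.02, 0.0, -0.03, -0.05],
                           r_effects=[-0.09, -0.03, 0.04, 0.08],
                           interaction=inter, noise_sd=noise_sd, seed=seed,
                           replicates=replicates), inter

    def test_gollob_df_bookkeeping_for_5x4(self):
        spec, _ = self.simulated_5x4(noise_sd=0.01)
        model = ammi_fit(simulate_fp_table(spec), n_components=2)
        anova = model.anova_.set_index("source")
        assert anova.loc["Interactions", "df"] == 12
        assert anova.loc["PC1", "df"] == 6
        assert anova.loc["PC2", "df"] == 4
        assert anova.loc["Residuals", "df"] == 2
        assert anova.loc["Genotype", "df"] == 4
        assert anova.loc["Environment", "df"] == 3

    @pytest.mark.parametrize("g,e", [(5, 4), (3, 7), (6, 6)])
    def test_gollob_df_sum_matches_interaction_df(self, g, e, rng):
        table = rng.random((g, e))
        model = ammi_fit(table)           # full rank
        anova = model.anova_.set_index("source")
        pc_df = [anova.loc[f"PC{k}", "df"]
                 for k in range(1, model.n_components_ + 1)]
        assert sum(pc_df) + anova.loc["Residuals", "df"] == (g - 1) * (e - 1)
        assert all(gollob_df(g, e, k + 1) == d for k, d in enumerate(pc_df))

    def test_additive_noiseless_table_has_zero_interaction(self):
        spec = FpTableSpec(mu=0.5, g_effects=[0.1, 0.0, -0.1],
                           r_effects=[0.05, -0.05])
        model = ammi_fit(simulate_fp_table(spec))
        assert model.singular_values_ == pytest.approx(0.0, abs=1e-12)
        anova = model.anova_.set_index("source")
        assert anova.loc["Interactions", "sum_sq"] == pytest.approx(0, abs=1e-20)

    def test_planted_rank_one_interaction_recovered(self):
        spec, inter = self.simulated_5x4(noise_sd=0.0)
        model = ammi_fit(simulate_fp_table(spec), n_components=2)
        assert model.variance_ratio_[0] == pytest.approx(1.0)
        assert model.singular_values_[0] == pytest.approx(0.3)
        # scores proportional to the planted vectors up to sign
        b = np.array([2.0, 1.0, 0.0, -1.0, -2.0])
        z = np.array([1.5, 0.5, -0.5, -1.5])
        cb = np.corrcoef(model.genotype_scores_[:, 0], b)[0, 1]
        cz = np.corrcoef(model.env_scores_[:, 0], z)[0, 1]
        assert abs(cb) == pytest.approx(1.0, abs=1e-9)
        assert abs(cz) == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reconstruction_is_exact(self):
        spec, _ = self.simulated_5x4(noise_sd=0.03, seed=4)
        model = ammi_fit(simulate_fp_table(spec))
        recon = model.reconstruct()
        assert recon.to_numpy() == pytest.approx(
            model.cell_means_.to_numpy(), abs=1e-12)

    def test_sum_of_squares_bookkeeping(self):
        spec, _ = self.simulated_5x4(noise_sd=0.05, seed=9)
        model = ammi_fit(simulate_fp_table(spec))
        y = model.cell_means_.to_numpy()
        ss_total = np.sum((y - y.mean()) ** 2)
        anova = model.anova_.set_index("source")
        parts = (anova.loc["Environment", "sum_sq"]
                 + anova.loc["Genotype", "sum_sq"]
                 + anova.loc["Interactions", "sum_sq"])
        assert parts == pytest.approx(ss_total)
        assert np.sum(model.singular_values_ ** 2) == pytest.approx(
            anova.loc["Interactions", "sum_sq"])

    def test_effects_sum_to_zero_and_scores_unit_norm(self):
        spec, _ = self.simulated_5x4(noise_sd=0.02, seed=2)
        model = ammi_fit(simulate_fp_table(spec))
        assert model.genotype_effects_.sum() == pytest.approx(0, abs=1e-12)
        assert model.env_effects_.sum() == pytest.approx(0, abs=1e-12)
        for k in range(model.n_components_):
            assert np.linalg.norm(
                model.genotype_scores_[:, k]) == pytest.approx(1.0)
            assert np.linalg.norm(
                model.env_scores_[:, k]) == pytest.approx(1.0)

    def test_singular_values_non_increasing(self, rng):
        model = ammi_fit(rng.random((6, 5)))
        s = model.singular_values_
        assert (np.diff(s) <= 1e-12).all()

    def test_replicates_add_pooled_error_row(self):
        spec, _ = self.simulated_5x4(noise_sd=0.02, replicates=3)
        model = ammi_fit(simulate_fp_table(spec))
        anova = model.anova_.set_index("source")
        assert anova.loc["Error", "df"] == 5 * 4 * 2
        assert model.n_replicates_ == 3

    def test_missing_cells_rejected(self):
        spec, _ = self.simulated_5x4()
        df = simulate_fp_table(spec).iloc[1:]   # drop one cell
        with pytest.raises(ValueError, match="missing cells"):
            ammi_fit(df)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            ammi_fit(rng.random((5, 4)), n_components=4)

    def test_interaction_recovery_with_noise_across_seeds(self):
        """Planted vs recovered interaction matrices correlate >= 0.99 at
        noise sd 0.02 under the replicated 3-block design (averaged over
        seeds); the interaction strength keeps the per-cell signal well
        above the double-centered noise floor."""
        cors = []
        for seed in range(100):
            spec, inter = self.simulated_5x4(noise_sd=0.02, seed=seed,
                                             replicates=3, lam=0.45)
            model = ammi_fit(simulate_fp_table(spec))
            rec = model.interaction_.to_numpy().ravel()
            cors.append(np.corrcoef(rec, inter.ravel())[0, 1])
        assert np.mean(cors) >= 0.99

    def test_biplot_coordinates_shape(self):
        spec, _ = self.simulated_5x4(noise_sd=0.01)
        model = ammi_fit(simulate_fp_table(spec), n_components=2)
        bp = model.biplot_coordinates()
        assert len(bp) == 9
        assert set(bp["kind"]) == {"genotype", "environment"}


class TestRDPI:
    def test_single_pair_worked_example(self):
        res = rdpi({"R1": 10.0, "R8": 30.0})
        assert res.rdpi == pytest.approx(0.5)
        assert res.n_pairs == 1

    def test_identical_phenotypes_give_zero(self):
        assert rdpi({"R1": 7.0, "R2": 7.0, "R4": 7.0}).rdpi == 0.0

    def test_scale_invariance(self):
        vals = {"R1": 12.0, "R2": 30.0, "R4": 45.0, "R8": 70.0}
        base = rdpi(vals).rdpi
        for c in (0.1, 3.0, 100.0):
            scaled = {k: v * c for k, v in vals.items()}
            assert rdpi(scaled).rdpi == pytest.approx(base)

    def test_headline_pair_preset(self):
        vals = {"R1": 10.0, "R2": 20.0, "R4": 25.0, "R8": 30.0}
        res = rdpi(vals, pairs=HEADLINE_PAIRS)
        expected = (abs(10 - 30) / 40 + abs(20 - 30) / 50) / 2
        assert res.rdpi == pytest.approx(expected)
        assert res.n_pairs == 2

    def test_bounds(self, rng):
        for _ in range(20):
            vals = dict(zip("abcd", rng.uniform(1, 90, 4)))
            assert 0 <= rdpi(vals).rdpi <= 1

    def test_nonpositive_phenotype_rejected(self):
        with pytest.raises(ValueError):
            rdpi({"R1": 0.0, "R8": 5.0})

    def test_rdpi_table_groups_by_genotype(self):
        df = pd.DataFrame({
            "genotype": ["A"] * 2 + ["B"] * 2,
            "env": ["R1", "R8"] * 2,
            "x": [10.0, 30.0, 20.0, 20.0]})
        out = rdpi_table(df, value_col="x", env_col="env")
        out = out.set_index("genotype")
        assert out.loc["A", "rdpi"] == pytest.approx(0.5)
        assert out.loc["B", "rdpi"] == pytest.approx(0.0)


class TestValidationMetrics:
    def test_identity(self):
        m = validation_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert m.rmse == pytest.approx(0.0)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_bias(self):
        obs = np.array([0.2, 0.4, 0.6, 0.8])
        m = validation_metrics(obs + 0.1, obs)
        assert m.rmse == pytest.approx(0.1)
        assert m.r2 == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = validation_metrics([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert np.isnan(m.r2)

    def test_null_r2_matches_one_over_n_minus_one(self, rng):
        """Independent Gaussians: E[R^2] = 1/(n-1) under the null."""
        n, reps = 20, 1000
        r2s = np.empty(reps)
        for i in range(reps):
            est = rng.normal(0.5, 0.1, n)
            obs = rng.normal(0.5, 0.1, n)
            r2s[i] = validation_metrics(est, obs).r2
        assert r2s.mean() == pytest.approx(1 / (n - 1), abs=0.015)
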