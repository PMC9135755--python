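"""OLS and phylogenetic GLS: exactness, equivalences, lambda estimation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import phyloallometry as pa
from phyloallometry.pgls import PGLS

from conftest import make_table


class TestOLS:
    def test_exact_line(self):
        x = np.arange(5.0)
        tab = make_table({"species": list("ABCDE"), "x": x, "y": 2.0 * x})
        fit = pa.ols_fit(tab, "y", ["x"])
        assert fit.coef("x") == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(fit.resid, 0.0, atol=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_two_predictor_grid_vs_normal_equations(self):
        """Brute-force normal equations reproduce the fitted coefficients."""
        x, z = np.meshgrid([0.0, 1.0, 2.0], [0.0, 1.0])
        x, z = x.ravel(), z.ravel()
        y = x + z + np.array([0.1, -0.1, 0.05, -0.05, 0.02, -0.02])
        tab = make_table({"species": list("ABCDEF"), "x": x, "z": z, "y": y})
        fit = pa.ols_fit(tab, "y", ["x", "z"])
        X = np.column_stack([np.ones(6), x, z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coef("x") == pytest.approx(beta[1], abs=1e-10)
        assert fit.coef("z") == pytest.approx(beta[2], abs=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        tab = make_table({"species": [f"s{i}" for i in range(30)],
                          "x": x, "y": 0.5 * x + rng.normal(size=30)})
        fit = pa.ols_fit(tab, "y", ["x"])
        assert abs(fit.resid.sum()) < 1e-10
        assert fit.df_resid == 28
        assert np.allclose(fit.tvalues, fit.params / fit.bse)

    def test_species_fixed_effect_offset(self):
        x = np.tile(np.arange(5.0), 2)
        species = ["a"] * 5 + ["b"] * 5
        y = 1.5 * x + np.where(np.array(species) == "b", 1.0, 0.0)
        tab = make_table({"species": species, "x": x, "y": y})
        fit = pa.ols_fit(tab, "y", ["x"], species_fixed=True)
        assert fit.coef("species[b]") == pytest.approx(1.0, abs=1e-10)
        assert fit.coef("x") == pytest.approx(1.5, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(6.0)
        tab = make_table({"species": list("ABCDEF"), "x": x, "x2": 2 * x,
                          "y": x})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            pa.ols_fit(tab, "y", ["x", "x2"])

    def test_too_few_rows(self):
        tab = make_table({"species": ["A", "B"], "x": [1., 2.],
                          "y": [1., 2.]})
        with pytest.raises(ValueError, match="usable rows"):
            pa.ols_fit(tab, "y", ["x"])


class TestPGLS:
    def test_identity_covariance_equals_ols(self, star_tree):
        """With a star phylogeny (C proportional to I) PGLS is OLS exactly."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=4)
        tab = make_table({"species": list("ABCD"), "x": x,
                          "y": 0.7 * x + rng.normal(size=4)},
                         index=list("ABCD"))
        cov = star_tree.bm_covariance()
        gls = pa.pgls_fit(tab, "y", ["x"], cov, lambda_mode=1.0)
        ols = pa.ols_fit(tab, "y", ["x"])
        for attr in ("params", "bse", "tvalues"):
            assert np.allclose(getattr(gls, attr), getattr(ols, attr),
                               atol=1e-10)
        assert np.allclose(gls.resid, ols.resid.loc[gls.resid.index],
                           atol=1e-10)

    def test_three_taxon_hand_oracle(self, three_taxon_tree):
        """Explicit inverse-matrix GLS on the 3-taxon tree."""
        tab = make_table({"species": ["A", "B", "C"],
                          "x": [1.0, 0.0, 0.0], "y": [2.0, 1.0, 0.0]},
                         index=["A", "B", "C"])
        cov = three_taxon_tree.bm_covariance()
        fit = pa.pgls_fit(tab, "y", ["x"], cov, lambda_mode=1.0)
        V = np.array([[2., 1., 0.], [1., 2., 0.], [0., 0., 2.]])
        X = np.column_stack([np.ones(3), [1., 0., 0.]])
        y = np.array([2., 1., 0.])
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coef("x") == pytest.approx(beta[1], abs=1e-10)

    def test_gls_orthogonality(self, yule_tree_59, chol_59):
        """Whitened residuals are orthogonal to the design: X'V^-1 e = 0."""
        cfg = pa.SimulationConfig(n_tips=59, seed=21)
        tab = pa.simulate_species_traits(yule_tree_59, cfg, chol=chol_59)
        cov = yule_tree_59.bm_covariance()
        fit = pa.pgls_fit(tab, "log_A", ["log_size"], cov, lambda_mode=1.0)
        Vi = np.linalg.inv(cov.C)
        data = tab.data.set_index("species").loc[fit.resid.index]
        X = np.column_stack([np.ones(59), data["log_size"]])
        assert np.allclose(X.T @ Vi @ fit.resid.values, 0.0, atol=1e-8)

    def test_matches_r_nlme_brownian_gls(self, tmp_path):
        """Independent oracle: nlme::gls with an ape Brownian correlation."""
        tree = pa.simulate_tree(10, seed=4)
        tree.write(tmp_path / "tree.nwk")
        cfg = pa.SimulationConfig(n_tips=10, seed=4,
                                  residual_mode="independent")
        tab = pa.simulate_species_traits(tree, cfg)
        tab.data[["species", "log_size", "log_A"]].to_csv(
            tmp_path / "dat.csv", index=False)
        fit = pa.pgls_fit(tab, "log_A", ["log_size"], tree.bm_covariance(),
                          lambda_mode=1.0)
        script = textwrap.dedent(f"""
            suppressMessages({{library(ape); library(nlme)}})
            tree <- read.tree('{tmp_path}/tree.nwk')
            dat <- read.csv('{tmp_path}/dat.csv')
            fit <- gls(log_A ~ log_size, data=dat,
                       correlation=corBrownian(1, tree, form=~species),
                       method="REML")
            s <- summary(fit)$tTable
            cat(sprintf("%.12f %.12f %.12f %.12f", s[1,1], s[2,1],
                        s[1,2], s[2,2]))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        b0, b1, se0, se1 = map(float, out.stdout.split())
        assert fit.params["const"] == pytest.approx(b0, abs=1e-8)
        assert fit.coef("log_size") == pytest.approx(b1, abs=1e-8)
        assert fit.bse["const"] == pytest.approx(se0, abs=1e-8)
        assert fit.bse["log_size"] == pytest.approx(se1, abs=1e-8)

    def test_lambda_zero_equals_ols_on_ultrametric(self, yule_tree_59,
                                                   chol_59):
        cfg = pa.SimulationConfig(n_tips=59, seed=22)
        tab = pa.simulate_species_traits(yule_tree_59, cfg, chol=chol_59)
        cov = yule_tree_59.bm_covariance()
        gls = pa.pgls_fit(tab, "log_A", ["log_size"], cov, lambda_mode=0.0)
        ols = pa.ols_fit(tab, "log_A", ["log_size"])
        assert np.allclose(gls.params, ols.params, atol=1e-10)
        assert np.allclose(gls.bse, ols.bse, atol=1e-10)

    def test_invalid_lambda(self, three_taxon_tree):
        tab = make_table({"species": ["A", "B", "C"], "x": [1., 2., 3.],
                          "y": [1., 2., 4.]}, index=["A", "B", "C"])
        with pytest.raises(ValueError, match="lambda"):
            pa.pgls_fit(tab, "y", ["x"], three_taxon_tree.bm_covariance(),
                        lambda_mode=1.5)

    def test_missing_species_in_cov(self, three_taxon_tree):
        tab = make_table({"species": ["A", "B", "X"], "x": [1., 2., 3.],
                          "y": [1., 2., 4.]}, index=["A", "B", "X"])
        with pytest.raises(KeyError, match="X"):
            pa.pgls_fit(tab, "y", ["x"], three_taxon_tree.bm_covariance())

    def test_log_base_invariance(self, yule_tree_59, chol_59):
        """Slopes and t statistics do not depend on the log base;
        intercepts scale by ln(10)."""
        cfg = pa.SimulationConfig(n_tips=59, seed=23)
        tab10 = pa.simulate_species_traits(yule_tree_59, cfg, chol=chol_59)
        ln = np.log(10.0)
        data = tab10.data.copy()
        data["log_size"] *= ln
        data["log_A"] *= ln
        tab_e = pa.TraitTable(data, species_col="species",
                              log_cols=tab10.log_cols, log_base=np.e)
        cov = yule_tree_59.bm_covariance()
        f10 = pa.pgls_fit(tab10, "log_A", ["log_size"], cov, lambda_mode=1.0)
        fe = pa.pgls_fit(tab_e, "log_A", ["log_size"], cov, lambda_mode=1.0)
        assert fe.coef("log_size") == pytest.approx(f10.coef("log_size"),
                                                    abs=1e-10)
        assert np.allclose(fe.tvalues, f10.tvalues, atol=1e-8)
        assert fe.params["const"] == pytest.approx(ln * f10.params["const"],
                                                   abs=1e-10)

    def test_ml_lambda_recovery_under_bm(self):
        """ML lambda on pure-BM data (lambda = 1) concentrates near 1."""
        tree = pa.simulate_tree(100, seed=31)
        cov = tree.bm_covariance()
        chol = np.linalg.cholesky(cov.C)
        lams = []
        for rep in range(200):
            cfg = pa.SimulationConfig(n_tips=100, seed=40_000 + rep,
                                      sd_a=0.05)
            tab = pa.simulate_species_traits(tree, cfg, chol=chol)
            fit = pa.pgls_fit(tab, "log_A", ["log_size"], cov,
                              lambda_mode="ml")
            lams.append(fit.lam)
        assert np.median(lams) >= 0.9

    def test_metropolis_posterior_agrees_with_ml(self, yule_tree_59,
                                                 chol_59):
        """Flat-prior Metropolis draws centre near the ML estimates and
        are reproducible by seed."""
        cfg = pa.SimulationConfig(n_tips=59, seed=24)
        tab = pa.simulate_species_traits(yule_tree_59, cfg, chol=chol_59)
        model = PGLS.from_table(tab, "log_A", ["log_size"],
                                yule_tree_59.bm_covariance())
        ml = model.fit(lambda_mode="ml", reml=False)
        draws = model.sample_posterior(n_samples=2000, seed=3, burn=500)
        post_mean = draws["log_size"].mean()
        post_sd = draws["log_size"].std()
        assert abs(post_mean - ml.coef("log_size")) < 2 * post_sd
        again = model.sample_posterior(n_samples=200, seed=3, burn=50)
        assert again.equals(model.sample_posterior(n_samples=200, seed=3,
                                                   burn=50))

    def test_residual_vector_keys(self, simple_species_table):
        fit = pa.ols_fit(simple_species_table, "y", ["x"])
        res = pa.residual_vector(fit)
        assert list(res.index) == list(simple_species_table.data.index)
        assert np.allclose(res, 0.0, atol=1e-10)  # exact line


class TestAnova:
    def _sim_tables(self, rng, offset):
        x = rng.normal(size=50)
        species = np.repeat([f"s{i}" for i in range(5)], 10)
        shift = offset * (species == "s3")
        y = 0.5 * x + shift + rng.normal(scale=1.0, size=50)
        return make_table({"species": species, "x": x, "y": y})

    def test_identical_models(self, simple_species_table):
        rng = np.random.default_rng(3)
        tab = self._sim_tables(rng, 0.0)
        fit = pa.ols_fit(tab, "y", ["x"])
        res = pa.anova_term(fit, fit)
        assert res.F == 0.0 and res.p_value == 1.0

    def test_strong_species_offsets(self):
        rng = np.random.default_rng(4)
        tab = self._sim_tables(rng, 25.0)
        full = pa.ols_fit(tab, "y", ["x"], species_fixed=True)
        red = pa.ols_fit(tab, "y", ["x"])
        res = pa.anova_term(full, red, term="species")
        assert res.df_num == 4 and res.p_value < 1e-6 and res.F > 50

    def test_null_rejection_rate_nominal(self):
        """Species term with zero true effect rejects at ~5%."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            tab = self._sim_tables(rng, 0.0)
            full = pa.ols_fit(tab, "y", ["x"], species_fixed=True)
            red = pa.ols_fit(tab, "y", ["x"])
            if pa.anova_term(full, red).p_value < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.02 <= rate <= 0.08  # 0.05 +/- ~3 binomial SEs

    def test_mismatched_rows_error(self):
        rng = np.random.default_rng(6)
        tab = self._sim_tables(rng, 0.0)
        tab2 = pa.TraitTable(tab.data.iloc[:-1].copy(), "species")
        full = pa.ols_fit(tab, "y", ["x"], species_fixed=True)
        red = pa.ols_fit(tab2, "y", ["x"])
        with pytest.raises(ValueError, match="different observations"):
            pa.anova_term(full, red)

    def test_non_nested_error(self):
        rng = np.random.default_rng(7)
        tab = self._sim_tables(rng, 0.0)
        f1 = pa.ols_fit(tab, "y", ["x"])
        tab_z = tab.with_column("z", rng.normal(size=50))
        f2 = pa.ols_fit(tab_z, "y", ["z"])
        with pytest.raises(ValueError, match="nest"):
            pa.anova_term(f1, f2)
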