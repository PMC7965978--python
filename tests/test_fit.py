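import json
import subprocess

import numpy as np
import pytest

from crossclass.fit import (
    fit_crossed_ml,
    fit_nested_ml,
    log_likelihood_crossed,
)
from helpers import dense_fit_oracle, dense_loglik, make_dataset


class TestLikelihoodAgainstDenseOracle:
    @pytest.mark.parametrize(
        "sigma2,tau_col,tau_row",
        [(1.0, 0.2, 0.3), (0.5, 0.0, 0.1), (2.0, 0.01, 0.0), (1.3, 0.0556, 0.0556)],
    )
    def test_matches_explicit_covariance_solve(
        self, tiny_dataset, sigma2, tau_col, tau_row
    ):
        fast = log_likelihood_crossed(tiny_dataset, sigma2, tau_col, tau_row)
        dense = dense_loglik(tiny_dataset.records, sigma2, tau_col, tau_row)
        assert fast == pytest.approx(dense, rel=1e-8)

    def test_zero_taus_collapse_to_ols_gaussian_loglik(self, tiny_dataset):
        rec = tiny_dataset.records
        n = len(rec)
        X = np.column_stack([np.ones(n), rec["x"], rec["w"], rec["z"]])
        beta, *_ = np.linalg.lstsq(X, rec["y"].to_numpy(), rcond=None)
        rss = float(((rec["y"] - X @ beta) ** 2).sum())
        sigma2 = 0.8
        expected = -0.5 * (n * np.log(2 * np.pi * sigma2) + rss / sigma2)
        got = log_likelihood_crossed(tiny_dataset, sigma2, 0.0, 0.0)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invariant_under_row_permutation(self, tiny_dataset):
        base = log_likelihood_crossed(tiny_dataset, 1.0, 0.1, 0.2)
        shuffled = tiny_dataset.records.sample(
            frac=1.0, random_state=0
        ).reset_index(drop=True)
        assert log_likelihood_crossed(shuffled, 1.0, 0.1, 0.2) == pytest.approx(
            base, rel=1e-10
        )

    def test_rejects_invalid_components(self, tiny_dataset):
        with pytest.raises(ValueError):
            log_likelihood_crossed(tiny_dataset, 0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            log_likelihood_crossed(tiny_dataset, 1.0, -0.1, 0.1)


class TestOptimizerAgainstDenseOracle:
    def test_crossed_fit_matches_grid_plus_polish(self, tiny_dataset):
        fit = fit_crossed_ml(tiny_dataset)
        dev, beta, sigma2, taus = dense_fit_oracle(tiny_dataset.records, "crossed")
        assert fit.deviance == pytest.approx(dev, abs=1e-4)
        got = np.array([v for v, _ in fit.fixed.values()])
        assert np.allclose(got, beta, rtol=1e-4, atol=1e-5)
        assert fit.variance["sigma2_e"] == pytest.approx(sigma2, abs=1e-4)
        assert fit.variance["tau_col"] == pytest.approx(taus[0], abs=1e-4)
        assert fit.variance["tau_row"] == pytest.approx(taus[1], abs=1e-4)

    def test_nested_fit_matches_grid_plus_polish(self, tiny_dataset):
        fit = fit_nested_ml(tiny_dataset, retained="col")
        dev, beta, sigma2, taus = dense_fit_oracle(
            tiny_dataset.records, "nested", retained="col"
        )
        assert fit.deviance == pytest.approx(dev, abs=1e-4)
        got = np.array([v for v, _ in fit.fixed.values()])
        assert np.allclose(got, beta, rtol=1e-4, atol=1e-5)
        assert fit.variance["tau_col"] == pytest.approx(taus[0], abs=1e-4)


class TestFitContracts:
    def test_parameter_counts_and_flags(self, tiny_dataset):
        fc = fit_crossed_ml(tiny_dataset)
        fn = fit_nested_ml(tiny_dataset)
        assert (fc.q, fn.q) == (7, 6)
        assert fc.n_level1 == fn.n_level1 == tiny_dataset.n
        assert fc.converged and fn.converged
        assert all(se > 0 for _, se in fc.fixed.values())
        assert all(v >= 0 for v in fc.variance.values())
        assert "tau_row" not in fn.variance

    @pytest.mark.parametrize("rep", range(4))
    def test_nested_deviance_dominates_crossed(self, rep):
        ds, *_ = make_dataset(
            mc=0.5, f=2, rho=0.4, groups=20, size=15.0, iucc=0.15, seed=21, rep=rep
        )
        fc = fit_crossed_ml(ds)
        fn = fit_nested_ml(ds)
        assert fn.deviance >= fc.deviance - 1e-6

    def test_parameter_recovery_under_truth(self):
        # MC 0.5, IUCC 0.15 (tau = 0.2143), J = K = 50, sizes ~ 40
        est_fixed, est_var = [], []
        for rep in range(5):
            ds, cond, params = make_dataset(
                mc=0.5, f=4, groups=50, size=40.0, iucc=0.15, seed=31, rep=rep
            )
            fit = fit_crossed_ml(ds)
            est_fixed.append([v for v, _ in fit.fixed.values()])
            se = [s for _, s in fit.fixed.values()]
            truth = [100.0, 0.5, 0.5, 0.5]
            for e, s, t in zip(est_fixed[-1], se, truth):
                assert abs(e - t) < 3 * s
            est_var.append(
                [fit.variance["sigma2_e"], fit.variance["tau_col"],
                 fit.variance["tau_row"]]
            )
        mean_var = np.mean(est_var, axis=0)
        assert np.allclose(mean_var, [1.0, 0.2143, 0.2143], rtol=0.25)

    def test_boundary_truth_yields_near_zero_taus(self):
        small = 0
        for rep in range(10):
            ds, *_ = make_dataset(
                mc=0.5, f=2, groups=30, size=20.0, iucc=0.0, seed=41, rep=rep
            )
            fit = fit_crossed_ml(ds)
            if fit.variance["tau_col"] < 0.01 and fit.variance["tau_row"] < 0.01:
                small += 1
        assert small >= 7

    def test_empty_row_levels_are_dropped(self):
        # with f = 1 many row groups receive nobody
        ds, *_ = make_dataset(mc=0.5, f=1, groups=12, size=10.0, seed=5)
        used = ds.records["k"].nunique()
        assert used < 12
        fit = fit_crossed_ml(ds)
        assert fit.converged
        assert fit.n_groups_used["row"] == used

    def test_model_se_calibrated_for_x_slope(self):
        # SE bias of the level-1 predictor should be within |0.10|
        for cond_kw in (
            dict(mc=0.5, f=2, groups=30, size=20.0, iucc=0.15),
            dict(mc=0.2, f=6, groups=50, size=20.0, iucc=0.05),
        ):
            est, ses = [], []
            for rep in range(300):
                ds, *_ = make_dataset(seed=51, rep=rep, **cond_kw)
                fit = fit_crossed_ml(ds)
                est.append(fit.fixed["slope_x"][0])
                ses.append(fit.fixed["slope_x"][1])
            ratio = np.mean(ses) / np.std(est, ddof=1)
            assert abs(ratio - 1) < 0.10


class TestAgainstLme4:
    @pytest.fixture(scope="class")
    def medium_dataset_csv(self, tmp_path_factory):
        ds, *_ = make_dataset(
            mc=0.5, f=2, rho=0.0, groups=12, size=12.0, iucc=0.15, seed=61
        )
        path = tmp_path_factory.mktemp("lme4") / "data.csv"
        ds.records.to_csv(path, index=False)
        return ds, path

    def _run_lmer(self, path, formula):
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{path}")
        d$j <- factor(d$j); d$k <- factor(d$k)
        m <- lmer({formula}, data = d, REML = FALSE)
        vc <- as.data.frame(VarCorr(m))
        out <- list(
          deviance = deviance(m),
          fixef = as.list(fixef(m)),
          se = as.list(sqrt(diag(as.matrix(vcov(m))))),
          vc = setNames(as.list(vc$vcov), vc$grp)
        )
        cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
        """
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        return json.loads(res.stdout)

    def test_crossed_fit_agrees_with_lmer(self, medium_dataset_csv):
        ds, path = medium_dataset_csv
        ref = self._run_lmer(path, "y ~ x + w + z + (1 | j) + (1 | k)")
        fit = fit_crossed_ml(ds)
        assert fit.deviance == pytest.approx(ref["deviance"], abs=1e-3)
        for ours, theirs in [
            ("intercept", "(Intercept)"), ("slope_x", "x"),
            ("slope_w", "w"), ("slope_z", "z"),
        ]:
            assert fit.fixed[ours][0] == pytest.approx(
                ref["fixef"][theirs], rel=1e-4, abs=1e-6
            )
            assert fit.fixed[ours][1] == pytest.approx(
                ref["se"][theirs], rel=1e-3
            )
        assert fit.variance["tau_col"] == pytest.approx(ref["vc"]["j"], abs=1e-4)
        assert fit.variance["tau_row"] == pytest.approx(ref["vc"]["k"], abs=1e-4)
        assert fit.variance["sigma2_e"] == pytest.approx(
            ref["vc"]["Residual"], abs=1e-4
        )

    def test_nested_fit_agrees_with_lmer(self, medium_dataset_csv):
        ds, path = medium_dataset_csv
        ref = self._run_lmer(path, "y ~ x + w + z + (1 | j)")
        fit = fit_nested_ml(ds, retained="col")
        assert fit.deviance == pytest.approx(ref["deviance"], abs=1e-3)
        assert fit.variance["tau_col"] == pytest.approx(ref["vc"]["j"], abs=1e-4)
        assert fit.fixed["slope_z"][1] == pytest.approx(ref["se"]["z"], rel=1e-3)
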