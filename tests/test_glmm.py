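import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy import integrate, special

from listlength.glmm import DesignMatrix, LogisticGLMM, aicc, standardize

from conftest import make_glmm_data


# ----------------------------------------------------------------- oracles


def naive_marginal_loglike(model, beta, sd, n_nodes=201):
    """Brute-force marginal log-likelihood: non-adaptive Gauss-Hermite
    quadrature centred at zero, per group (independent of the adaptive
    implementation under test)."""
    z, w = hermgauss(n_nodes)
    X = np.column_stack([np.ones(model.nobs), model.exog])
    eta0 = X @ np.asarray(beta, dtype=float)
    total = 0.0
    for g in range(model.n_groups):
        rows = model._codes == g
        b = np.sqrt(2.0) * sd * z
        eta = eta0[rows][:, None] + b[None, :]
        cond = (model.endog[rows][:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        total += special.logsumexp(cond + np.log(w) - 0.5 * np.log(np.pi))
    return total


def irls_logistic(y, X, tol=1e-12, maxiter=200):
    """Independent iteratively-reweighted least-squares logistic fit."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(maxiter):
        eta = X1 @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        zvec = eta + (y - mu) / np.clip(w, 1e-12, None)
        WX = X1 * w[:, None]
        beta_new = np.linalg.solve(X1.T @ WX, WX.T @ zvec)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


# ----------------------------------------------------------------- standardize


class TestStandardize:
    def test_forced_arithmetic(self):
        out, consts = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].tolist() == [-1.0, 0.0, 1.0]
        assert consts["x"] == (2.0, 1.0)  # SD with the n-1 denominator

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        out, _ = standardize(pd.DataFrame({"x": x}))
        assert np.allclose(out["x"], x, atol=1e-12)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="effortless"):
            standardize(pd.DataFrame({"effortless": [2.0, 2.0, 2.0]}))

    def test_columns_have_unit_moments(self, rng):
        df = pd.DataFrame(rng.normal(2, 7, size=(40, 3)), columns=list("abc"))
        out, _ = standardize(df)
        assert np.allclose(out.mean(), 0.0, atol=1e-8)
        assert np.allclose(out.std(ddof=1), 1.0, atol=1e-8)


# ----------------------------------------------------------------- likelihood


class TestMarginalLoglike:
    def test_single_row_null_model_is_log_half(self):
        model = LogisticGLMM([1.0], np.zeros((1, 1)), ["c"])
        assert model.loglike(np.zeros(2), 0.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_sd_zero_reduces_to_plain_bernoulli(self, toy_glmm):
        beta = np.array([0.1, 0.5, -0.3])
        X = np.column_stack([np.ones(toy_glmm.nobs), toy_glmm.exog])
        eta = X @ beta
        plain = float((toy_glmm.endog * eta - np.logaddexp(0.0, eta)).sum())
        assert toy_glmm.loglike(beta, 0.0) == pytest.approx(plain, abs=1e-12)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_matches_bruteforce_quadrature(self, seed):
        y, X, groups = make_glmm_data(seed, n=150, n_groups=seed - 6)
        model = LogisticGLMM(y, X, groups)
        rng = np.random.default_rng(seed)
        beta = rng.normal(scale=0.5, size=3)
        sd = rng.uniform(0.3, 1.0)
        ours = model.loglike(beta, sd, n_nodes=15)
        oracle = naive_marginal_loglike(model, beta, sd)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_matches_scipy_quad(self):
        """Second, fully independent integration oracle on one dataset."""
        y, X, groups = make_glmm_data(21, n=60, n_groups=4)
        model = LogisticGLMM(y, X, groups)
        beta, sd = np.array([0.2, 0.6, -0.4]), 0.7
        eta0 = beta[0] + X @ beta[1:]
        total = 0.0
        for g in np.unique(groups):
            rows = groups == g

            def integrand(b):
                eta = eta0[rows] + b
                ll = (y[rows] * eta - np.logaddexp(0.0, eta)).sum()
                return np.exp(ll) * np.exp(-0.5 * (b / sd) ** 2) / (sd * np.sqrt(2 * np.pi))

            val, _ = integrate.quad(integrand, -8 * sd, 8 * sd, epsabs=1e-13, epsrel=1e-12)
            total += np.log(val)
        assert model.loglike(beta, sd, n_nodes=15) == pytest.approx(total, abs=1e-6)

    def test_laplace_close_to_quadrature(self):
        """Laplace (1 node) tracks 15-node AGQ on balanced data with large
        groups, where the per-group Laplace error (O(1/group size)) is small."""
        y, X, _ = make_glmm_data(7, n=2000, n_groups=2, sd=0.5)
        groups = np.arange(2000) % 2  # two balanced groups of 1000 rows
        model = LogisticGLMM(y, X, groups)
        beta = np.array([0.2, 0.8, -0.5])
        laplace = model.loglike(beta, 0.5, n_nodes=1)
        agq = model.loglike(beta, 0.5, n_nodes=15)
        assert laplace == pytest.approx(agq, abs=1e-3)

    def test_node_count_converges_to_oracle(self, toy_glmm):
        beta = np.array([0.2, 0.8, -0.5])
        oracle = naive_marginal_loglike(toy_glmm, beta, 0.7)
        errors = [
            abs(toy_glmm.loglike(beta, 0.7, n_nodes=k) - oracle) for k in (1, 3, 7, 15)
        ]
        for lo, hi in zip(errors[1:], errors[:-1]):
            assert lo <= hi + 1e-10
        assert errors[-1] < 1e-8

    def test_group_relabeling_invariance(self, rng):
        y, X, groups = make_glmm_data(31, n=100, n_groups=6)
        model = LogisticGLMM(y, X, groups)
        relabel = {g: f"county-{9 - g}" for g in range(6)}
        model2 = LogisticGLMM(y, X, np.array([relabel[g] for g in groups]))
        beta = np.array([0.1, 0.4, -0.2])
        assert model.loglike(beta, 0.6) == pytest.approx(model2.loglike(beta, 0.6), abs=1e-10)

    def test_nonfinite_predictor_rejected(self, toy_glmm):
        with pytest.raises(ValueError, match="linear predictor"):
            toy_glmm.loglike(np.array([np.inf, 0.0, 0.0]), 0.5)


# ----------------------------------------------------------------- fitting


class TestFit:
    def test_sd_fixed_zero_matches_irls(self):
        y, X, groups = make_glmm_data(41, n=200, n_groups=5, sd=0.0)
        res = LogisticGLMM(y, X, groups).fit(fix_re_sd=0.0)
        oracle = irls_logistic(y, X)
        assert np.max(np.abs(res.fe_params - oracle)) < 1e-6
        assert res.re_sd == 0.0 and res.converged

    def test_row_duplication_scales_information(self):
        """With the variance fixed the likelihood doubles under duplication:
        identical estimates, SEs shrink by sqrt(2)."""
        y, X, groups = make_glmm_data(43, n=150, n_groups=5)
        res1 = LogisticGLMM(y, X, groups).fit(fix_re_sd=0.0)
        res2 = LogisticGLMM(
            np.tile(y, 2), np.tile(X, (2, 1)), np.tile(groups, 2)
        ).fit(fix_re_sd=0.0)
        assert np.allclose(res1.fe_params, res2.fe_params, atol=1e-8)
        assert np.allclose(res1.bse / res2.bse, np.sqrt(2.0), atol=1e-6)

    def test_recovers_truth_within_sampling_error(self, small_simulation):
        config, records, truth = small_simulation
        species = config.species_names[0]
        res = LogisticGLMM.from_design(truth.design_matrix(species)).fit()
        assert res.converged
        true = truth.coefficients.loc[species]
        zscores = (res.fe_params - true.to_numpy()) / res.bse
        assert np.all(np.abs(zscores) < 4.0)

    def test_boundary_variance_reported_as_zero(self):
        y, X, groups = make_glmm_data(47, n=250, n_groups=5, sd=0.0)
        res = LogisticGLMM(y, X, groups).fit()
        assert res.re_sd == 0.0
        assert np.isfinite(res.llf)

    def test_nonconvergence_is_flagged_not_silent(self):
        y, X, groups = make_glmm_data(49, n=80, n_groups=4)
        res = LogisticGLMM(y, X, groups).fit(maxiter=1)
        assert not res.converged

    def test_results_table_round_trip(self, toy_glmm):
        res = toy_glmm.fit(n_nodes=7)
        frame = res.to_frame()
        assert list(frame["term"]) == toy_glmm.param_names
        assert frame["aicc"].iloc[0] == pytest.approx(res.aicc)
        assert "logLik" in res.summary() or "logLik" in frame.columns

    def test_statsmodels_glm_cross_check(self):
        """sd=0 path against the statsmodels GLM fit (independent oracle)."""
        import statsmodels.api as sm

        y, X, groups = make_glmm_data(53, n=180, n_groups=6)
        res = LogisticGLMM(y, X, groups).fit(fix_re_sd=0.0)
        sm_res = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        assert np.allclose(res.fe_params, sm_res.params, atol=1e-6)
        assert np.allclose(res.bse, sm_res.bse, atol=1e-5)


class TestAicc:
    def test_closed_form(self):
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_limits(self):
        assert aicc(0.0, 0, 10) == 0.0
        big_n = aicc(-10.0, 3, 10**9)
        assert big_n == pytest.approx(-2 * -10.0 + 2 * 3, abs=1e-6)

    def test_undefined_small_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestDesignMatrix:
    def test_rejects_non_binary_response(self):
        with pytest.raises(ValueError):
            DesignMatrix(
                endog=np.array([0.0, 2.0]), exog=np.zeros((2, 1)),
                groups=np.array([0, 1]), exog_names=["x"],
            )

    def test_rejects_misaligned_groups(self):
        with pytest.raises(ValueError):
            DesignMatrix(
                endog=np.array([0.0, 1.0]), exog=np.zeros((2, 1)),
                groups=np.array([0]), exog_names=["x"],
            )


class TestLme4CrossCheck:
    def test_agrees_with_glmer_agq(self, tmp_path):
        """Independent mixed-model oracle: R lme4::glmer with 15-node AGQ."""
        import shutil
        import subprocess

        assert shutil.which("Rscript"), "Rscript expected on PATH"
        y, X, groups = make_glmm_data(61, n=200, n_groups=8, sd=0.8)
        csv = tmp_path / "toy.csv"
        pd.DataFrame(
            {"y": y.astype(int), "x1": X[:, 0], "x2": X[:, 1], "g": groups}
        ).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial, nAGQ=15)\n"
            "cat(sprintf('%.10f\\n', as.numeric(logLik(m))))\n"
            "cat(sprintf('%.10f\\n', fixef(m)))\n"
            "cat(sprintf('%.10f\\n', sqrt(as.numeric(VarCorr(m)$g))))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        llf_r, b0, b1, b2, sd_r = map(float, out)
        res = LogisticGLMM(y, X, groups).fit(n_nodes=15)
        assert res.llf == pytest.approx(llf_r, abs=1e-4)
        assert np.allclose(res.fe_params, [b0, b1, b2], atol=1e-3)
        assert res.re_sd == pytest.approx(sd_r, abs=1e-3)
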