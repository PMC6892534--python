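import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import linalg
from scipy.stats import norm

import collidersim as cs
from collidersim import lmm

TIMES = np.array([-1.0, 0.0, 1.0])


class TestSubjectCovariance:
    def test_pure_residual_is_identity(self):
        vc = lmm.VarComp(0, 0, 0, 1.0, 0.0)
        np.testing.assert_allclose(lmm.subject_covariance(vc, TIMES), np.eye(3))

    def test_pure_random_intercept_is_all_ones(self):
        vc = lmm.VarComp(1.0, 0, 0, 0.0, 0.0)
        np.testing.assert_allclose(lmm.subject_covariance(vc, TIMES), np.ones((3, 3)))

    def test_ar1_decay_by_lag(self):
        vc = lmm.VarComp(0, 0, 0, 1.0, 0.5)
        V = lmm.subject_covariance(vc, TIMES)
        np.testing.assert_allclose(V[0], [1.0, 0.5, 0.25])

    @given(
        su0=st.floats(0.01, 5.0),
        su1=st.floats(0.01, 5.0),
        r01=st.floats(-0.95, 0.95),
        se=st.floats(0.01, 5.0),
        rho=st.floats(-0.9, 0.9),
    )
    def test_always_positive_definite(self, su0, su1, r01, se, rho):
        vc = lmm.VarComp(su0, su1, r01 * np.sqrt(su0 * su1), se, rho)
        linalg.cholesky(lmm.subject_covariance(vc, TIMES))  # must not raise

    def test_invalid_varcomp_rejected(self):
        with pytest.raises(lmm.LMMDomainError):
            lmm.VarComp(1.0, 1.0, 2.0, 1.0, 0.0)  # covariance beyond bound
        with pytest.raises(lmm.LMMDomainError):
            lmm.VarComp(1.0, 1.0, 0.0, 1.0, 1.0)  # |rho| = 1


THETAS = [
    np.array([0.2, -0.5, 0.3, 0.1, 0.2]),
    np.array([-1.0, 0.5, -0.8, 0.4, -0.3]),
    np.array([0.0, 0.0, 0.0, 0.0, 0.0]),
]


class TestLikelihood:
    @pytest.mark.parametrize("estimation", ["ML", "REML"])
    @pytest.mark.parametrize("theta", THETAS, ids=["t0", "t1", "t2"])
    def test_matches_dense_multivariate_normal_oracle(self, small_long, estimation, theta):
        # block/profiled computation vs one dense stacked-covariance density
        spec = lmm.LMMSpec(estimation=estimation)
        fast = lmm.negative_log_likelihood(theta, small_long, spec)
        dense = lmm.dense_negative_log_likelihood(theta, small_long, spec)
        assert fast == pytest.approx(dense, abs=1e-8)

    @pytest.mark.parametrize("estimation", ["ML", "REML"])
    def test_outcome_covariate_design_matches_dense_oracle(self, small_long, estimation):
        spec = lmm.LMMSpec(
            fixed_terms=lmm.FIXED_TERMS_OUTCOME_COVARIATE, estimation=estimation
        )
        if small_long["diabetes"].nunique() < 2:  # ensure both groups present
            small_long = small_long.copy()
            small_long.loc[small_long["id"] == small_long["id"].iloc[0], "diabetes"] = 1
        theta = THETAS[0]
        fast = lmm.negative_log_likelihood(theta, small_long, spec)
        dense = lmm.dense_negative_log_likelihood(theta, small_long, spec)
        assert fast == pytest.approx(dense, abs=1e-8)

    def test_reduces_to_iid_ols_likelihood(self, small_long):
        # no random effects, no autocorrelation -> ordinary Gaussian density
        sigma2 = 1.7
        vc = lmm.VarComp(0.0, 0.0, 0.0, sigma2, 0.0)
        spec = lmm.LMMSpec(estimation="ML")
        stats = lmm._prepare(small_long, spec)
        nll, beta, _ = lmm._nll_core(vc, stats, spec)
        X = np.column_stack(
            [np.ones(len(small_long)), small_long.sort_values(["id", "time_centered"])["time_centered"]]
        )
        y = small_long.sort_values(["id", "time_centered"])["weight"].to_numpy()
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, b_ols, atol=1e-10)
        ll_ols = norm.logpdf(y, X @ b_ols, np.sqrt(sigma2)).sum()
        assert nll == pytest.approx(-ll_ols, abs=1e-8)

    def test_invariant_to_subject_ordering(self, small_long):
        spec = lmm.LMMSpec()
        shuffled = small_long.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = lmm.negative_log_likelihood(THETAS[0], small_long, spec)
        b = lmm.negative_log_likelihood(THETAS[0], shuffled, spec)
        assert a == pytest.approx(b, abs=1e-10)

    def test_profiled_beta_equals_closed_form_gls(self, small_long):
        vc = lmm.VarComp(0.5, 0.0, 0.0, 1.2, 0.0)
        spec = lmm.LMMSpec()
        stats = lmm._prepare(small_long, spec)
        _, beta, _ = lmm._nll_core(vc, stats, spec)
        V = lmm.subject_covariance(vc, TIMES)
        d = small_long.sort_values(["id", "time_centered"])
        Vd = linalg.block_diag(*[V] * d["id"].nunique())
        X = np.column_stack([np.ones(len(d)), d["time_centered"]])
        y = d["weight"].to_numpy()
        W = np.linalg.inv(Vd)
        b_gls = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        np.testing.assert_allclose(beta, b_gls, atol=1e-10)


def _simulate_from_varcomp(vc, m, beta=(4.0, 4.0), seed=0):
    rng = np.random.default_rng(seed)
    V = lmm.subject_covariance(vc, TIMES)
    mu = beta[0] + beta[1] * TIMES
    Y = rng.multivariate_normal(mu, V, size=m, method="cholesky")
    return pd.DataFrame(
        {
            "id": np.repeat(np.arange(1, m + 1), 3),
            "time_centered": np.tile(TIMES, m),
            "weight": Y.ravel(),
        }
    )


class TestFitting:
    def test_recovers_iid_truth(self):
        # generated with zero random-effect variances and no autocorrelation
        truth = lmm.VarComp(0.0, 0.0, 0.0, 1.0, 0.0)
        data = _simulate_from_varcomp(truth, 5000, seed=5)
        fit = lmm.fit_lmm(data, lmm.LMMSpec(estimation="ML"))
        assert fit.converged
        N = 3 * 5000
        se_var = np.sqrt(2.0 / N)  # MC standard error of a variance estimate
        assert fit.varcomp.sigma_u0_sq + fit.varcomp.sigma_e_sq == pytest.approx(
            1.0, abs=3 * se_var + 0.02
        )
        assert fit.varcomp.sigma_u0_sq < 0.05
        assert fit.varcomp.sigma_u1_sq < 0.05
        assert abs(fit.varcomp.rho) < 0.1
        np.testing.assert_allclose(
            [fit.fixed_effects["intercept"], fit.fixed_effects["time"]],
            [4.0, 4.0],
            atol=3 * 1.0 / np.sqrt(5000),
        )

    def test_recovers_full_varcomp(self):
        truth = lmm.VarComp(1.0, 0.5, 0.2, 0.8, 0.3)
        data = _simulate_from_varcomp(truth, 8000, seed=6)
        fit = lmm.fit_lmm(data, lmm.LMMSpec())
        assert fit.converged
        # marginal covariance is what the data identify; compare V entrywise
        V_hat = lmm.subject_covariance(fit.varcomp, TIMES)
        V_true = lmm.subject_covariance(truth, TIMES)
        np.testing.assert_allclose(V_hat, V_true, atol=3 * 4.0 / np.sqrt(8000))

    def test_reml_and_ml_agree_at_large_n(self, joint_gaussians):
        cohort = cs.simulate_cohort(joint_gaussians["A"], 5000, 77)
        long = cs.to_long(cohort)[["id", "time_centered", "weight"]]
        reml = lmm.fit_lmm(long, lmm.LMMSpec(estimation="REML"))
        ml = lmm.fit_lmm(long, lmm.LMMSpec(estimation="ML"))
        for term in ("intercept", "time"):
            assert reml.fixed_effects[term] == pytest.approx(
                ml.fixed_effects[term], rel=0.01
            )
        V_reml = lmm.subject_covariance(reml.varcomp, TIMES)
        V_ml = lmm.subject_covariance(ml.varcomp, TIMES)
        np.testing.assert_allclose(V_reml, V_ml, rtol=0.01)

    def test_unbalanced_design_rejected(self, small_long):
        with pytest.raises(ValueError, match="balanced"):
            lmm.fit_lmm(small_long.iloc[1:], lmm.LMMSpec())


class TestRandomSlopes:
    def test_matches_dense_conditional_mean_oracle(self, small_long):
        fit = lmm.fit_lmm(small_long[["id", "time_centered", "weight"]], lmm.LMMSpec())
        vc, fe = fit.varcomp, fit.fixed_effects
        V = lmm.subject_covariance(vc, TIMES)
        Z = np.column_stack([np.ones(3), TIMES])
        K = vc.G @ Z.T @ np.linalg.inv(V)
        d = small_long.sort_values(["id", "time_centered"])
        for sid, sub in d.groupby("id"):
            r = sub["weight"].to_numpy() - (fe["intercept"] + fe["time"] * TIMES)
            u = K @ r
            assert fit.subject_slopes.loc[sid] == pytest.approx(fe["time"] + u[1], abs=1e-8)
            assert fit.subject_intercepts.loc[sid] == pytest.approx(
                fe["intercept"] + u[0], abs=1e-8
            )

    def test_mean_slope_equals_fixed_slope(self, joint_gaussians):
        cohort = cs.simulate_cohort(joint_gaussians["B"], 400, 8)
        long = cs.to_long(cohort)[["id", "time_centered", "weight"]]
        fit = lmm.fit_lmm(long, lmm.LMMSpec())
        # GLS normal equations force the EB deviations to sum to zero exactly
        assert cs.random_slopes(fit).mean() == pytest.approx(
            fit.fixed_effects["time"], abs=1e-8
        )

    def test_nonconverged_fit_refuses_extraction(self, small_long):
        fit = lmm.fit_lmm(small_long[["id", "time_centered", "weight"]], lmm.LMMSpec())
        fit.converged = False
        with pytest.raises(RuntimeError):
            cs.random_slopes(fit)


NLME_SCRIPT = textwrap.dedent(
    """
    library(nlme)
    args <- commandArgs(trailingOnly = TRUE)
    d <- read.csv(args[1])
    m <- lme(weight ~ time_centered, random = ~ time_centered | id,
             correlation = corAR1(form = ~ 1 | id), data = d, method = "REML",
             control = lmeControl(maxIter = 200, msMaxIter = 200, opt = "optim"))
    fe <- fixef(m)
    G <- getVarCov(m)
    rho <- as.numeric(coef(m$modelStruct$corStruct, unconstrained = FALSE))
    cat(sprintf(paste0('{"intercept": %.10f, "time": %.10f, "g11": %.10f, ',
        '"g12": %.10f, "g22": %.10f, "sigma": %.10f, "rho": %.10f, "logLik": %.10f}'),
        fe[1], fe[2], G[1, 1], G[1, 2], G[2, 2], m$sigma, rho, as.numeric(logLik(m))))
    """
)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_agrees_with_nlme_reference(tmp_path, joint_gaussians):
    """Cross-validation against the standard mixed-model implementation:
    same model fitted by nlme::lme must give the same fixed effects,
    residual structure and (up to the flat intercept-slope ridge) the same
    restricted likelihood."""
    cohort = cs.simulate_cohort(joint_gaussians["A"], 300, np.random.SeedSequence([42]))
    long = cs.to_long(cohort)[["id", "time_centered", "weight"]]
    csv = tmp_path / "long.csv"
    long.to_csv(csv, index=False)
    rfile = tmp_path / "fit.R"
    rfile.write_text(NLME_SCRIPT)
    out = subprocess.run(
        ["Rscript", str(rfile), str(csv)], capture_output=True, text=True, check=True
    )
    ref = json.loads(out.stdout.strip().splitlines()[-1])

    fit = lmm.fit_lmm(long, lmm.LMMSpec(estimation="REML"))
    assert fit.converged
    assert fit.fixed_effects["intercept"] == pytest.approx(ref["intercept"], abs=1e-4)
    assert fit.fixed_effects["time"] == pytest.approx(ref["time"], abs=1e-4)
    assert fit.varcomp.rho == pytest.approx(ref["rho"], abs=0.02)
    assert np.sqrt(fit.varcomp.sigma_e_sq) == pytest.approx(ref["sigma"], rel=0.02)
    # same objective, same constant convention: our optimum can only be at
    # least as good, and must be close
    assert fit.loglik >= ref["logLik"] - 1e-6
    assert fit.loglik == pytest.approx(ref["logLik"], abs=0.5)
    # implied marginal covariance agrees even where the G-split is flat
    vc_ref = lmm.VarComp(ref["g11"], ref["g22"], ref["g12"], ref["sigma"] ** 2, ref["rho"])
    np.testing.assert_allclose(
        lmm.subject_covariance(fit.varcomp, TIMES),
        lmm.subject_covariance(vc_ref, TIMES),
        rtol=0.05,
        atol=0.05,
    )
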