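"""The three trajectory-analysis procedures compared in the study.

Each consumes one simulated cohort and returns a :class:`MethodResult`:

* ``zscore_profiles`` — mean weight z-scores per age within diabetes groups
  (a method that conditions on the outcome by construction);
* ``outcome_covariate_model`` — mixed model of weight on age with diabetes
  and an age-by-diabetes interaction as covariates (conditions on the
  outcome through the fixed effects);
* ``two_step`` — mixed model of weight on age fitted agnostic to the
  outcome, followed by logistic regression of diabetes on the extracted
  per-person growth rate (per 0.1 kg/yr) adjusting for birthweight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import lmm, simulate

GROWTH_RATE_UNIT = 0.1  # kg/yr; odds ratios are reported per this increment


@dataclass
class ZScoreProfile:
    """Mean weight z-score at each age within outcome groups.

    ``means`` is indexed by age in years (0, 1, 2) with columns
    ``diabetic`` / ``non_diabetic``; z-scores use the within-cohort,
    per-age sample mean and SD (ddof=1).
    """

    means: pd.DataFrame
    prevalence: float

    def separation(self) -> pd.Series:
        """diabetic minus non-diabetic mean z-score per age."""
        return self.means["diabetic"] - self.means["non_diabetic"]


@dataclass
class MethodResult:
    method: str  # zscore | outcome_covariate | two_step
    payload: dict = field(default_factory=dict)
    profile: Optional[ZScoreProfile] = None
    converged: bool = True


class DegenerateInputError(ValueError):
    pass


def zscore_profiles(cohort: pd.DataFrame) -> ZScoreProfile:
    """Standardise weight per age and average within outcome groups."""
    diab = cohort["diabetes"].to_numpy()
    if diab.sum() == 0 or diab.sum() == len(diab):
        raise DegenerateInputError("both outcome groups must be non-empty")
    rows = {}
    for age, col in enumerate(simulate.WEIGHT_LABELS):
        w = cohort[col].to_numpy(dtype=float)
        sd = w.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"zero SD at age {age}")
        z = (w - w.mean()) / sd
        rows[age] = {
            "diabetic": z[diab == 1].mean(),
            "non_diabetic": z[diab == 0].mean(),
        }
    means = pd.DataFrame.from_dict(rows, orient="index")
    means.index.name = "age"
    return ZScoreProfile(means=means, prevalence=float(diab.mean()))


def outcome_covariate_model(
    long: pd.DataFrame, spec: lmm.LMMSpec | None = None
) -> MethodResult:
    """Mixed model of weight with the outcome entering as a covariate."""
    if spec is None:
        spec = lmm.LMMSpec(fixed_terms=lmm.FIXED_TERMS_OUTCOME_COVARIATE)
    elif not spec.uses_outcome:
        raise ValueError("spec must include diabetes terms")
    fit = lmm.fit_lmm(long, spec)
    payload = dict(fit.fixed_effects)
    payload.update(
        intercept_variance=fit.varcomp.sigma_u0_sq,
        slope_variance=fit.varcomp.sigma_u1_sq,
        intercept_slope_covariance=fit.varcomp.sigma_u01,
        intercept_slope_correlation=fit.varcomp.corr_u01,
        residual_variance=fit.varcomp.sigma_e_sq,
        autocorrelation=fit.varcomp.rho,
        loglik=fit.loglik,
    )
    return MethodResult("outcome_covariate", payload=payload, converged=fit.converged)


def fit_logistic(y, X) -> tuple[dict[str, float], bool]:
    """Maximum-likelihood logistic regression.

    ``X`` is a DataFrame of regressors (no constant column; one is added).
    Returns (coefficient map, converged); perfect separation or a singular
    design is reported as non-convergence rather than raising.
    """
    import warnings

    X = sm.add_constant(pd.DataFrame(X), has_constant="add")
    y = np.asarray(y, dtype=float)
    try:
        with warnings.catch_warnings():
            # separation is reported through the converged flag instead
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter(
                "ignore", sm.tools.sm_exceptions.PerfectSeparationWarning
            )
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        coefs = {k: float(v) for k, v in res.params.items()}
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return {}, False
    if not all(np.isfinite(v) for v in coefs.values()):
        converged = False
    return coefs, converged


def exposure_model(long: pd.DataFrame, estimation: str = "REML") -> lmm.LMMFit:
    """Step 1: growth model fitted agnostic to the outcome.

    Receives only id/time/weight — the diabetes column is dropped before the
    fit so the exposure model cannot condition on the outcome.
    """
    cols = ["id", "time_centered", "weight"]
    spec = lmm.LMMSpec(fixed_terms=lmm.FIXED_TERMS_EXPOSURE, estimation=estimation)
    return lmm.fit_lmm(long[cols].copy(), spec)


def two_step(cohort: pd.DataFrame, estimation: str = "REML") -> MethodResult:
    """Growth-rate extraction followed by outcome regression.

    Step 1 fits the exposure-only mixed model and records each person's
    empirical-Bayes growth rate.  Step 2 regresses diabetes on that growth
    rate (rescaled to 0.1 kg/yr increments) and birthweight; the payload
    carries exponentiated coefficients (odds ratios).
    """
    long = simulate.to_long(cohort)
    step1 = exposure_model(long, estimation=estimation)
    if not step1.converged:
        return MethodResult("two_step", converged=False)
    slopes = lmm.random_slopes(step1)

    wide = cohort.set_index("id")
    X = pd.DataFrame(
        {
            "growth_rate": slopes.loc[wide.index] / GROWTH_RATE_UNIT,
            "weight_0": wide["weight_0"],
        },
        index=wide.index,
    )
    coefs, ok = fit_logistic(wide["diabetes"], X)
    payload = {}
    if ok:
        payload = {
            "or_growth_rate": float(np.exp(coefs["growth_rate"])),
            "or_weight_0": float(np.exp(coefs["weight_0"])),
            "constant": float(np.exp(coefs["const"])),
            "growth_rate_fixed_effect": step1.fixed_effects["time"],
        }
    return MethodResult("two_step", payload=payload, converged=ok)
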