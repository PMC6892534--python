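"""Linear mixed models with random intercept+slope and AR(1) residuals.

The model for weight of individual *j* at occasion *i* is

    weight_ij = x_ij' beta + u0j + u1j * t_ij + e_ij,

with (u0j, u1j) bivariate normal with covariance G = [[s_u0^2, s_u01],
[s_u01, s_u1^2]] and within-subject errors e_j normal with covariance
``sigma_e^2 * R(rho)``, ``R_st = rho^|s-t|`` over consecutive measurement
occasions.  The marginal covariance of a subject's T observations is

    V = Z G Z' + sigma_e^2 R(rho),      Z = [1, t].

Estimation maximises the marginal Gaussian likelihood directly: the fixed
effects are profiled out by generalised least squares at every value of the
variance parameters, which are optimised on an unconstrained scale (log
variances; Fisher-z for the intercept-slope correlation and for rho).  REML
(the default) adds the usual log-determinant adjustment for the profiled
fixed effects.  Individual growth rates are the empirical-Bayes (BLUP)
conditional means ``gamma_1 + u1j``.

All designs here are balanced — every subject is measured at the same
centred times — so each likelihood evaluation needs only per-group
sufficient statistics (counts, sums and cross-product matrices), independent
of the number of subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

LOG2PI = np.log(2.0 * np.pi)

FIXED_TERMS_EXPOSURE = ("intercept", "time")
FIXED_TERMS_OUTCOME_COVARIATE = ("intercept", "time", "diabetes", "time:diabetes")


class LMMDomainError(ValueError):
    """Invalid variance components."""


@dataclass(frozen=True)
class LMMSpec:
    """Model specification.

    ``fixed_terms`` is an ordered subset of (intercept, time, diabetes,
    time:diabetes); the random part is always intercept + time; ``ar1``
    toggles the autocorrelated residual structure (all study models use it).
    """

    fixed_terms: tuple[str, ...] = FIXED_TERMS_EXPOSURE
    ar1: bool = True
    estimation: str = "REML"

    def __post_init__(self):
        allowed = {"intercept", "time", "diabetes", "time:diabetes"}
        unknown = set(self.fixed_terms) - allowed
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be REML or ML")

    @property
    def uses_outcome(self) -> bool:
        return any("diabetes" in t for t in self.fixed_terms)


@dataclass(frozen=True)
class VarComp:
    """Variance components of the mixed model."""

    sigma_u0_sq: float  # random-intercept variance, kg^2
    sigma_u1_sq: float  # random-slope variance, (kg/yr)^2
    sigma_u01: float    # intercept-slope covariance
    sigma_e_sq: float   # residual variance, kg^2
    rho: float          # AR(1) correlation between consecutive occasions

    def __post_init__(self):
        if self.sigma_u0_sq < 0 or self.sigma_u1_sq < 0 or self.sigma_e_sq < 0:
            raise LMMDomainError("variances must be non-negative")
        bound = np.sqrt(self.sigma_u0_sq * self.sigma_u1_sq)
        if abs(self.sigma_u01) > bound + 1e-12:
            raise LMMDomainError("|sigma_u01| exceeds Cauchy-Schwarz bound")
        if not -1.0 < self.rho < 1.0:
            raise LMMDomainError("rho must lie in (-1, 1)")

    @property
    def G(self) -> np.ndarray:
        return np.array(
            [
                [self.sigma_u0_sq, self.sigma_u01],
                [self.sigma_u01, self.sigma_u1_sq],
            ]
        )

    @property
    def corr_u01(self) -> float:
        denom = np.sqrt(self.sigma_u0_sq * self.sigma_u1_sq)
        return float(self.sigma_u01 / denom) if denom > 0 else 0.0


@dataclass
class LMMFit:
    """Fitted mixed model."""

    spec: LMMSpec
    fixed_effects: dict[str, float]
    varcomp: VarComp
    loglik: float
    converged: bool
    n_subjects: int
    subject_slopes: pd.Series = field(repr=False)      # id -> kg/yr
    subject_intercepts: pd.Series = field(repr=False)  # id -> kg
    grad_norm: float = np.nan

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects,
            "varcomp": {
                "sigma_u0_sq": self.varcomp.sigma_u0_sq,
                "sigma_u1_sq": self.varcomp.sigma_u1_sq,
                "sigma_u01": self.varcomp.sigma_u01,
                "sigma_e_sq": self.varcomp.sigma_e_sq,
                "rho": self.varcomp.rho,
            },
            "loglik": self.loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
        }


def subject_covariance(vc: VarComp, times) -> np.ndarray:
    """Marginal covariance V = Z G Z' + sigma_e^2 R(rho) for one subject."""
    t = np.asarray(times, dtype=float)
    Z = np.column_stack([np.ones_like(t), t])
    lags = np.abs(np.subtract.outer(np.arange(t.size), np.arange(t.size)))
    R = vc.rho ** lags
    return Z @ vc.G @ Z.T + vc.sigma_e_sq * R


# ---------------------------------------------------------------------------
# unconstrained parameterisation
# ---------------------------------------------------------------------------

def theta_from_varcomp(vc: VarComp) -> np.ndarray:
    r01 = np.clip(vc.corr_u01, -0.999, 0.999)
    rho = np.clip(vc.rho, -0.999, 0.999)
    return np.array(
        [
            np.log(max(vc.sigma_u0_sq, 1e-10)),
            np.log(max(vc.sigma_u1_sq, 1e-10)),
            np.arctanh(r01),
            np.log(max(vc.sigma_e_sq, 1e-10)),
            np.arctanh(rho),
        ]
    )


def varcomp_from_theta(theta, ar1: bool = True) -> VarComp:
    su0, su1 = np.exp(theta[0]), np.exp(theta[1])
    r01 = np.tanh(theta[2])
    se = np.exp(theta[3])
    rho = np.tanh(theta[4]) if ar1 else 0.0
    return VarComp(su0, su1, r01 * np.sqrt(su0 * su1), se, rho)


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood
# ---------------------------------------------------------------------------

def _design_row_pattern(terms: tuple[str, ...], times: np.ndarray, diab: int) -> np.ndarray:
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones_like(times))
        elif term == "time":
            cols.append(times)
        elif term == "diabetes":
            cols.append(np.full_like(times, float(diab)))
        elif term == "time:diabetes":
            cols.append(times * float(diab))
    return np.column_stack(cols)


@dataclass
class _SuffStats:
    """Balanced-design sufficient statistics, grouped by covariate pattern."""

    times: np.ndarray          # shared centred times, length T
    designs: list[np.ndarray]  # per group: T x p design
    counts: list[int]          # per group: number of subjects
    sums: list[np.ndarray]     # per group: sum of y_j  (length T)
    crossprods: list[np.ndarray]  # per group: sum of y_j y_j' (T x T)
    ids: np.ndarray            # subject ids, group-ordered
    Y: np.ndarray              # m x T response matrix, group-ordered
    group_of_subject: np.ndarray  # group index per subject


def _prepare(data: pd.DataFrame, spec: LMMSpec) -> _SuffStats:
    required = {"id", "time_centered", "weight"}
    if spec.uses_outcome:
        required.add("diabetes")
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long data missing columns {sorted(missing)}")

    d = data.sort_values(["id", "time_centered"], kind="mergesort")
    times = np.sort(d["time_centered"].unique())
    T = times.size
    counts_per_id = d.groupby("id").size()
    if counts_per_id.nunique() != 1 or counts_per_id.iloc[0] != T:
        raise ValueError("design must be balanced: same times for every subject")
    m = counts_per_id.size
    if m < 2 or T < 2:
        raise ValueError("need at least 2 subjects with at least 2 occasions")

    Y = d["weight"].to_numpy().reshape(m, T)
    ids = d["id"].to_numpy()[::T]
    if spec.uses_outcome:
        diab = d["diabetes"].to_numpy()[::T].astype(int)
        levels = [0, 1]
    else:
        diab = np.zeros(m, dtype=int)
        levels = [0]

    designs, counts, sums, crossprods = [], [], [], []
    order = []
    group_of = np.empty(m, dtype=int)
    g = 0
    for level in levels:
        mask = diab == level
        if not mask.any():
            if spec.uses_outcome:
                raise ValueError(f"outcome group {level} is empty")
            continue
        Yg = Y[mask]
        designs.append(_design_row_pattern(spec.fixed_terms, times, level))
        counts.append(int(mask.sum()))
        sums.append(Yg.sum(axis=0))
        crossprods.append(Yg.T @ Yg)
        order.append(np.flatnonzero(mask))
        group_of[mask] = g
        g += 1
    perm = np.concatenate(order)
    return _SuffStats(
        times=times,
        designs=designs,
        counts=counts,
        sums=sums,
        crossprods=crossprods,
        ids=ids[perm],
        Y=Y[perm],
        group_of_subject=group_of[perm],
    )


_PENALTY = 1e10


def _nll_core(vc: VarComp, stats: _SuffStats, spec: LMMSpec):
    """-log likelihood with fixed effects profiled out by GLS.

    Returns (nll, beta, W) where W = V^{-1}; (PENALTY, None, None) when V is
    numerically singular.
    """
    V = subject_covariance(vc, stats.times)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return _PENALTY, None, None
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    W = linalg.cho_solve(cho, np.eye(V.shape[0]))

    p = stats.designs[0].shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    for A, n_g, s_g in zip(stats.designs, stats.counts, stats.sums):
        AW = A.T @ W
        XtWX += n_g * (AW @ A)
        XtWy += AW @ s_g
    try:
        with warnings.catch_warnings():
            # near-singular XtWX mid-search is handled by the penalty path
            warnings.simplefilter("ignore", linalg.LinAlgWarning)
            beta = linalg.solve(XtWX, XtWy, assume_a="pos")
    except linalg.LinAlgError:
        return _PENALTY, None, None
    if not np.all(np.isfinite(beta)):
        return _PENALTY, None, None

    quad = 0.0
    for A, n_g, s_g, Q_g in zip(stats.designs, stats.counts, stats.sums, stats.crossprods):
        mu = A @ beta
        Wmu = W @ mu
        quad += float(np.sum(W * Q_g)) - 2.0 * float(s_g @ Wmu) + n_g * float(mu @ Wmu)

    m = sum(stats.counts)
    N = m * stats.times.size
    nll = 0.5 * (N * LOG2PI + m * logdet_V + quad)
    if spec.estimation == "REML":
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return _PENALTY, None, None
        nll += 0.5 * (logdet_XtWX - p * LOG2PI)
    if not np.isfinite(nll):
        return _PENALTY, None, None
    return nll, beta, W


def negative_log_likelihood(params, data: pd.DataFrame, spec: LMMSpec) -> float:
    """Profiled negative log likelihood at an unconstrained parameter vector."""
    stats = _prepare(data, spec)
    vc = varcomp_from_theta(np.asarray(params, dtype=float), ar1=spec.ar1)
    return _nll_core(vc, stats, spec)[0]


def _initial_theta(stats: _SuffStats) -> np.ndarray:
    """Moment-based start: per-subject OLS intercepts/slopes."""
    t = stats.times
    Y = stats.Y
    b0 = Y.mean(axis=1)
    stt = float(np.sum((t - t.mean()) ** 2))
    b1 = (Y - Y.mean(axis=1, keepdims=True)) @ (t - t.mean()) / stt
    resid = Y - b0[:, None] - np.outer(b1, t - t.mean())
    dof = max(t.size - 2, 1)
    se2 = max(float(np.mean(np.sum(resid**2, axis=1)) / dof), 1e-2)
    su0 = max(float(np.var(b0)) - se2 / t.size, 1e-2)
    su1 = max(float(np.var(b1)) - se2 / stt, 1e-2)
    r01 = float(np.corrcoef(b0, b1)[0, 1]) if b0.size > 2 else 0.0
    r01 = np.clip(np.nan_to_num(r01), -0.9, 0.9)
    return np.array([np.log(su0), np.log(su1), np.arctanh(r01), np.log(se2), 0.0])


def _central_gradient(fun, x, rel_step: float = 1e-5) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * h)
    return g


def fit_lmm(
    data: pd.DataFrame,
    spec: LMMSpec = LMMSpec(),
    n_restarts: int = 3,
    grad_tol: float = 1e-3,
) -> LMMFit:
    """Fit the mixed model by quasi-Newton optimisation with restarts.

    Each attempt runs L-BFGS-B and then a Nelder-Mead polish (the likelihood
    can be extremely flat near the optimum, e.g. when the intercept-slope
    correlation saturates at its boundary, where quasi-Newton steps stall on
    finite-difference noise).  Convergence requires an infinity-norm of the
    central-difference gradient below ``grad_tol`` on the unconstrained
    scale; non-converged fits carry ``converged=False`` and are discarded by
    the Monte-Carlo harness.
    """
    stats = _prepare(data, spec)
    theta0 = _initial_theta(stats)

    def objective(theta):
        vc = varcomp_from_theta(theta, ar1=spec.ar1)
        return _nll_core(vc, stats, spec)[0]

    jitter_rng = np.random.default_rng(20231204)  # fixed: fits are deterministic
    best = None
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + jitter_rng.normal(0, 0.5, size=5)
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        gnorm = float(np.max(np.abs(_central_gradient(objective, res.x))))
        if gnorm >= grad_tol:
            polished = optimize.minimize(
                objective,
                res.x,
                method="Nelder-Mead",
                options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
            )
            if polished.fun <= res.fun:
                res = polished
            gnorm = float(np.max(np.abs(_central_gradient(objective, res.x))))
        ok = gnorm < grad_tol and res.fun < _PENALTY / 2
        cand = (ok, -res.fun, res, gnorm)
        if best is None or cand[:2] > best[:2]:
            best = cand
        if ok:
            break

    converged, _, res, gnorm = best
    vc = varcomp_from_theta(res.x, ar1=spec.ar1)
    nll, beta, W = _nll_core(vc, stats, spec)
    if beta is None:
        converged = False
        beta = np.full(stats.designs[0].shape[1], np.nan)
        W = np.zeros((stats.times.size,) * 2)

    fixed_effects = dict(zip(spec.fixed_terms, np.asarray(beta, dtype=float)))

    # empirical-Bayes random effects: u_j = G Z' V^{-1} (y_j - X_j beta)
    t = stats.times
    Z = np.column_stack([np.ones_like(t), t])
    K = vc.G @ Z.T @ W  # 2 x T
    resid = np.empty_like(stats.Y)
    offset = 0
    fixed_slope = np.empty(stats.Y.shape[0])
    fixed_icept = np.empty(stats.Y.shape[0])
    for A, n_g in zip(stats.designs, stats.counts):
        mu = A @ beta
        resid[offset : offset + n_g] = stats.Y[offset : offset + n_g] - mu
        # per-subject fixed intercept/slope implied by the group's design
        coef = np.linalg.lstsq(Z, mu, rcond=None)[0]
        fixed_icept[offset : offset + n_g] = coef[0]
        fixed_slope[offset : offset + n_g] = coef[1]
        offset += n_g
    u = resid @ K.T  # m x 2
    slopes = pd.Series(fixed_slope + u[:, 1], index=stats.ids, name="slope")
    icepts = pd.Series(fixed_icept + u[:, 0], index=stats.ids, name="intercept")
    slopes = slopes.sort_index()
    icepts = icepts.sort_index()

    return LMMFit(
        spec=spec,
        fixed_effects=fixed_effects,
        varcomp=vc,
        loglik=float(-nll),
        converged=bool(converged),
        n_subjects=int(stats.Y.shape[0]),
        subject_slopes=slopes,
        subject_intercepts=icepts,
        grad_norm=gnorm,
    )


def random_slopes(fit: LMMFit) -> pd.Series:
    """Per-subject growth rates gamma_1 + u1j (kg/yr), indexed by id."""
    if not fit.converged:
        raise RuntimeError("cannot extract slopes from a non-converged fit")
    return fit.subject_slopes


# ---------------------------------------------------------------------------
# dense reference likelihood (test oracle; O(N^3), small fixtures only)
# ---------------------------------------------------------------------------

def dense_negative_log_likelihood(params, data: pd.DataFrame, spec: LMMSpec) -> float:
    """Same likelihood computed from one dense stacked covariance matrix.

    Builds the full N x N block-diagonal marginal covariance and the stacked
    design, then evaluates the (restricted) Gaussian log density directly —
    no grouping, profiling shortcuts, or shared-V assumptions.
    """
    d = data.sort_values(["id", "time_centered"], kind="mergesort")
    vc = varcomp_from_theta(np.asarray(params, dtype=float), ar1=spec.ar1)
    ids = d["id"].unique()
    blocks, Xs, ys = [], [], []
    for sid in ids:
        sub = d[d["id"] == sid]
        t = sub["time_centered"].to_numpy(dtype=float)
        diab = int(sub["diabetes"].iloc[0]) if spec.uses_outcome else 0
        blocks.append(subject_covariance(vc, t))
        Xs.append(_design_row_pattern(spec.fixed_terms, t, diab))
        ys.append(sub["weight"].to_numpy(dtype=float))
    V = linalg.block_diag(*blocks)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    W = np.linalg.inv(V)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    r = y - X @ beta
    sign, logdet_V = np.linalg.slogdet(V)
    nll = 0.5 * (y.size * LOG2PI + logdet_V + r @ W @ r)
    if spec.estimation == "REML":
        _, logdet_XtWX = np.linalg.slogdet(XtWX)
        nll += 0.5 * (logdet_XtWX - X.shape[1] * LOG2PI)
    return float(nll)
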