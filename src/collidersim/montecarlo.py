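"""Monte-Carlo harness for the simulation study.

Runs the replicate loop for each causal scenario: simulate a cohort, record
its moments, run the three analysis methods, then summarise every recorded
quantity across replicates with its mean, median and empirical 95% CI (the
2.5th and 97.5th centiles).  Replicates where a model failed to converge are
excluded from that model's summaries (per-model discard policy) and counted
in the discard log.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import methods as methods_mod
from . import scenarios as scen_mod
from . import simulate as sim_mod

SCENARIO_IDS = ("A", "B", "C")


@dataclass
class StudyConfig:
    scenarios: tuple[str, ...] = SCENARIO_IDS
    n_per_cohort: int = 1000
    n_replicates: int = 1000
    master_seed: int = 0
    estimation: str = "REML"
    output_dir: Path | None = None

    def __post_init__(self):
        unknown = set(self.scenarios) - set(SCENARIO_IDS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.n_per_cohort < 10:
            raise ValueError("need at least 10 individuals per cohort")


def replicate_seed(master_seed: int, scenario_id: str, replicate: int) -> np.random.SeedSequence:
    """Independent, individually reproducible substream per replicate."""
    return np.random.SeedSequence(
        [int(master_seed), scen_mod.CAUSAL_WEIGHT_INDEX[scenario_id], int(replicate)]
    )


Summary = namedtuple("Summary", ["mean", "median", "centile_2_5", "centile_97_5"])


def summarize(values) -> Summary:
    """Mean, median and 2.5/97.5 centiles (linear order-statistic interpolation)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    lo, hi = np.percentile(v, [2.5, 97.5])
    return Summary(float(v.mean()), float(np.median(v)), float(lo), float(hi))


def _moment_rows(cohort: pd.DataFrame) -> dict[str, float]:
    out = {}
    h = cohort["hba1c"]
    for age, col in enumerate(sim_mod.WEIGHT_LABELS):
        w = cohort[col]
        out[f"mean_weight_{age}"] = float(w.mean())
        out[f"sd_weight_{age}"] = float(w.std(ddof=1))
        out[f"corr_weight_{age}_hba1c"] = float(np.corrcoef(w, h)[0, 1])
    out["mean_hba1c"] = float(h.mean())
    out["sd_hba1c"] = float(h.std(ddof=1))
    out["prevalence"] = float(cohort["diabetes"].mean())
    return out


def _group_mean_rows(cohort: pd.DataFrame) -> dict[str, float]:
    out = {}
    for label, grp in (("diabetic", 1), ("non_diabetic", 0)):
        sub = cohort[cohort["diabetes"] == grp]
        for age, col in enumerate(sim_mod.WEIGHT_LABELS):
            out[f"mean_weight_{age}_{label}"] = float(sub[col].mean())
    return out


def run_replicate(
    jg: scen_mod.JointGaussian,
    n: int,
    seed,
    estimation: str = "REML",
) -> tuple[dict[str, dict[str, float]], dict[str, bool]]:
    """One replicate: simulate and apply every method.

    Returns (estimates per method, convergence flag per method).
    """
    cohort = sim_mod.simulate_cohort(jg, n, seed)
    long = sim_mod.to_long(cohort)

    estimates: dict[str, dict[str, float]] = {}
    converged: dict[str, bool] = {}

    estimates["moments"] = {**_moment_rows(cohort), **_group_mean_rows(cohort)}
    converged["moments"] = True

    try:
        profile = methods_mod.zscore_profiles(cohort)
        z = {}
        for age in profile.means.index:
            z[f"z_age{age}_diabetic"] = float(profile.means.loc[age, "diabetic"])
            z[f"z_age{age}_non_diabetic"] = float(profile.means.loc[age, "non_diabetic"])
        estimates["zscore"] = z
        converged["zscore"] = True
    except methods_mod.DegenerateInputError:
        estimates["zscore"] = {}
        converged["zscore"] = False

    ocm_spec = None
    if estimation != "REML":
        from .lmm import LMMSpec, FIXED_TERMS_OUTCOME_COVARIATE

        ocm_spec = LMMSpec(fixed_terms=FIXED_TERMS_OUTCOME_COVARIATE, estimation=estimation)
    ocm = methods_mod.outcome_covariate_model(long, ocm_spec)
    estimates["outcome_covariate"] = ocm.payload if ocm.converged else {}
    converged["outcome_covariate"] = ocm.converged

    ts = methods_mod.two_step(cohort, estimation=estimation)
    estimates["two_step"] = ts.payload if ts.converged else {}
    converged["two_step"] = ts.converged

    return estimates, converged


def run_scenario(cfg: StudyConfig, scenario_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate loop for one scenario.

    Returns ``(estimates, log)``: a tidy per-replicate table with columns
    (replicate, scenario, method, parameter, estimate, converged) holding
    every recorded quantity from converged fits, and a convergence log with
    one row per (replicate, method).
    """
    jg = scen_mod.scenario_joint_gaussian(scenario_id)
    est_rows, log_rows = [], []
    for rep in range(cfg.n_replicates):
        seed = replicate_seed(cfg.master_seed, scenario_id, rep)
        estimates, converged = run_replicate(
            jg, cfg.n_per_cohort, seed, estimation=cfg.estimation
        )
        for method, params in estimates.items():
            for name, value in params.items():
                est_rows.append(
                    (rep, scenario_id, method, name, value, converged[method])
                )
        for method, flag in converged.items():
            log_rows.append((rep, scenario_id, method, flag))
    estimates_df = pd.DataFrame(
        est_rows,
        columns=["replicate", "scenario", "method", "parameter", "estimate", "converged"],
    )
    log_df = pd.DataFrame(log_rows, columns=["replicate", "scenario", "method", "converged"])
    if log_df.groupby("method")["converged"].sum().min() == 0:
        raise RuntimeError(f"all replicates discarded for a model in scenario {scenario_id}")
    return estimates_df, log_df


def summarize_study(estimates: pd.DataFrame, log: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate summary per (scenario, method, parameter)."""
    n_total = log.groupby(["scenario", "method"])["converged"].size()
    n_used = log.groupby(["scenario", "method"])["converged"].sum()
    rows = []
    for (scen, method, param), grp in estimates.groupby(
        ["scenario", "method", "parameter"], sort=True
    ):
        s = summarize(grp["estimate"])
        used = int(n_used.loc[(scen, method)])
        rows.append(
            {
                "scenario": scen,
                "method": method,
                "parameter": param,
                "mean": s.mean,
                "median": s.median,
                "centile_2_5": s.centile_2_5,
                "centile_97_5": s.centile_97_5,
                "n_used": used,
                "n_discarded": int(n_total.loc[(scen, method)]) - used,
            }
        )
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run every requested scenario; optionally write outputs to disk."""
    all_est, all_log = [], []
    for sid in cfg.scenarios:
        est, log = run_scenario(cfg, sid)
        all_est.append(est)
        all_log.append(log)
    estimates = pd.concat(all_est, ignore_index=True)
    log = pd.concat(all_log, ignore_index=True)
    summary = summarize_study(estimates, log)
    out = {"estimates": estimates, "log": log, "summary": summary}
    if cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        estimates.to_csv(outdir / "replicate_estimates.csv", index=False)
        log.to_csv(outdir / "convergence_log.csv", index=False)
        summary.to_csv(outdir / "study_summary.csv", index=False)
        render_tables(summary, outdir)
    return out


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_TABLE5_PARAMS = [
    ("diabetes", "Diabetes"),
    ("time", "Age"),
    ("time:diabetes", "Diabetes*Age"),
    ("intercept", "Intercept"),
    ("intercept_variance", "Intercept variance"),
    ("slope_variance", "Age variance"),
    ("residual_variance", "Residual variance"),
    ("intercept_slope_covariance", "Intercept-age covariance"),
    ("intercept_slope_correlation", "Intercept-age correlation"),
    ("autocorrelation", "Autocorrelation parameter"),
]

_TABLE6_PARAMS = [
    ("or_growth_rate", "Growth rate (OR per 0.1 kg/yr)"),
    ("or_weight_0", "Birthweight (OR per kg)"),
    ("constant", "Constant (odds)"),
]


def _tidy_table(summary: pd.DataFrame, method: str, params: list[tuple[str, str]]) -> pd.DataFrame:
    sub = summary[summary["method"] == method].set_index(["parameter", "scenario"])
    rows = []
    for key, label in params:
        for scen in sorted(summary["scenario"].unique()):
            if (key, scen) in sub.index:
                r = sub.loc[(key, scen)]
                rows.append(
                    {
                        "parameter": label,
                        "scenario": scen,
                        "mean": r["mean"],
                        "ci_low": r["centile_2_5"],
                        "ci_high": r["centile_97_5"],
                    }
                )
            else:
                rows.append(
                    {"parameter": label, "scenario": scen, "mean": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan}
                )
    return pd.DataFrame(rows)


def render_tables(summary: pd.DataFrame, outdir) -> list[Path]:
    """Write one CSV per report table (cohort moments, mixed-model fixed
    effects and variance components, two-step odds ratios, z-score points).
    Cells are written with 3-decimal formatting; missing cells are NA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    scens = sorted(summary["scenario"].unique())
    if not scens:
        import warnings

        warnings.warn("empty scenario subset; no tables written")
        return written

    moment_params = [
        (f"{stat}_weight_{age}", f"{stat.upper() if stat == 'sd' else 'Mean'} weight_{age}")
        for age in range(3)
        for stat in ("mean", "sd")
    ] + [
        (f"corr_weight_{age}_hba1c", f"Correlation weight_{age} with HbA1c")
        for age in range(3)
    ] + [("mean_hba1c", "Mean HbA1c"), ("sd_hba1c", "SD HbA1c"), ("prevalence", "Diabetes prevalence")]
    tables = {
        "table_cohort_moments.csv": _tidy_table(summary, "moments", moment_params),
        "table_outcome_covariate.csv": _tidy_table(summary, "outcome_covariate", _TABLE5_PARAMS),
        "table_two_step.csv": _tidy_table(summary, "two_step", _TABLE6_PARAMS),
        "table_zscore_profiles.csv": _tidy_table(
            summary,
            "zscore",
            [
                (f"z_age{age}_{grp}", f"Mean z at age {age} ({grp.replace('_', '-')})")
                for age in range(3)
                for grp in ("diabetic", "non_diabetic")
            ],
        ),
    }
    for fname, df in tables.items():
        path = outdir / fname
        df.to_csv(path, index=False, float_format="%.3f")
        written.append(path)
    return written
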