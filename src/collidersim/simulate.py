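"""Cohort simulation and reshaping.

A cohort is a wide :class:`pandas.DataFrame` with columns
``id, weight_0, weight_1, weight_2, hba1c, diabetes`` — one row per person,
weights in kg at ages 0/1/2 years, HbA1c in % at age 40, and diabetes the
indicator ``hba1c > 6.5``.  The long format used by the mixed models has
columns ``id, time_centered, weight, diabetes`` with age centred at 1 year,
so time takes the values -1, 0, 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenarios import JointGaussian, WEIGHT_LABELS

DIABETES_THRESHOLD = 6.5  # % HbA1c; diagnosis requires strictly exceeding it

WIDE_COLUMNS = ["id", "weight_0", "weight_1", "weight_2", "hba1c", "diabetes"]
LONG_COLUMNS = ["id", "time_centered", "weight", "diabetes"]


def dichotomize(hba1c_values, threshold: float = DIABETES_THRESHOLD) -> np.ndarray:
    """Binary diabetes status: 1 iff HbA1c strictly exceeds the threshold."""
    values = np.asarray(hba1c_values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("HbA1c values must be finite")
    return (values > threshold).astype(np.int64)


def simulate_cohort(jg: JointGaussian, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` i.i.d. individuals from the joint Gaussian.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`; identical seeds give identical cohorts.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(jg.mean, jg.covariance, size=n, method="cholesky")
    cohort = pd.DataFrame(draws, columns=list(jg.labels))
    cohort.insert(0, "id", np.arange(1, n + 1))
    cohort["diabetes"] = dichotomize(cohort["hba1c"])
    return cohort


def to_long(cohort: pd.DataFrame, center_age: float = 1.0) -> pd.DataFrame:
    """Reshape a wide cohort to the long format the mixed models consume."""
    long = cohort.melt(
        id_vars=["id", "diabetes"],
        value_vars=list(WEIGHT_LABELS),
        var_name="age",
        value_name="weight",
    )
    long["time_centered"] = long["age"].str.removeprefix("weight_").astype(float) - center_age
    long = long[LONG_COLUMNS].sort_values(["id", "time_centered"], kind="mergesort")
    return long.reset_index(drop=True)


def to_wide(long: pd.DataFrame, center_age: float = 1.0) -> pd.DataFrame:
    """Inverse of :func:`to_long` (drops the continuous hba1c column)."""
    wide = long.pivot(index="id", columns="time_centered", values="weight")
    wide.columns = [f"weight_{t + center_age:.0f}" for t in wide.columns]
    wide = wide.reset_index()
    status = long.groupby("id", sort=True)["diabetes"].first().reset_index()
    return wide.merge(status, on="id")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(WIDE_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    return cohort[WIDE_COLUMNS]
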