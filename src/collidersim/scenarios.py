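"""Causal-scenario calibration.

Three scenarios (A, B, C) describe an infant-growth cohort in which exactly
one weight measurement (at age 0, 1 or 2 years) has a direct causal arrow to
adult HbA1c.  Because latent growth and confounding are marginalised out, each
scenario is fully characterised by the reduced-form joint Gaussian over the
four observed variables (weight_0, weight_1, weight_2, hba1c).

Calibration works backwards from the cross-sectional weight-HbA1c
correlations each scenario is required to induce: when only one weight carries
a direct arrow to the outcome, d-separation factorises every non-causal
weight's outcome correlation as

    corr(W_j, H) = direct_effect * corr(W_j, W_causal).

Stacking those equations over all three scenarios over-determines the three
unknown between-age weight correlations; we solve the system by least squares
and refuse to proceed if the residuals show the targets are inconsistent with
a single-direct-arrow structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

WEIGHT_LABELS = ("weight_0", "weight_1", "weight_2")
LABELS = WEIGHT_LABELS + ("hba1c",)

#: scenario id -> index of the weight with the direct arrow to HbA1c
CAUSAL_WEIGHT_INDEX = {"A": 0, "B": 1, "C": 2}

#: default moments: mean weight 4/8/12 kg at ages 0/1/2, HbA1c 5.8 %
DEFAULT_WEIGHT_MEANS = (4.0, 8.0, 12.0)
DEFAULT_WEIGHT_SDS = (2.0, 2.0, 2.0)
DEFAULT_HBA1C_MEAN = 5.8
DEFAULT_HBA1C_SD = 1.0

#: standardised direct effect of the causal weight on HbA1c
DEFAULT_DIRECT_EFFECT = 0.70

#: target cross-sectional correlations of (weight_0, weight_1, weight_2) with
#: HbA1c that each scenario must induce.  These are the study's calibration
#: anchors; the causal weight's entry equals the direct effect up to rounding.
DEFAULT_OUTCOME_CORR_TARGETS = {
    "A": (0.699, 0.029, -0.105),
    "B": (0.027, 0.699, 0.229),
    "C": (-0.106, 0.229, 0.700),
}


class CalibrationError(ValueError):
    """Raised when targets cannot be reconciled with the causal structure."""


def _as_corr_matrix(rho01: float, rho02: float, rho12: float) -> np.ndarray:
    m = np.array(
        [
            [1.0, rho01, rho02],
            [rho01, 1.0, rho12],
            [rho02, rho12, 1.0],
        ]
    )
    return m


def _assert_positive_definite(m: np.ndarray, what: str) -> None:
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError(f"{what} is not positive definite") from exc


def derive_weight_correlations(
    targets: dict[str, tuple[float, float, float]] | None = None,
    direct_effect: float = DEFAULT_DIRECT_EFFECT,
    max_residual: float = 0.01,
) -> np.ndarray:
    """Solve for the 3x3 between-age weight correlation matrix.

    Parameters
    ----------
    targets
        Per scenario, the required correlations of (weight_0, weight_1,
        weight_2) with HbA1c.  Defaults to the study's calibration anchors.
    direct_effect
        Standardised path coefficient of the causal weight on HbA1c,
        shared across scenarios.
    max_residual
        Largest tolerated absolute residual, on the correlation scale,
        between a target and its least-squares reconstruction.

    Returns
    -------
    numpy.ndarray
        Symmetric positive-definite 3x3 correlation matrix, identical across
        scenarios (only the outcome column differs between scenarios).
    """
    if targets is None:
        targets = DEFAULT_OUTCOME_CORR_TARGETS
    if not 0.0 < direct_effect <= 1.0:
        raise ValueError("direct_effect must lie in (0, 1]")

    # unknowns ordered (rho01, rho02, rho12); pair -> column index
    pair_col = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    rows, rhs = [], []
    for sid, tgt in targets.items():
        k = CAUSAL_WEIGHT_INDEX[sid]
        tgt = np.asarray(tgt, dtype=float)
        if abs(tgt[k] - direct_effect) > max_residual:
            raise CalibrationError(
                f"scenario {sid}: causal-weight target {tgt[k]} is not "
                f"consistent with direct_effect={direct_effect}"
            )
        for j in range(3):
            if j == k:
                continue
            row = np.zeros(3)
            row[pair_col[tuple(sorted((j, k)))]] = direct_effect
            rows.append(row)
            rhs.append(tgt[j])
    A = np.vstack(rows)
    b = np.asarray(rhs)
    rho, *_ = np.linalg.lstsq(A, b, rcond=None)
    residuals = A @ rho - b
    if np.max(np.abs(residuals)) >= max_residual:
        raise CalibrationError(
            "outcome-correlation targets are inconsistent with a "
            f"single-direct-arrow structure (max residual "
            f"{np.max(np.abs(residuals)):.4f})"
        )
    corr = _as_corr_matrix(*rho)
    _assert_positive_definite(corr, "calibrated weight correlation matrix")
    return corr


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one causal scenario.

    ``causal_weight_index`` is the age index (0, 1 or 2 years) of the single
    weight measurement with a direct arrow to HbA1c; every other weight is
    associated with the outcome only through its correlation with that weight.
    """

    scenario_id: str
    direct_effect: float = DEFAULT_DIRECT_EFFECT
    weight_means: tuple[float, float, float] = DEFAULT_WEIGHT_MEANS
    weight_sds: tuple[float, float, float] = DEFAULT_WEIGHT_SDS
    hba1c_mean: float = DEFAULT_HBA1C_MEAN
    hba1c_sd: float = DEFAULT_HBA1C_SD
    weight_corr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.scenario_id not in CAUSAL_WEIGHT_INDEX:
            raise ValueError(f"unknown scenario {self.scenario_id!r}")
        if not 0.0 < self.direct_effect <= 1.0:
            raise ValueError("direct_effect must lie in (0, 1]")
        wc = self.weight_corr
        if wc is None:
            wc = derive_weight_correlations(direct_effect=self.direct_effect)
        wc = np.asarray(wc, dtype=float)
        if wc.shape != (3, 3) or not np.allclose(wc, wc.T):
            raise ValueError("weight_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(wc), 1.0):
            raise ValueError("weight_corr must have a unit diagonal")
        _assert_positive_definite(wc, "weight_corr")
        object.__setattr__(self, "weight_corr", wc)

    @property
    def causal_weight_index(self) -> int:
        return CAUSAL_WEIGHT_INDEX[self.scenario_id]

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "direct_effect": self.direct_effect,
            "weight_means": list(self.weight_means),
            "weight_sds": list(self.weight_sds),
            "hba1c_mean": self.hba1c_mean,
            "hba1c_sd": self.hba1c_sd,
            "weight_corr": self.weight_corr.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            scenario_id=d["scenario_id"],
            direct_effect=d.get("direct_effect", DEFAULT_DIRECT_EFFECT),
            weight_means=tuple(d.get("weight_means", DEFAULT_WEIGHT_MEANS)),
            weight_sds=tuple(d.get("weight_sds", DEFAULT_WEIGHT_SDS)),
            hba1c_mean=d.get("hba1c_mean", DEFAULT_HBA1C_MEAN),
            hba1c_sd=d.get("hba1c_sd", DEFAULT_HBA1C_SD),
            weight_corr=np.asarray(d["weight_corr"]) if "weight_corr" in d else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class JointGaussian:
    """Multivariate normal law over (weight_0, weight_1, weight_2, hba1c)."""

    mean: np.ndarray
    covariance: np.ndarray
    labels: tuple[str, ...] = LABELS

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (len(self.labels),):
            raise ValueError("mean has wrong length")
        if cov.shape != (len(self.labels),) * 2 or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be square symmetric")
        _assert_positive_definite(cov, "joint covariance")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    def to_csv(self, path) -> None:
        """Write mean vector and covariance matrix for audit."""
        import pandas as pd

        mat = np.vstack([self.mean, self.covariance])
        idx = ["mean"] + [f"cov_{l}" for l in self.labels]
        pd.DataFrame(mat, index=idx, columns=self.labels).to_csv(path)


def build_joint_gaussian(spec: ScenarioSpec) -> JointGaussian:
    """Assemble the 4x4 joint Gaussian a scenario implies.

    The weight block is ``diag(sds) @ weight_corr @ diag(sds)``; each
    weight-outcome covariance is ``direct_effect * corr(W_j, W_causal) *
    sd_j * hba1c_sd`` (with ``corr(W_causal, W_causal) = 1``), i.e. the
    reduced form of a structure where only the causal weight points at HbA1c.
    """
    sds = np.asarray(spec.weight_sds, dtype=float)
    d = np.diag(sds)
    weight_cov = d @ spec.weight_corr @ d
    k = spec.causal_weight_index
    cross = spec.direct_effect * spec.weight_corr[:, k] * sds * spec.hba1c_sd
    cov = np.empty((4, 4))
    cov[:3, :3] = weight_cov
    cov[:3, 3] = cross
    cov[3, :3] = cross
    cov[3, 3] = spec.hba1c_sd**2
    mean = np.append(np.asarray(spec.weight_means, dtype=float), spec.hba1c_mean)
    try:
        return JointGaussian(mean=mean, covariance=cov)
    except CalibrationError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise CalibrationError(str(exc)) from exc


def implied_outcome_correlations(jg: JointGaussian) -> np.ndarray:
    """Correlations of each weight with HbA1c implied by ``jg.covariance``."""
    cov = jg.covariance
    sds = np.sqrt(np.diag(cov))
    return cov[:3, 3] / (sds[:3] * sds[3])


def scenario_joint_gaussian(scenario_id: str, **kwargs) -> JointGaussian:
    """Convenience: calibrated joint Gaussian for a scenario id."""
    return build_joint_gaussian(ScenarioSpec(scenario_id, **kwargs))
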