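"""Data-generating model for block-randomised trials with a binary endpoint.

A trial enrols ``T`` patients in ``J`` blocks of size ``b``; patient ``i`` in
block ``j`` is allocated to one of ``K + 1`` arms (arm 0 is control) and yields
a Bernoulli outcome whose success probability follows a logistic model

    logit Pr(Y = 1 | Z, arm k) = beta0 + beta_t * (j - 1) + beta_z * Z + beta_k,

with ``beta_k = 0`` for the control arm.  The block-level time coefficient
``beta_t`` encodes a trend in the standard of care ("scenario 1"); a binary
patient covariate ``Z ~ Bern(q_j)`` whose prevalence ``q_j`` evolves over
blocks encodes patient drift ("scenario 2").

This module also serves as the synthetic-data generator for the rest of the
package: every simulated trial, test fixture, and operating-characteristics
study samples its outcomes from here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "DesignSpec",
    "ModelParams",
    "CovariatePath",
    "ScenarioSpec",
    "TrialRecord",
    "success_probability",
    "marginal_rate",
    "mean_rate",
    "solve_beta_t",
    "sample_block",
]

#: probabilities are clamped away from {0, 1} before Bernoulli sampling so
#: that downstream log-likelihoods never see an exact zero.
PROB_EPS = 1e-12

SIMPLEX_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Trial skeleton shared by every allocation rule and scenario.

    Parameters
    ----------
    K : int
        Number of experimental arms; the control arm (index 0) is implicit,
        so the trial has ``K + 1`` arms in total.
    T : int
        Total number of patients; must equal ``b * J``.
    J : int
        Number of blocks (interim updates happen between blocks).
    b : int
        Block size.
    prior_a, prior_b : float
        Beta prior pseudo-counts per arm (uniform prior by default).
    """

    K: int
    T: int
    J: int
    b: int
    prior_a: float = 1.0
    prior_b: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.b < 1 or self.J < 1:
            raise ValueError("b and J must be >= 1")
        if self.T != self.b * self.J:
            raise ValueError(f"T must equal b*J (got T={self.T}, b*J={self.b * self.J})")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior pseudo-counts must be positive")

    @property
    def n_arms(self) -> int:
        return self.K + 1


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Coefficients of the logistic outcome model.

    ``effect_mode`` selects how experimental-arm effects enter:

    - ``"logit_additive"``: ``beta_k`` is a log-odds shift (the model above,
      taken literally);
    - ``"risk_difference"``: ``beta_k`` is a constant probability-scale
      increment added to the control success probability (clamped to [0, 1]),
      so that the arm-vs-control risk difference is exactly ``beta_k`` in
      every stratum and block.
    """

    beta0: float
    beta_t: float = 0.0
    beta_z: float = 0.0
    beta_k: tuple[float, ...] = (0.0,)
    effect_mode: str = "logit_additive"

    def __post_init__(self) -> None:
        if self.effect_mode not in ("logit_additive", "risk_difference"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        object.__setattr__(self, "beta_k", tuple(float(v) for v in self.beta_k))

    @property
    def K(self) -> int:
        return len(self.beta_k)


@dataclasses.dataclass(frozen=True)
class CovariatePath:
    """Per-block prevalence q_j of the binary covariate Z."""

    q: tuple[float, ...]

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.q)
        if any(v < 0 or v > 1 for v in q):
            raise ValueError("every q_j must lie in [0, 1]")
        object.__setattr__(self, "q", q)

    @classmethod
    def constant(cls, q: float, J: int) -> "CovariatePath":
        return cls((q,) * J)

    @classmethod
    def linear(cls, start: float, step: float, J: int) -> "CovariatePath":
        return cls(tuple(start + step * j for j in range(J)))

    def __len__(self) -> int:
        return len(self.q)


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A design plus a data-generating process.

    ``scenario1`` is a trend in the standard of care (beta_t != 0, beta_z = 0);
    ``scenario2`` is patient drift (beta_z != 0, beta_t = 0, q_j evolving).
    """

    design: DesignSpec
    params: ModelParams
    q_path: CovariatePath
    D: float = 0.0
    scenario_label: str = "custom"
    z_observed: bool = False

    def __post_init__(self) -> None:
        if len(self.q_path) != self.design.J:
            raise ValueError(
                f"q_path length {len(self.q_path)} != J={self.design.J}"
            )
        if len(self.params.beta_k) != self.design.K:
            raise ValueError(
                f"beta_k length {len(self.params.beta_k)} != K={self.design.K}"
            )
        if self.scenario_label not in ("scenario1", "scenario2", "custom"):
            raise ValueError(f"unknown scenario_label {self.scenario_label!r}")
        if self.scenario_label == "scenario1" and self.params.beta_z != 0.0:
            raise ValueError("scenario1 requires beta_z = 0")
        if self.scenario_label == "scenario2" and self.params.beta_t != 0.0:
            raise ValueError("scenario2 requires beta_t = 0")

    # -- factories -----------------------------------------------------

    @classmethod
    def standard_of_care(
        cls,
        design: DesignSpec,
        p0: float = 0.3,
        D: float = 0.0,
        arm_effects: Sequence[float] | None = None,
        effect_mode: str = "logit_additive",
    ) -> "ScenarioSpec":
        """Scenario 1: linear upward trend of overall magnitude D in the
        control success probability, calibrated on the z=0 stratum."""
        beta_t = solve_beta_t(D, p0, design.J) if D != 0.0 else 0.0
        beta_k = tuple(arm_effects) if arm_effects is not None else (0.0,) * design.K
        params = ModelParams(
            beta0=float(logit(p0)),
            beta_t=beta_t,
            beta_z=0.0,
            beta_k=beta_k,
            effect_mode=effect_mode,
        )
        return cls(
            design=design,
            params=params,
            q_path=CovariatePath.constant(0.0, design.J),
            D=float(D),
            scenario_label="scenario1",
        )

    @classmethod
    def patient_drift(
        cls,
        design: DesignSpec,
        q_path: CovariatePath,
        p_neg: float = 0.3,
        p_pos: float = 0.6,
        arm_effects: Sequence[float] | None = None,
        effect_mode: str = "logit_additive",
        z_observed: bool = False,
    ) -> "ScenarioSpec":
        """Scenario 2: covariate effect p_neg -> p_pos with evolving
        prevalence q_j, no block-level trend."""
        beta_k = tuple(arm_effects) if arm_effects is not None else (0.0,) * design.K
        params = ModelParams(
            beta0=float(logit(p_neg)),
            beta_t=0.0,
            beta_z=float(logit(p_pos) - logit(p_neg)),
            beta_k=beta_k,
            effect_mode=effect_mode,
        )
        return cls(
            design=design,
            params=params,
            q_path=q_path,
            D=0.0,
            scenario_label="scenario2",
            z_observed=z_observed,
        )

    def true_mean_rates(self) -> np.ndarray:
        """Mean success rate per arm, averaged over blocks and Z."""
        return np.array(
            [mean_rate(k, self.params, self.q_path) for k in range(self.design.K + 1)]
        )

    def best_arm(self) -> int:
        """Index of the truly best arm; under the global null (all arms tied)
        arm 1 is the designated reference arm."""
        rates = self.true_mean_rates()
        if np.allclose(rates, rates[0]):
            return 1
        return int(np.argmax(rates))


# ---------------------------------------------------------------------------
# model arithmetic
# ---------------------------------------------------------------------------


def _check_indices(j: int, k: int, params: ModelParams, J: int | None) -> None:
    if j < 1 or (J is not None and j > J):
        raise ValueError(f"block index j={j} outside 1..{J if J else 'J'}")
    if k < 0 or k > params.K:
        raise ValueError(f"arm index k={k} outside 0..{params.K}")


def success_probability(
    j: int, z: int, k: int, params: ModelParams, J: int | None = None
) -> float:
    """Success probability for a patient in block ``j`` with covariate ``z``
    on arm ``k`` (blocks are 1-indexed; the time covariate is ``t_j = j-1``)."""
    _check_indices(j, k, params, J)
    if z not in (0, 1):
        raise ValueError(f"z must be 0 or 1, got {z}")
    eta0 = params.beta0 + params.beta_t * (j - 1) + params.beta_z * z
    if k == 0:
        return float(expit(eta0))
    if params.effect_mode == "logit_additive":
        return float(expit(eta0 + params.beta_k[k - 1]))
    # risk-difference mode: constant probability-scale increment, clamped
    return float(np.clip(expit(eta0) + params.beta_k[k - 1], 0.0, 1.0))


def marginal_rate(
    j: int, k: int, params: ModelParams, q_path: CovariatePath
) -> float:
    """Success rate in block ``j`` on arm ``k`` marginalised over Z ~ Bern(q_j)."""
    if j < 1 or j > len(q_path):
        raise ValueError(f"block index j={j} outside 1..{len(q_path)}")
    q = q_path.q[j - 1]
    return (1.0 - q) * success_probability(j, 0, k, params) + q * success_probability(
        j, 1, k, params
    )


def mean_rate(k: int, params: ModelParams, q_path: CovariatePath) -> float:
    """Mean response rate on arm ``k``: the arithmetic average of the
    per-block marginal rates (equal numbers recruited per block)."""
    J = len(q_path)
    return float(np.mean([marginal_rate(j, k, params, q_path) for j in range(1, J + 1)]))


def solve_beta_t(D: float, p0: float, J: int) -> float:
    """Per-block trend coefficient giving an overall trend of magnitude D.

    D is the rise of the (z=0 stratum, control-arm) success probability from
    the first block (t=0) to the last (t=J-1):

        Expit(beta0 + beta_t*(J-1)) - Expit(beta0) = D,   beta0 = logit(p0),

    which has the closed form ``(logit(p0 + D) - logit(p0)) / (J - 1)``.
    """
    if J < 2:
        raise ValueError("J must be >= 2 to define a trend")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not (0.0 < p0 + D < 1.0):
        raise ValueError(f"p0 + D = {p0 + D} must lie in (0, 1)")
    if D == 0.0:
        return 0.0
    return float((logit(p0 + D) - logit(p0)) / (J - 1))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _success_matrix(j: int, params: ModelParams, K: int) -> np.ndarray:
    """(2, K+1) matrix of success probabilities indexed by [z, arm]."""
    out = np.empty((2, K + 1))
    for z in (0, 1):
        for k in range(K + 1):
            out[z, k] = success_probability(j, z, k, params)
    return np.clip(out, PROB_EPS, 1.0 - PROB_EPS)


def sample_block(
    j: int,
    probs: np.ndarray,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one block of ``b`` patients.

    Returns ``(arms, z, y)`` integer arrays of length ``b``: the allocated
    arm, the covariate, and the outcome of each patient.
    """
    design = scenario.design
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (design.K + 1,):
        raise ValueError(f"probs must have length K+1={design.K + 1}")
    if np.any(probs < -SIMPLEX_TOL) or abs(probs.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"allocation probabilities off the simplex: {probs}")
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()

    arms = rng.choice(design.K + 1, size=design.b, p=probs)
    z = (rng.random(design.b) < scenario.q_path.q[j - 1]).astype(np.int8)
    p = _success_matrix(j, scenario.params, design.K)[z, arms]
    y = (rng.random(design.b) < p).astype(np.int8)
    return arms.astype(np.int64), z, y


@dataclasses.dataclass
class TrialRecord:
    """A completed (or simulated) trial.

    Arrays are flat over patients in enrolment order (block-major); ``probs``
    holds the per-block allocation probabilities actually used.
    """

    design: DesignSpec
    block: np.ndarray  # (T,) 1-based block index
    arm: np.ndarray  # (T,) allocated arm, 0..K
    z: np.ndarray  # (T,) covariate
    y: np.ndarray  # (T,) outcome
    probs: np.ndarray  # (J, K+1)
    z_observed: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        T, J, K = self.design.T, self.design.J, self.design.K
        for name in ("block", "arm", "z", "y"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (T,):
                raise ValueError(f"{name} must have shape ({T},)")
            setattr(self, name, arr.astype(np.int64))
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (J, K + 1):
            raise ValueError(f"probs must have shape ({J}, {K + 1})")
        row_sums = self.probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > SIMPLEX_TOL) or np.any(self.probs < -SIMPLEX_TOL):
            raise ValueError("per-block allocation probabilities off the simplex")

    # -- summaries -----------------------------------------------------

    def arm_counts(self) -> np.ndarray:
        return np.bincount(self.arm, minlength=self.design.K + 1)

    def arm_successes(self) -> np.ndarray:
        return np.bincount(self.arm, weights=self.y, minlength=self.design.K + 1).astype(
            np.int64
        )

    def total_successes(self) -> int:
        return int(self.y.sum())

    def proportion_on_arm(self, k: int) -> float:
        return float(np.mean(self.arm == k))

    # -- serialisation -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        patient_in_block = np.concatenate(
            [np.arange(1, self.design.b + 1) for _ in range(self.design.J)]
        )
        return pd.DataFrame(
            {
                "block": self.block,
                "patient_in_block": patient_in_block,
                "arm": self.arm,
                "z": self.z,
                "y": self.y,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write patient-level CSV plus a sidecar JSON with the per-block
        allocation probabilities, design, and seed."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "design": dataclasses.asdict(self.design),
            "probs": self.probs.tolist(),
            "z_observed": self.z_observed,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialRecord":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        design = DesignSpec(**sidecar["design"])
        return cls(
            design=design,
            block=df["block"].to_numpy(),
            arm=df["arm"].to_numpy(),
            z=df["z"].to_numpy(),
            y=df["y"].to_numpy(),
            probs=np.asarray(sidecar["probs"]),
            z_observed=bool(sidecar.get("z_observed", False)),
            seed=sidecar.get("seed"),
        )
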