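"""Block-wise allocation rules: CR, Thompson sampling, RSIHR/DBCD, FLGI, CFLGI.

Every rule maps the data accumulated over blocks ``1..j-1`` (summarised as
Beta posterior pseudo-counts per arm) to a vector of allocation
probabilities ``pi_{j,k}`` for block ``j``:

- **CR** — complete randomisation, ``1/(K+1)`` throughout;
- **TS** — Thompson sampling with a tuning exponent ``c = (j-1) b / (2T)``
  applied to the posterior probability of each arm being best, so the rule
  starts uniform and grows more aggressive as data accumulate;
- **RSIHR** — the optimal allocation minimising expected failures at fixed
  estimator variance, targeted through Hu and Zhang's doubly-adaptive biased
  coin design (DBCD) with exponent ``gamma``;
- **FLGI** — the forward-looking Gittins index rule: the expected fraction
  of the next block allocated to each arm under greedy Gittins-index play,
  estimated by Monte-Carlo rollouts with virtual outcomes drawn from the
  posterior predictive;
- **CFLGI** — FLGI with the control allocation pinned at ``1/(K+1)``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize

from .gittins import GittinsTable
from .outcome_model import DesignSpec, TrialRecord

__all__ = [
    "PosteriorCounts",
    "PolicyConfig",
    "cr_policy",
    "prob_best",
    "ts_probabilities",
    "rsihr_target",
    "dbcd_probabilities",
    "flgi_probabilities",
    "cflgi_probabilities",
    "make_policy",
    "Policy",
]

RULES = ("CR", "TS", "RSIHR", "FLGI", "CFLGI")


@dataclasses.dataclass
class PosteriorCounts:
    """Per-arm Beta posterior pseudo-counts (prior included) and sample sizes."""

    s: np.ndarray  # prior_a + successes, length K+1
    f: np.ndarray  # prior_b + failures
    prior_a: float = 1.0
    prior_b: float = 1.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.s.shape != self.f.shape:
            raise ValueError("s and f must have matching shapes")
        if np.any(self.s < self.prior_a) or np.any(self.f < self.prior_b):
            raise ValueError("pseudo-counts cannot fall below the prior")

    @classmethod
    def initial(cls, design: DesignSpec) -> "PosteriorCounts":
        n = design.K + 1
        return cls(
            s=np.full(n, design.prior_a),
            f=np.full(n, design.prior_b),
            prior_a=design.prior_a,
            prior_b=design.prior_b,
        )

    @classmethod
    def from_record(cls, record: TrialRecord, up_to_block: int | None = None) -> "PosteriorCounts":
        """Counts after observing blocks ``1..up_to_block`` (all by default)."""
        design = record.design
        counts = cls.initial(design)
        mask = (
            np.ones_like(record.block, dtype=bool)
            if up_to_block is None
            else record.block <= up_to_block
        )
        counts.update(record.arm[mask], record.y[mask])
        return counts

    @property
    def n_arms(self) -> int:
        return self.s.shape[0]

    @property
    def n(self) -> np.ndarray:
        return (self.s - self.prior_a) + (self.f - self.prior_b)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.s / (self.s + self.f)

    def update(self, arms: np.ndarray, y: np.ndarray) -> None:
        np.add.at(self.s, arms, y)
        np.add.at(self.f, arms, 1 - np.asarray(y))

    def key(self) -> tuple:
        """Hashable state key used for memoisation."""
        return (tuple(self.s.tolist()), tuple(self.f.tolist()))

    def copy(self) -> "PosteriorCounts":
        return PosteriorCounts(self.s.copy(), self.f.copy(), self.prior_a, self.prior_b)


@dataclasses.dataclass
class PolicyConfig:
    """Tunables shared by the allocation rules."""

    rule: str = "CR"
    ts_mc_draws: int = 10_000
    flgi_mc_reps: int = 100
    gamma: float = 2.0
    gi_table: GittinsTable | None = None
    rsihr_form: str = "sqrt"  # "sqrt" (optimal allocation) or "ratio"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.ts_mc_draws < 1 or self.flgi_mc_reps < 1:
            raise ValueError("Monte-Carlo counts must be >= 1")


def _simplex(v: np.ndarray) -> np.ndarray:
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    total = v.sum()
    if total <= 0:
        return np.full(v.shape, 1.0 / v.size)
    return v / total


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------


def cr_policy(j: int, counts: PosteriorCounts) -> np.ndarray:
    """Complete randomisation: uniform regardless of the data."""
    n = counts.n_arms
    return np.full(n, 1.0 / n)


def prob_best(
    counts: PosteriorCounts, mc_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Posterior probability that each arm has the strictly largest success
    rate, by joint Beta posterior sampling; exact ties in a draw are broken
    uniformly at random."""
    draws = rng.beta(counts.s, counts.f, size=(mc_draws, counts.n_arms))
    best = draws.max(axis=1, keepdims=True)
    is_best = draws == best
    # break (measure-zero, but possible at degenerate states) ties at random
    weights = np.where(is_best, rng.random(draws.shape), -1.0)
    winners = np.argmax(weights, axis=1)
    return np.bincount(winners, minlength=counts.n_arms) / mc_draws


def ts_probabilities(
    j: int,
    counts: PosteriorCounts,
    design: DesignSpec,
    config: PolicyConfig,
    rng: np.random.Generator,
    c: float | None = None,
) -> np.ndarray:
    """Tuned Thompson sampling: pi_k proportional to P(arm k best)^c with
    c = (j-1) b / (2T); uniform at the first block (c = 0).  The exponent can
    be overridden via ``c`` to study the rule's aggressiveness directly."""
    if j < 1 or j > design.J:
        raise ValueError(f"block index {j} outside 1..{design.J}")
    if c is None:
        c = (j - 1) * design.b / (2.0 * design.T)
    if c == 0.0:
        return np.full(counts.n_arms, 1.0 / counts.n_arms)
    pb = prob_best(counts, config.ts_mc_draws, rng)
    powered = pb**c
    if powered.sum() <= 0.0:
        warnings.warn("all posterior-best probabilities were 0; falling back to uniform")
        return np.full(counts.n_arms, 1.0 / counts.n_arms)
    return _simplex(powered)


def rsihr_target(
    p_hat: np.ndarray, K: int, form: str = "sqrt", floor: float = 0.05
) -> np.ndarray:
    """Target allocation minimising expected failures at fixed variance.

    For ``K == 1`` the closed form is ``rho_1 = sqrt(p1) / (sqrt(p0) +
    sqrt(p1))`` (``form="ratio"`` selects the plain-ratio variant
    ``p1 / (p0 + p1)``).  For ``K > 1`` the programme is solved numerically:
    minimise ``sum_k rho_k (1 - p_k)`` subject to the control-vs-best-arm
    Wald variance being no larger than under equal allocation, with
    ``rho`` on the simplex and ``rho_k >= floor``.
    """
    p = np.asarray(p_hat, dtype=float)
    if p.shape != (K + 1,):
        raise ValueError(f"p_hat must have length K+1={K + 1}")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn("success-rate estimates outside (0,1); clamping to [0.01, 0.99]")
        p = np.clip(p, 0.01, 0.99)

    if K == 1:
        if form == "ratio":
            rho1 = p[1] / (p[0] + p[1])
        elif form == "sqrt":
            rho1 = np.sqrt(p[1]) / (np.sqrt(p[0]) + np.sqrt(p[1]))
        else:
            raise ValueError(f"unknown RSIHR form {form!r}")
        return np.array([1.0 - rho1, rho1])

    best = 1 + int(np.argmax(p[1:]))
    v = p * (1.0 - p)
    equal = np.full(K + 1, 1.0 / (K + 1))
    var_equal = v[0] / equal[0] + v[best] / equal[best]

    def objective(rho: np.ndarray) -> float:
        return float(np.dot(rho, 1.0 - p))

    constraints = [
        {"type": "eq", "fun": lambda rho: rho.sum() - 1.0},
        {"type": "ineq", "fun": lambda rho: var_equal - (v[0] / rho[0] + v[best] / rho[best])},
    ]
    res = minimize(
        objective,
        x0=equal,
        method="SLSQP",
        bounds=[(floor, 1.0)] * (K + 1),
        constraints=constraints,
    )
    rho = res.x if res.success else equal
    return _simplex(np.clip(rho, floor, None))


def dbcd_probabilities(
    j: int,
    counts: PosteriorCounts,
    p_hat: np.ndarray,
    config: PolicyConfig,
) -> np.ndarray:
    """Hu-Zhang doubly-adaptive biased coin: push the realised allocation
    proportions x toward the target rho with force gamma,
    ``pi_k \\propto rho_k (rho_k / x_k)^gamma``."""
    if j < 1:
        raise ValueError("block index must be >= 1")
    K = counts.n_arms - 1
    rho = rsihr_target(p_hat, K, form=config.rsihr_form)
    n = counts.n
    total = n.sum()
    if total <= 0 or np.any(n == 0):
        # cannot form (rho/x)^gamma with an empty arm: fall back to the target
        return rho
    x = n / total
    pi = rho * (rho / x) ** config.gamma
    return _simplex(pi)


def flgi_probabilities(
    j: int,
    counts: PosteriorCounts,
    design: DesignSpec,
    config: PolicyConfig,
    rng: np.random.Generator,
    block_size: int | None = None,
) -> np.ndarray:
    """Forward-looking Gittins index probabilities for the next block.

    Each of ``flgi_mc_reps`` rollouts allocates ``b`` virtual patients one at
    a time to the arm with the highest Gittins index (ties uniform at
    random), draws a virtual outcome from that arm's posterior-predictive
    success probability ``s/(s+f)``, and updates the virtual state;
    ``pi_k`` is the mean fraction of the block given to arm k.
    """
    table = config.gi_table
    if table is None:
        raise ValueError("FLGI requires a GittinsTable in PolicyConfig.gi_table")
    b = design.b if block_size is None else block_size
    R = config.flgi_mc_reps
    A = counts.n_arms

    S = np.tile(np.asarray(counts.s, dtype=np.int64), (R, 1))
    F = np.tile(np.asarray(counts.f, dtype=np.int64), (R, 1))
    if np.any(S != counts.s) or np.any(F != counts.f):
        raise ValueError("FLGI requires integer pseudo-counts")
    alloc = np.zeros(A, dtype=np.int64)
    rows = np.arange(R)
    for _ in range(b):
        gi = table.lookup(S, F)
        best = gi.max(axis=1, keepdims=True)
        ties = gi == best  # identical states share identical table entries
        weights = np.where(ties, rng.random((R, A)), -1.0)
        choice = np.argmax(weights, axis=1)
        s_c = S[rows, choice]
        y = rng.random(R) < s_c / (s_c + F[rows, choice])
        S[rows, choice] += y
        F[rows, choice] += ~y
        np.add.at(alloc, choice, 1)
    return alloc / (R * b)


def cflgi_probabilities(
    j: int,
    counts: PosteriorCounts,
    design: DesignSpec,
    config: PolicyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Control-protected FLGI: the control arm keeps its equal-allocation
    probability 1/(K+1) exactly; the remaining mass follows FLGI run among
    the experimental arms alone."""
    K = counts.n_arms - 1
    pi = np.empty(K + 1)
    pi[0] = 1.0 / (K + 1)
    if K == 1:
        pi[1] = 1.0 - pi[0]
        return pi
    sub = PosteriorCounts(
        counts.s[1:].copy(), counts.f[1:].copy(), counts.prior_a, counts.prior_b
    )
    sub_pi = flgi_probabilities(j, sub, design, config, rng, block_size=design.b)
    pi[1:] = (1.0 - pi[0]) * _simplex(sub_pi)
    return pi


# ---------------------------------------------------------------------------
# stateful policy objects (memoisation + reproducible per-state streams)
# ---------------------------------------------------------------------------


class Policy:
    """A seeded, memoising wrapper around one allocation rule.

    Monte-Carlo rules (TS, FLGI, CFLGI) derive an independent random stream
    from ``(seed, rule, block, state)``, so the probabilities for a given
    posterior state are reproducible regardless of evaluation order — which
    makes memoisation exact and lets randomisation-test resamples share work.
    """

    _RULE_TAGS = {name: i for i, name in enumerate(RULES)}

    def __init__(self, design: DesignSpec, config: PolicyConfig):
        if config.rule in ("FLGI", "CFLGI") and config.gi_table is None:
            raise ValueError(f"{config.rule} requires a Gittins table")
        self.design = design
        self.config = config
        self._cache: dict[tuple, np.ndarray] = {}

    @property
    def rule(self) -> str:
        return self.config.rule

    def _state_rng(self, j: int, counts: PosteriorCounts) -> np.random.Generator:
        s, f = counts.key()
        entropy = [self.config.seed, self._RULE_TAGS[self.rule], j]
        entropy += [int(v) for v in s] + [int(v) for v in f]
        return np.random.default_rng(np.random.SeedSequence(entropy))

    def probabilities(self, j: int, counts: PosteriorCounts) -> np.ndarray:
        rule = self.rule
        if rule == "CR":
            return cr_policy(j, counts)
        if rule == "RSIHR":
            p_hat = counts.posterior_mean  # prior mean at j=1, posterior after
            return dbcd_probabilities(j, counts, p_hat, self.config)

        # Monte-Carlo rules: memoise on (block, state). FLGI/CFLGI ignore j
        # in the rollout itself but the cache key keeps TS (which depends on
        # j through its tuning exponent) correct under the same machinery.
        key = (j if rule == "TS" else 0, counts.key())
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        rng = self._state_rng(key[0], counts)
        if rule == "TS":
            pi = ts_probabilities(j, counts, self.design, self.config, rng)
        elif rule == "FLGI":
            pi = flgi_probabilities(j, counts, self.design, self.config, rng)
        else:  # CFLGI
            pi = cflgi_probabilities(j, counts, self.design, self.config, rng)
        self._cache[key] = pi
        return pi


def make_policy(design: DesignSpec, config: PolicyConfig) -> Policy:
    return Policy(design, config)
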