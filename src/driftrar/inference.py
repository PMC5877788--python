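"""Hypothesis tests and model-based analyses for adaptive trials.

Provides the pooled two-proportion z-test, the Fisher exact test with a
simulation-calibrated rejection cutoff (needed because bandit-style rules
leave some arms with very small samples), Bonferroni multiplicity control,
a Monte-Carlo randomisation test that rebuilds the null distribution of the
statistic by re-running the allocation rule with outcomes pinned to patient
positions, and logistic-regression analyses with and without Firth's
Jeffreys-prior penalty (the penalty keeps estimates finite under the
complete or quasi-complete separation that aggressive adaptive rules
frequently produce).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from scipy.special import expit

from .outcome_model import DesignSpec, ScenarioSpec, TrialRecord
from .policies import Policy, PosteriorCounts

__all__ = [
    "TestResult",
    "RandTestConfig",
    "GlmFit",
    "pooled_z_test",
    "fisher_exact_test",
    "calibrate_cutoff",
    "randomisation_test",
    "bonferroni_decide",
    "fit_logistic_ml",
    "fit_logistic_firth",
]

#: absolute coefficient size beyond which a maximum-likelihood logistic fit
#: is flagged as (quasi-)separated.
SEPARATION_BOUND = 15.0


@dataclasses.dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p_value: float
    reject: bool
    alpha: float = 0.05
    sided: str = "one"
    per_arm_p: np.ndarray | None = None
    per_arm_reject: np.ndarray | None = None
    flags: tuple[str, ...] = ()


@dataclasses.dataclass
class RandTestConfig:
    """Settings for the Monte-Carlo randomisation test."""

    M: int = 500
    statistic: str = "prop_diff"  # or "pooled_z"
    sided: str = "one"
    include_observed: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.statistic not in ("prop_diff", "pooled_z"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------


def pooled_z_test(
    x0: int, n0: int, x1: int, n1: int, sided: str = "one", alpha: float = 0.05
) -> TestResult:
    """Two-proportion z-test with pooled variance; one-sided alternative is
    arm 1 better than arm 0."""
    flags: list[str] = []
    if n0 < 1 or n1 < 1:
        return TestResult(0.0, 1.0, False, alpha, sided, flags=("degenerate",))
    p0, p1 = x0 / n0, x1 / n1
    pbar = (x0 + x1) / (n0 + n1)
    if pbar in (0.0, 1.0):
        z = 0.0
        flags.append("degenerate")
    else:
        z = (p1 - p0) / np.sqrt(pbar * (1.0 - pbar) * (1.0 / n0 + 1.0 / n1))
    if sided == "one":
        p = float(stats.norm.sf(z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(float(z), p, p <= alpha, alpha, sided, flags=tuple(flags))


def fisher_exact_test(table: np.ndarray, sided: str = "one") -> float:
    """Fisher exact p-value for a 2x2 table; one-sided alternative is that
    row 0 has the higher success odds (rows are (successes, failures))."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        return 1.0
    alternative = "greater" if sided == "one" else "two-sided"
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def arm_table(record: TrialRecord, k: int) -> np.ndarray:
    """2x2 (successes, failures) table for arm ``k`` vs control."""
    counts = record.arm_counts()
    succ = record.arm_successes()
    return np.array(
        [
            [succ[k], counts[k] - succ[k]],
            [succ[0], counts[0] - succ[0]],
        ]
    )


def bonferroni_decide(p_values: np.ndarray, alpha_family: float = 0.05) -> np.ndarray:
    """Per-arm decisions controlling the family-wise error rate: reject arm k
    iff p_k <= alpha / K."""
    p = np.asarray(p_values, dtype=float)
    return p <= alpha_family / p.size


# ---------------------------------------------------------------------------
# calibrated cutoffs
# ---------------------------------------------------------------------------


def calibrate_cutoff(
    policy: Policy,
    null_scenario: ScenarioSpec,
    test,
    n_sim: int,
    alpha_target: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulation-calibrated rejection cutoff for a (typically discrete and
    miscalibrated) test under a given allocation rule.

    ``test`` maps a :class:`TrialRecord` to a p-value.  Returns the largest
    cutoff c among the simulated null p-values such that rejecting at
    ``p <= c`` keeps the simulated type-I error at or below
    ``alpha_target``; ties resolve to the smaller (conservative) cutoff.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a usable calibration")
    if not np.allclose(null_scenario.params.beta_k, 0.0):
        raise ValueError("calibration scenario must satisfy the global null")
    from .simulation import run_trial  # local import to avoid a cycle

    rng = np.random.default_rng() if rng is None else rng
    pvals = np.empty(n_sim)
    for i in range(n_sim):
        record = run_trial(policy, null_scenario, rng)
        pvals[i] = test(record)
    return cutoff_from_pvalues(pvals, alpha_target)


def cutoff_from_pvalues(pvals: np.ndarray, alpha_target: float) -> float:
    """Largest observed p-value c with mean(p <= c) <= alpha_target."""
    pvals = np.sort(np.asarray(pvals, dtype=float))
    n = pvals.size
    frac = np.arange(1, n + 1) / n
    # for tied p-values only the last index carries the true rejection mass
    last_of_value = np.r_[pvals[1:] != pvals[:-1], True]
    ok = (frac <= alpha_target) & last_of_value
    if not ok.any():
        return 0.0
    return float(pvals[np.nonzero(ok)[0][-1]])


# ---------------------------------------------------------------------------
# randomisation test
# ---------------------------------------------------------------------------


def _prop_diff(arms: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    n1 = np.count_nonzero(arms == 1)
    n0 = np.count_nonzero(arms == 0)
    if n0 == 0 or n1 == 0:
        return 0.0, True
    return float(y[arms == 1].mean() - y[arms == 0].mean()), False


def _pooled_z_stat(arms: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    n1 = np.count_nonzero(arms == 1)
    n0 = np.count_nonzero(arms == 0)
    if n0 == 0 or n1 == 0:
        return 0.0, True
    res = pooled_z_test(int(y[arms == 0].sum()), n0, int(y[arms == 1].sum()), n1)
    return res.statistic, "degenerate" in res.flags


_STATISTICS = {"prop_diff": _prop_diff, "pooled_z": _pooled_z_stat}


def randomisation_test(
    observed: TrialRecord,
    policy: Policy,
    config: RandTestConfig,
    rng: np.random.Generator,
) -> TestResult:
    """Monte-Carlo randomisation test for a 2-armed adaptive trial.

    The observed outcomes are pinned to patient positions (under the null
    they do not depend on the arm), and ``M`` re-randomised trials are
    generated by re-running the allocation rule block by block: each
    resample's block-``j`` probabilities are computed from its own
    re-randomised allocations combined with the pinned outcomes of blocks
    ``1..j-1``.  The p-value is ``(1 + #{resample stat >= observed}) /
    (M + 1)``, which is finite-sample valid for any allocation rule and any
    arm-ignoring outcome process (including arbitrary time trends).
    """
    design = observed.design
    if design.K != 1:
        raise ValueError("the randomisation test is defined for 2-armed trials")
    stat_fn = _STATISTICS[config.statistic]
    y = observed.y
    obs_stat, obs_degen = stat_fn(observed.arm, y)

    def extremity(s: float) -> float:
        return s if config.sided == "one" else abs(s)

    count = 0
    n_degen = int(obs_degen)
    arms_buf = np.empty(design.T, dtype=np.int64)
    for _ in range(config.M):
        counts = PosteriorCounts.initial(design)
        for j in range(1, design.J + 1):
            if j == 1:
                pi = np.full(design.K + 1, 1.0 / (design.K + 1))
            else:
                pi = policy.probabilities(j, counts)
            lo, hi = (j - 1) * design.b, j * design.b
            block_arms = rng.choice(design.K + 1, size=design.b, p=pi)
            arms_buf[lo:hi] = block_arms
            counts.update(block_arms, y[lo:hi])
        stat, degen = stat_fn(arms_buf, y)
        n_degen += int(degen)
        if extremity(stat) >= extremity(obs_stat):
            count += 1
    offset = 1 if config.include_observed else 0
    p = (offset + count) / (config.M + offset)
    flags = ("degenerate_resamples",) if n_degen else ()
    return TestResult(
        obs_stat, float(p), p <= config.alpha, config.alpha, config.sided, flags=flags
    )


# ---------------------------------------------------------------------------
# logistic-regression analyses
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GlmFit:
    names: tuple[str, ...]
    estimates: np.ndarray
    bse: np.ndarray
    p_values: np.ndarray
    converged: bool
    separation: bool
    penalised: bool
    degenerate: bool = False

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])


def design_matrix(
    record: TrialRecord, terms: tuple[str, ...] = ("t", "z", "arm")
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix for the outcome model: intercept plus any of the block
    trend ``t = j - 1``, the covariate ``z``, and arm indicators."""
    T, K = record.design.T, record.design.K
    cols = [np.ones(T)]
    names = ["beta0"]
    if "t" in terms:
        cols.append((record.block - 1).astype(float))
        names.append("beta_t")
    if "z" in terms:
        if not record.z_observed:
            warnings.warn("covariate z included in the model but flagged unobserved")
        cols.append(record.z.astype(float))
        names.append("beta_z")
    if "arm" in terms:
        for k in range(1, K + 1):
            cols.append((record.arm == k).astype(float))
            names.append(f"beta_{k}")
    return np.column_stack(cols), tuple(names)


def fit_logistic_ml(
    record: TrialRecord, terms: tuple[str, ...] = ("t", "z", "arm")
) -> GlmFit:
    """Maximum-likelihood logistic fit with Wald p-values.

    Separation (diverging estimates or a numerically singular information
    matrix) is flagged and the fit reported as non-converged.
    """
    import statsmodels.api as sm

    X, names = design_matrix(record, terms)
    y = record.y.astype(float)
    if y.min() == y.max():
        k = X.shape[1]
        return GlmFit(
            names, np.full(k, np.nan), np.full(k, np.nan), np.full(k, np.nan),
            converged=False, separation=False, penalised=False, degenerate=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            pvals = np.asarray(res.pvalues)
            converged = bool(res.converged)
        except Exception:
            k = X.shape[1]
            return GlmFit(
                names, np.full(k, np.nan), np.full(k, np.nan), np.full(k, np.nan),
                converged=False, separation=True, penalised=False,
            )
    separation = (
        bool(np.any(np.abs(params) > SEPARATION_BOUND))
        or bool(np.any(~np.isfinite(bse)))
        or not converged
    )
    return GlmFit(
        names, params, bse, pvals,
        converged=converged and not separation,
        separation=separation,
        penalised=False,
    )


def _penalised_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    W = mu * (1.0 - mu)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    free: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    max_step: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton iteration on Firth's modified score, optionally with some
    coefficients frozen at zero (for penalised likelihood-ratio tests).

    Returns (beta, observed information at beta, converged).
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    if not np.any(free):  # fully constrained fit: nothing to optimise
        mu = expit(X @ beta)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        return beta, X.T @ (X * W[:, None]), True
    plf = _penalised_loglik(X, y, beta)
    converged = False
    info = np.eye(k)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        XW = X * W[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        score = X.T @ (y - mu + h * (0.5 - mu))
        if np.max(np.abs(score[free])) < tol:
            converged = True
            break
        try:
            step_free = np.linalg.solve(info[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            break
        step = np.zeros(k)
        step[free] = np.clip(step_free, -max_step, max_step)
        # step-halving: the penalised log-likelihood must not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            plf_new = _penalised_loglik(X, y, cand)
            if plf_new >= plf - 1e-12:
                beta, plf = cand, plf_new
                break
            factor *= 0.5
        else:
            converged = True  # no improving step left: at the optimum
            break
    return beta, info, converged


def fit_logistic_firth(
    record: TrialRecord, terms: tuple[str, ...] = ("t", "z", "arm")
) -> GlmFit:
    """Firth-penalised logistic fit: maximises the Jeffreys-penalised
    log-likelihood ``l(beta) + 0.5 log det I(beta)``, which yields finite
    estimates even under complete separation.  P-values are penalised
    likelihood-ratio tests (each coefficient refit at zero); Wald standard
    errors from the inverse information are also reported.
    """
    X, names = design_matrix(record, terms)
    y = record.y.astype(float)
    k = X.shape[1]
    free_all = np.ones(k, dtype=bool)
    beta, info, converged = _firth_newton(X, y, free_all)
    try:
        bse = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.nan)
    plf_full = _penalised_loglik(X, y, beta)
    pvals = np.empty(k)
    for r in range(k):
        free = free_all.copy()
        free[r] = False
        start = beta.copy()
        start[r] = 0.0
        beta_r, _, _ = _firth_newton(X, y, free, beta0=start)
        lr = 2.0 * (plf_full - _penalised_loglik(X, y, beta_r))
        pvals[r] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return GlmFit(
        names, beta, bse, pvals,
        converged=converged, separation=False, penalised=True,
    )
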