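"""Gittins indices for Bernoulli reward processes with Beta posteriors.

The Gittins index nu(s, f) of an arm in posterior state Beta(s, f) is the
retirement rate lambda at which pulling the arm once more (and then behaving
optimally) is exactly as valuable as retiring on a known arm paying lambda
per period, under geometric discounting d.  Greedy play of the index is the
optimal policy for the classic discounted multi-armed bandit, and it is the
engine behind the forward-looking (FLGI/CFLGI) allocation rules.

Computation is by calibration: for a candidate lambda, the value of the
one-armed stopping problem is found by backward induction over the triangular
lattice of posterior states, truncated at a depth where the discount weight
is negligible; bisection on lambda locates the indifference point.  Building
a whole table exploits the fact that one backward induction over the full
lattice classifies *every* state as continue-or-retire for that lambda, so a
dyadic sweep of lambda values resolves all states simultaneously.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

__all__ = ["GittinsTable", "gittins_index", "build_gi_table"]

#: default discount factor, as used for forward-looking Gittins rules in the
#: block-randomised bandit design literature.
DEFAULT_DISCOUNT = 0.995

#: default bisection tolerance on lambda.
DEFAULT_TOL = 1e-4

#: discount-weight threshold that sets the default truncation horizon:
#: the smallest N with d**N below this value.
HORIZON_WEIGHT = 1e-4


def default_horizon(discount: float, weight: float = HORIZON_WEIGHT) -> int:
    if discount <= 0.0:
        return 1
    return max(1, int(math.ceil(math.log(weight) / math.log(discount))))


def _check_state(s: float, f: float, discount: float) -> None:
    if s <= 0 or f <= 0:
        raise ValueError(f"pseudo-counts must be positive, got s={s}, f={f}")
    if not (0.0 <= discount < 1.0):
        raise ValueError(f"discount must lie in [0, 1), got {discount}")


def _root_value(s: int, f: int, lam: float, d: float, horizon: int) -> tuple[float, float]:
    """Value of the optimal-stopping problem rooted at (s, f) with forced
    retirement after ``horizon`` pulls; returns (value, retirement value)."""
    retire = lam / (1.0 - d)
    # states at depth n are (s+i, f+n-i), i = 0..n
    V = np.full(horizon + 1, retire)
    for n in range(horizon - 1, -1, -1):
        i = np.arange(n + 1)
        succ = s + i
        mass = s + f + n
        p = succ / mass
        cont = p * (1.0 + d * V[i + 1]) + (1.0 - p) * d * V[i]
        V = np.maximum(retire, cont)
    return float(V[0]), retire


def gittins_index(
    s: int,
    f: int,
    discount: float = DEFAULT_DISCOUNT,
    horizon: int | None = None,
    tol: float = DEFAULT_TOL,
) -> float:
    """Gittins index of a Bernoulli arm in posterior state Beta(s, f).

    With ``discount == 0`` the index reduces to the posterior mean
    ``s / (s + f)``.  The truncation ``horizon`` defaults to the smallest N
    with ``discount**N < 1e-4``.
    """
    _check_state(s, f, discount)
    if discount == 0.0:
        return s / (s + f)
    if horizon is None:
        horizon = default_horizon(discount)
    lo = s / (s + f)  # the index never falls below the posterior mean
    hi = 1.0
    while hi - lo > tol:
        lam = 0.5 * (lo + hi)
        value, retire = _root_value(s, f, lam, discount, horizon)
        if value > retire:
            lo = lam
        else:
            hi = lam
    return 0.5 * (lo + hi)


def _classify_lattice(
    lam: float, d: float, max_mass: int, horizon: int
) -> np.ndarray:
    """One backward induction over the full lattice for a fixed lambda.

    Returns a boolean array ``cont[s, f]`` (valid for s, f >= 1 and
    s + f <= max_mass) that is True where continuation is strictly preferred
    to retiring at rate lambda.
    """
    L = max_mass + horizon  # boundary mass: forced retirement
    retire = lam / (1.0 - d) if d > 0 else lam
    cont_flags = np.zeros((max_mass + 1, max_mass + 1), dtype=bool)
    V = np.full(L - 1, retire)  # states (s, L - s), s = 1..L-1
    for m in range(L - 1, 1, -1):
        s = np.arange(1, m)
        p = s / m
        # from (s, m-s): success -> (s+1, .) at mass m+1 -> index s;
        # failure -> (s, .) at mass m+1 -> index s-1 (arrays are 0-based on s-1)
        cont = p * (1.0 + d * V[1:m]) + (1.0 - p) * d * V[0 : m - 1]
        if m <= max_mass:
            cont_flags[s, m - s] = cont > retire
        V = np.maximum(retire, cont)
    return cont_flags


@dataclasses.dataclass
class GittinsTable:
    """Precomputed Gittins indices on the lattice ``s + f <= max_mass``.

    ``grid[s, f]`` holds nu(s, f); entries outside the lattice are NaN.
    """

    discount: float
    horizon: int
    tol: float
    max_depth: int
    grid: np.ndarray

    @property
    def max_mass(self) -> int:
        return self.grid.shape[0] - 1

    def value(self, s: int, f: int) -> float:
        if s < 1 or f < 1 or s + f > self.max_mass:
            raise KeyError(f"state ({s}, {f}) outside table (max mass {self.max_mass})")
        v = self.grid[s, f]
        if np.isnan(v):
            raise KeyError(f"state ({s}, {f}) missing from table")
        return float(v)

    def lookup(self, s: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Vectorised lookup; raises if any requested state is uncovered."""
        s = np.asarray(s)
        f = np.asarray(f)
        if np.any(s + f > self.max_mass) or np.any(s < 1) or np.any(f < 1):
            raise KeyError("Gittins table too shallow for a requested state")
        v = self.grid[s, f]
        if np.isnan(v).any():
            raise KeyError("Gittins table too shallow for a requested state")
        return v

    # -- serialisation -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        entries = [
            {"s": int(s), "f": int(f), "value": float(self.grid[s, f])}
            for s in range(1, self.max_mass)
            for f in range(1, self.max_mass + 1 - s)
            if not np.isnan(self.grid[s, f])
        ]
        payload = {
            "discount": self.discount,
            "horizon": self.horizon,
            "tol": self.tol,
            "max_depth": self.max_depth,
            "entries": entries,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GittinsTable":
        payload = json.loads(Path(path).read_text())
        max_mass = max(e["s"] + e["f"] for e in payload["entries"])
        grid = np.full((max_mass + 1, max_mass + 1), np.nan)
        for e in payload["entries"]:
            grid[e["s"], e["f"]] = e["value"]
        return cls(
            discount=payload["discount"],
            horizon=payload["horizon"],
            tol=payload["tol"],
            max_depth=payload["max_depth"],
            grid=grid,
        )


def build_gi_table(
    max_depth: int,
    discount: float = DEFAULT_DISCOUNT,
    horizon: int | None = None,
    tol: float = DEFAULT_TOL,
    prior_mass: int = 2,
) -> GittinsTable:
    """Build a table of indices for all states with ``s + f <= max_depth +
    prior_mass`` (so a trial of ``max_depth`` patients starting from a
    uniform prior never leaves the lattice).

    Uses a shared dyadic bisection: each candidate lambda costs one backward
    induction over the whole lattice and tightens the bracket of every state
    whose current interval straddles it.
    """
    if max_depth < 2:
        raise ValueError("max_depth must be >= 2")
    if not (0.0 <= discount < 1.0):
        raise ValueError(f"discount must lie in [0, 1), got {discount}")
    max_mass = max_depth + prior_mass
    if horizon is None:
        horizon = default_horizon(discount)

    s_idx, f_idx = np.meshgrid(
        np.arange(max_mass + 1), np.arange(max_mass + 1), indexing="ij"
    )
    valid = (s_idx >= 1) & (f_idx >= 1) & (s_idx + f_idx <= max_mass)
    grid = np.full((max_mass + 1, max_mass + 1), np.nan)

    if discount == 0.0:
        grid[valid] = (s_idx / np.maximum(s_idx + f_idx, 1))[valid]
        return GittinsTable(discount, horizon, tol, max_depth, grid)

    lo = np.where(valid, s_idx / np.maximum(s_idx + f_idx, 1), np.nan)
    hi = np.where(valid, 1.0, np.nan)

    depth = max(1, int(math.ceil(math.log2(1.0 / tol))))
    for level in range(1, depth + 1):
        step = 0.5**level
        lams = np.arange(1, 2**level, 2) * step  # odd dyadic points at this level
        with np.errstate(invalid="ignore"):
            width = hi - lo
        for lam in lams:
            with np.errstate(invalid="ignore"):
                needs = valid & (lo < lam) & (lam < hi) & (width > tol)
            if not needs.any():
                continue
            cont = _classify_lattice(float(lam), discount, max_mass, horizon)
            lo = np.where(needs & cont, lam, lo)
            hi = np.where(needs & ~cont, lam, hi)
            with np.errstate(invalid="ignore"):
                width = hi - lo

    grid[valid] = (0.5 * (lo + hi))[valid]
    return GittinsTable(discount, horizon, tol, max_depth, grid)
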