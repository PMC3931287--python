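"""Classical (frequentist) LQAS design machinery.

An LQAS survey samples ``n`` individuals from a supervision area and counts
successes ``X ~ Binomial(n, p)``.  The area is classified as achieving the
benchmark when ``X > d``.  The pair ``(n, d)`` is chosen so that the two
misclassification risks

* ``alpha = P(X <= d | p = p_u)`` — classifying a genuinely high-coverage
  area as low, and
* ``beta  = P(X > d | p = p_l)`` — classifying a genuinely low-coverage
  area as high,

stay below user-specified maxima.  Coverages between ``p_l`` and ``p_u``
form the *grey region*, where neither risk is controlled.

This module solves for the smallest such ``(n, d)`` and produces the
operating-characteristic (OC) and risk curves that summarise a design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec",
    "Design",
    "ProbabilityCurve",
    "InfeasibleDesignError",
    "acceptance_probability",
    "classification_risks",
    "solve_design",
    "oc_curve",
    "risk_curve",
]


class InfeasibleDesignError(ValueError):
    """No (n, d) pair satisfies both risk constraints within the search bound."""


def _check_unit_open(value: float, name: str) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1); got {value!r}")


@dataclass(frozen=True)
class DesignSpec:
    """The four risk parameters of an LQAS design plus an optional target.

    Parameters
    ----------
    p_l, p_u
        Lower and upper coverage thresholds delimiting the grey region;
        ``p_l < p_u`` and both strictly inside (0, 1).
    alpha_max
        Maximum tolerated risk of classifying an area with true coverage
        ``p_u`` as failing the benchmark.
    beta_max
        Maximum tolerated risk of classifying an area with true coverage
        ``p_l`` as achieving the benchmark.
    p_star
        Optional programmatic target separating "correct" from "incorrect"
        classification when evaluating the design; usually ``p_l`` or ``p_u``.
    """

    p_l: float
    p_u: float
    alpha_max: float
    beta_max: float
    p_star: Optional[float] = None

    def __post_init__(self) -> None:
        _check_unit_open(self.p_l, "p_l")
        _check_unit_open(self.p_u, "p_u")
        _check_unit_open(self.alpha_max, "alpha_max")
        _check_unit_open(self.beta_max, "beta_max")
        if self.p_star is not None:
            _check_unit_open(self.p_star, "p_star")
        if not self.p_l < self.p_u:
            raise ValueError(
                f"p_l must be smaller than p_u; got p_l={self.p_l}, p_u={self.p_u}"
            )


@dataclass(frozen=True)
class Design:
    """A solved LQAS design: sample size, decision rule, achieved risks."""

    n: int
    d: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size n must be >= 1; got {self.n}")
        if not (-1 <= self.d <= self.n):
            raise ValueError(f"decision rule d must lie in [-1, n]; got {self.d}")


@dataclass(frozen=True)
class ProbabilityCurve:
    """A probability evaluated on an increasing grid of coverages.

    ``label`` is ``"oc"`` for acceptance curves and ``"risk"`` for
    misclassification curves.
    """

    p: np.ndarray
    probability: np.ndarray
    label: str = field(default="oc")

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        prob = np.asarray(self.probability, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "probability", prob)
        if p.ndim != 1 or p.shape != prob.shape:
            raise ValueError("grid and probabilities must be matching 1-d arrays")
        if not np.all(np.diff(p) > 0):
            raise ValueError("coverage grid must be strictly increasing")
        if np.any((prob < -1e-12) | (prob > 1 + 1e-12)):
            raise ValueError("curve probabilities must lie within [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.p, "probability": self.probability})

    def to_csv(self, path) -> None:
        """Write the curve as two-column CSV (p, probability)."""
        self.to_frame().to_csv(path, index=False)


def _validate_rule(n: int, d: int) -> None:
    if n < 1:
        raise ValueError(f"sample size n must be >= 1; got {n}")
    if not (-1 <= d <= n):
        raise ValueError(f"decision rule d must lie in [-1, {n}]; got {d}")


def acceptance_probability(n: int, d: int, p) -> float | np.ndarray:
    """P(X > d) for X ~ Binomial(n, p): the chance of classifying as high.

    Evaluated with the binomial survival function, so it is stable for
    large ``n``.  ``d = -1`` (always accept) and ``d = n`` (never accept)
    are admitted as degenerate rules.  ``p`` may be a scalar or array.
    """
    _validate_rule(n, d)
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError(f"coverage p must lie in [0, 1]; got {p!r}")
    out = stats.binom.sf(d, n, p_arr)
    return float(out) if np.isscalar(p) else out


def classification_risks(n: int, d: int, spec: DesignSpec) -> tuple[float, float]:
    """Achieved risks (alpha, beta) of the rule (n, d) at the design thresholds.

    ``alpha = P(X <= d | n, p_u)`` and ``beta = P(X > d | n, p_l)``.
    """
    _validate_rule(n, d)
    alpha = float(stats.binom.cdf(d, n, spec.p_u))
    beta = float(stats.binom.sf(d, n, spec.p_l))
    return alpha, beta


def _feasible_rules(n: int, spec: DesignSpec) -> np.ndarray:
    """All decision rules d in [-1, n] meeting both risk constraints at n."""
    d = np.arange(-1, n + 1)
    alpha = stats.binom.cdf(d, n, spec.p_u)
    beta = stats.binom.sf(d, n, spec.p_l)
    return d[(alpha <= spec.alpha_max) & (beta <= spec.beta_max)]

def solve_design(spec: DesignSpec, n_max: int = 1000) -> Design:
    """Smallest-n design meeting both risk constraints.

    Searches ``n`` ascending from 1; at the first ``n`` admitting a feasible
    decision rule, returns the ``d`` minimising ``max(alpha, beta)``, ties
    broken toward smaller ``d``.  Because the binomial tails are evaluated at
    two distinct proportions, feasibility is not monotone in ``n`` (a
    saw-tooth), so the minimal feasible ``n`` can be followed by infeasible
    sizes; the returned design is minimal nonetheless.

    Raises
    ------
    InfeasibleDesignError
        If no ``n <= n_max`` admits a feasible rule.  The message names the
        constraint gap at ``n_max``.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1; got {n_max}")
    for n in range(1, n_max + 1):
        feasible = _feasible_rules(n, spec)
        if feasible.size == 0:
            continue
        risks = [classification_risks(n, int(d), spec) for d in feasible]
        worst = [max(a, b) for a, b in risks]
        i = int(np.argmin(worst))  # argmin keeps the first (smallest d) on ties
        alpha, beta = risks[i]
        return Design(n=n, d=int(feasible[i]), alpha=alpha, beta=beta)
    # diagnose which constraint blocks at n_max
    d = np.arange(-1, n_max + 1)
    alpha_ok = stats.binom.cdf(d, n_max, spec.p_u) <= spec.alpha_max
    beta_ok = stats.binom.sf(d, n_max, spec.p_l) <= spec.beta_max
    d_hi = int(d[alpha_ok].max()) if alpha_ok.any() else None
    d_lo = int(d[beta_ok].min()) if beta_ok.any() else None
    raise InfeasibleDesignError(
        f"no (n, d) with n <= {n_max} satisfies alpha <= {spec.alpha_max} and "
        f"beta <= {spec.beta_max}: at n = {n_max} the alpha constraint at "
        f"p_u = {spec.p_u} allows d <= {d_hi} while the beta constraint at "
        f"p_l = {spec.p_l} requires d >= {d_lo}"
    )


def _even_grid(grid_size: int) -> np.ndarray:
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2; got {grid_size}")
    return np.linspace(0.0, 1.0, grid_size)


def oc_curve(n: int, d: int, grid_size: int = 101) -> ProbabilityCurve:
    """Operating-characteristic curve P(X > d | p) over an even grid on [0, 1]."""
    grid = _even_grid(grid_size)
    return ProbabilityCurve(grid, acceptance_probability(n, d, grid), label="oc")


def risk_curve(n: int, d: int, p_star: float, grid_size: int = 101) -> ProbabilityCurve:
    """Probability of incorrect classification as a function of true coverage.

    Below the programmatic target ``p_star`` a "high" classification is the
    error, so the curve is ``P(X > d | p)``; at and above ``p_star`` a "low"
    classification is the error, giving ``P(X <= d | p)``.  The boundary
    point ``p == p_star`` is assigned to the latter branch.
    """
    _check_unit_open(p_star, "p_star")
    _validate_rule(n, d)
    grid = _even_grid(grid_size)
    accept = stats.binom.sf(d, n, grid)
    risk = np.where(grid < p_star, accept, 1.0 - accept)
    return ProbabilityCurve(grid, risk, label="risk")
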