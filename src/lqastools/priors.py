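"""Beta coverage distributions and how to obtain them.

The distribution of true coverage across supervision areas (SAs) is modelled
as a Beta(a, b).  A prior can be elicited from a stated mean and standard
deviation, shifted or rescaled from another prior, or fitted to a past
survey's per-SA counts.  Fits are offered on four routes:

``betabinomial_moments`` (default)
    Match the mean and (population) variance of the counts to the
    beta-binomial moments.  Requires a common ``n`` and genuine
    overdispersion relative to the binomial; closed form, no optimizer.
    Working on the counts rather than the proportions deconvolves the
    binomial sampling noise, so the implied Beta spread is the spread of
    the coverages themselves.
``betabinomial_mle``
    Maximise the beta-binomial likelihood of the raw counts ``(X_i, n_i)``.
    Shares the moment fit's deconvolution property and remains well defined
    when an observed proportion hits 0 or 1, at the cost of an optimizer.
``proportions_mle``
    Maximise the Beta likelihood of the observed proportions, clipped a
    hair's breadth away from {0, 1} where the log-likelihood diverges.
``moments``
    Moment-match the empirical mean and (m-1 denominator) standard deviation
    of the observed proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BetaPrior",
    "SurveyTable",
    "FitConvergenceError",
    "beta_from_mean_sd",
    "prior_interval_mass",
    "prior_survivor",
    "shift_prior",
    "fit_beta",
    "FIT_METHODS",
]

#: clipping margin for proportions exactly at 0 or 1 under ``proportions_mle``
PROPORTION_CLIP = 1e-6

FIT_METHODS = ("betabinomial_moments", "betabinomial_mle", "proportions_mle", "moments")


class FitConvergenceError(RuntimeError):
    """A prior fit failed to converge or the data admit no Beta fit."""


@dataclass(frozen=True)
class BetaPrior:
    """A Beta(a, b) distribution of true coverage across SAs."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Beta shapes must be positive; got a={self.a}, b={self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def pdf(self, x) -> np.ndarray:
        return stats.beta.pdf(x, self.a, self.b)

    def interval_mass(self, lo: float, hi: float) -> float:
        return prior_interval_mass(self, lo, hi)

    def survivor(self, p_star: float) -> float:
        return prior_survivor(self, p_star)

    def __str__(self) -> str:  # e.g. "Beta(9.66, 8.69)"
        return f"Beta({self.a:g}, {self.b:g})"


@dataclass(frozen=True)
class SurveyTable:
    """Per-SA survey counts: identifiers, successes X_i, sample sizes n_i."""

    sa_id: tuple[str, ...]
    successes: np.ndarray
    sampled: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sa_id)
        x = np.asarray(self.successes, dtype=int)
        n = np.asarray(self.sampled, dtype=int)
        object.__setattr__(self, "sa_id", ids)
        object.__setattr__(self, "successes", x)
        object.__setattr__(self, "sampled", n)
        if len(ids) == 0:
            raise ValueError("a survey table needs at least one row")
        if not (len(ids) == x.size == n.size):
            raise ValueError("sa_id, successes and sampled must have equal length")
        if np.any(n < 1):
            bad = int(np.flatnonzero(n < 1)[0])
            raise ValueError(f"row {bad} ({ids[bad]}): sampled must be >= 1")
        if np.any((x < 0) | (x > n)):
            bad = int(np.flatnonzero((x < 0) | (x > n))[0])
            raise ValueError(
                f"row {bad} ({ids[bad]}): successes must lie in [0, sampled]; "
                f"got {int(x[bad])} of {int(n[bad])}"
            )

    @property
    def m(self) -> int:
        """Number of supervision areas (rows)."""
        return len(self.sa_id)

    @property
    def proportions(self) -> np.ndarray:
        """Observed per-SA proportions X_i / n_i in row order."""
        return self.successes / self.sampled

    def subset(self, rows: Sequence[int]) -> "SurveyTable":
        rows = np.asarray(rows, dtype=int)
        return SurveyTable(
            tuple(self.sa_id[i] for i in rows),
            self.successes[rows],
            self.sampled[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sa_id": self.sa_id, "successes": self.successes, "sampled": self.sampled}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurveyTable":
        return cls(
            tuple(frame["sa_id"].astype(str)),
            frame["successes"].to_numpy(),
            frame["sampled"].to_numpy(),
        )

    @classmethod
    def from_counts(
        cls, successes: Iterable[int], sampled, prefix: str = "SA"
    ) -> "SurveyTable":
        """Build a table from counts; ``sampled`` may be a scalar common n."""
        x = np.asarray(list(successes), dtype=int)
        n = np.broadcast_to(np.asarray(sampled, dtype=int), x.shape).copy()
        ids = tuple(f"{prefix}{i + 1}" for i in range(x.size))
        return cls(ids, x, n)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyTable):
            return NotImplemented
        return (
            self.sa_id == other.sa_id
            and np.array_equal(self.successes, other.successes)
            and np.array_equal(self.sampled, other.sampled)
        )


def beta_from_mean_sd(mean: float, sd: float) -> BetaPrior:
    """Moment-matched Beta(a, b) with the given mean and standard deviation.

    Solves ``a + b = mean (1 - mean) / sd^2 - 1`` and ``a = mean (a + b)``.
    A Beta distribution with mean ``m`` cannot have variance at or above
    ``m (1 - m)``; such inputs raise a ``ValueError``.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean must lie strictly inside (0, 1); got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be positive; got {sd}")
    limit = mean * (1.0 - mean)
    if sd * sd >= limit:
        raise ValueError(
            f"no Beta distribution has mean {mean} with sd {sd}: "
            f"variance must be below mean*(1-mean) = {limit:.6g}"
        )
    total = limit / (sd * sd) - 1.0
    return BetaPrior(a=mean * total, b=(1.0 - mean) * total)


def prior_interval_mass(prior: BetaPrior, lo: float, hi: float) -> float:
    """P(lo < p < hi) under the prior: a regularised incomplete-beta difference."""
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"need 0 <= lo <= hi <= 1; got lo={lo}, hi={hi}")
    return float(
        stats.beta.cdf(hi, prior.a, prior.b) - stats.beta.cdf(lo, prior.a, prior.b)
    )


def prior_survivor(prior: BetaPrior, p_star: float) -> float:
    """P(p > p_star) under the prior."""
    if not (0.0 <= p_star <= 1.0):
        raise ValueError(f"p_star must lie in [0, 1]; got {p_star}")
    return float(stats.beta.sf(p_star, prior.a, prior.b))


def shift_prior(
    prior: BetaPrior, new_mean: float | None = None, sd_scale: float = 1.0
) -> BetaPrior:
    """Re-elicit a prior with a shifted mean and/or rescaled spread.

    Keeps the current mean when ``new_mean`` is None and multiplies the
    standard deviation by ``sd_scale``; the result is moment-matched, so
    ``sd_scale = 1`` with the same mean is the identity.
    """
    if sd_scale <= 0:
        raise ValueError(f"sd_scale must be positive; got {sd_scale}")
    mean = prior.mean if new_mean is None else new_mean
    return beta_from_mean_sd(mean, sd_scale * prior.sd)


def _maximize(nll, start: tuple[float, float]) -> BetaPrior:
    """Minimise a negative log-likelihood over log-shape parameters."""
    res = optimize.minimize(
        lambda t: nll(np.exp(t[0]), np.exp(t[1])),
        np.log(start),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitConvergenceError(f"beta fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    return BetaPrior(float(a), float(b))


def _moment_start(props: np.ndarray) -> tuple[float, float]:
    try:
        prior = beta_from_mean_sd(
            float(np.clip(props.mean(), 1e-3, 1 - 1e-3)),
            float(props.std(ddof=1)),
        )
        return prior.a, prior.b
    except ValueError:
        return 1.0, 1.0


def fit_beta(survey: SurveyTable, method: str = "betabinomial_moments") -> BetaPrior:
    """Best-fitting Beta coverage distribution for a past survey.

    See the module docstring for the four routes.  Degenerate data (all
    observed proportions identical) leave the overdispersion unidentified
    and raise :class:`FitConvergenceError`, as does optimizer failure —
    never a silent fallback.
    """
    if method not in FIT_METHODS:
        raise ValueError(f"unknown fit method {method!r}; choose from {FIT_METHODS}")
    if survey.m < 2:
        raise ValueError("fitting a coverage distribution needs at least two SAs")
    props = survey.proportions
    if np.allclose(props, props[0]):
        raise FitConvergenceError(
            "all observed proportions are identical; the spread of the "
            "coverage distribution is not identifiable"
        )

    if method == "moments":
        mean = float(props.mean())
        sd = float(props.std(ddof=1))
        try:
            return beta_from_mean_sd(mean, sd)
        except ValueError as err:
            raise FitConvergenceError(str(err)) from err

    if method == "proportions_mle":
        clipped = np.clip(props, PROPORTION_CLIP, 1.0 - PROPORTION_CLIP)

        def nll(a: float, b: float) -> float:
            return -float(np.sum(stats.beta.logpdf(clipped, a, b)))

        return _maximize(nll, _moment_start(props))

    if method == "betabinomial_moments":
        return _betabinomial_moments(survey)

    x, n = survey.successes, survey.sampled

    def nll(a: float, b: float) -> float:
        return -float(
            np.sum(
                special.betaln(a + x, b + n - x)
                - special.betaln(a, b)
            )
        )

    try:
        start = _betabinomial_moments(survey)
        start_ab = (start.a, start.b)
    except (FitConvergenceError, ValueError):
        start_ab = _moment_start(props)
    return _maximize(nll, start_ab)


def _betabinomial_moments(survey: SurveyTable) -> BetaPrior:
    """Beta-binomial method-of-moments fit on the raw counts.

    Uses the population (m-denominator) variance of the counts and requires
    a common per-SA sample size.  The intraclass correlation
    ``rho = 1 / (a + b + 1)`` is identified from the variance inflation of
    the counts over the binomial.
    """
    n_unique = np.unique(survey.sampled)
    if n_unique.size != 1:
        raise FitConvergenceError(
            "the beta-binomial moment fit needs a common sample size per SA"
        )
    n = int(n_unique[0])
    if n < 2:
        raise FitConvergenceError("moment fit needs n >= 2 to see overdispersion")
    x = survey.successes.astype(float)
    p_bar = x.mean() / n
    if not 0.0 < p_bar < 1.0:
        raise FitConvergenceError("pooled proportion at 0 or 1; no Beta fit exists")
    var_x = x.var(ddof=0)
    inflation = var_x / (n * p_bar * (1.0 - p_bar))
    rho = (inflation - 1.0) / (n - 1.0)
    if rho <= 0.0:
        raise FitConvergenceError(
            "counts are not overdispersed relative to the binomial; "
            "the implied Beta spread is zero or negative"
        )
    if rho >= 1.0:
        raise FitConvergenceError("implied intraclass correlation is >= 1")
    total = 1.0 / rho - 1.0
    return BetaPrior(a=p_bar * total, b=(1.0 - p_bar) * total)
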