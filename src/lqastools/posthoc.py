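"""Post-survey estimation of the coverage distribution across SAs.

After a survey, the observed proportions ``X_i / n_i`` are point estimates
of the per-SA coverages.  The distribution of true coverage is estimated
three ways — a crude histogram (empirical fraction of point estimates in an
interval), a Gaussian kernel density with a deliberately narrow bandwidth,
and a parametric Beta fit — and interval probabilities such as the
grey-region mass carry bootstrap standard errors from resampling SAs.

Interval conventions
--------------------
Histogram intervals are half-open ``[lo, hi)`` so a partition of [0, 1]
sums to exactly one, except that an interval ending at 1 is closed so the
final bin keeps proportions equal to 1.  The kernel estimator integrates
untruncated Gaussian bumps over ``(lo, hi)`` with no boundary correction
or renormalisation to [0, 1].

Bandwidth
---------
Silverman's rule of thumb ``0.9 min(s, IQR/1.34) m^(-1/5)`` (sample sd with
m-1 denominator, quartiles by linear interpolation) is shrunk by a further
``m^(-0.3)`` to prioritise small bias over smoothness when the number of
SAs is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .priors import FitConvergenceError, SurveyTable, fit_beta, prior_interval_mass

__all__ = [
    "DensityEstimate",
    "BootstrapSummary",
    "observed_proportions",
    "histogram_interval_prob",
    "kde_bandwidth",
    "kde_interval_prob",
    "beta_fit_interval_prob",
    "bootstrap_se",
    "density_curves",
    "ESTIMATORS",
]

ESTIMATORS = ("histogram", "kernel", "beta")


@dataclass(frozen=True)
class BootstrapSummary:
    """A point estimate with its bootstrap standard error.

    ``n_failed`` counts replicates on which the estimator could not be
    evaluated (e.g. a degenerate resample for the kernel bandwidth or a
    non-convergent Beta fit); those are excluded from the standard error.
    """

    estimate: float
    se: float
    replicates: int
    n_failed: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_failed > self.replicates:
            raise ValueError("n_failed cannot exceed the number of replicates")
        if self.se < 0:
            raise ValueError("a standard error cannot be negative")


def observed_proportions(survey: SurveyTable) -> np.ndarray:
    """Per-SA coverage point estimates X_i / n_i in row order."""
    return survey.proportions


def _check_interval(lo: float, hi: float) -> None:
    if not lo < hi:
        raise ValueError(f"need lo < hi; got lo={lo}, hi={hi}")


def _in_interval(props: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (props >= lo) & (props < hi)
    if hi >= 1.0:  # the bin touching 1 is closed on the right
        mask |= props == hi
    return mask


def histogram_interval_prob(survey: SurveyTable, lo: float, hi: float) -> float:
    """Crude-histogram mass: the fraction of SAs with X_i/n_i in [lo, hi)."""
    _check_interval(lo, hi)
    props = survey.proportions
    return float(_in_interval(props, lo, hi).sum()) / survey.m


def kde_bandwidth(props) -> float:
    """Silverman rule-of-thumb bandwidth times m^(-0.3).

    ``0.9 min(s, IQR/1.34) m^(-1/5) * m^(-0.3)`` with the sample standard
    deviation (m-1 denominator) and linearly interpolated quartiles.
    """
    props = np.asarray(props, dtype=float)
    m = props.size
    if m < 2:
        raise ValueError("bandwidth selection needs at least two proportions")
    s = float(props.std(ddof=1))
    q1, q3 = np.percentile(props, [25, 75])  # linear interpolation
    h = 0.9 * min(s, (q3 - q1) / 1.34) * m ** (-0.2)
    if h <= 0.0:
        raise ValueError(
            "degenerate spread: the Silverman bandwidth is zero "
            "(identical proportions or collapsed interquartile range)"
        )
    return h * m ** (-0.3)


def kde_interval_prob(
    survey: SurveyTable, lo: float, hi: float, bandwidth: float | None = None
) -> float:
    """Mass of the Gaussian kernel density over (lo, hi).

    Averages ``Phi((hi - p_i)/bw) - Phi((lo - p_i)/bw)`` over the observed
    proportions.  The mixture is untruncated: mass spilling outside [0, 1]
    is neither reflected nor renormalised.  ``bandwidth`` overrides the
    rule-of-thumb value when given.
    """
    _check_interval(lo, hi)
    props = survey.proportions
    bw = kde_bandwidth(props) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise ValueError(f"bandwidth must be positive; got {bw}")
    return float(
        np.mean(stats.norm.cdf((hi - props) / bw) - stats.norm.cdf((lo - props) / bw))
    )


def beta_fit_interval_prob(
    survey: SurveyTable, lo: float, hi: float, method: str = "betabinomial_moments"
) -> float:
    """Interval mass of a Beta distribution fitted to the survey.

    ``method`` is forwarded to :func:`lqastools.priors.fit_beta`; fit
    failures propagate as :class:`FitConvergenceError`.
    """
    _check_interval(lo, hi)
    prior = fit_beta(survey, method=method)
    return prior_interval_mass(prior, max(lo, 0.0), min(hi, 1.0))


_ESTIMATOR_FUNCS = {
    "histogram": histogram_interval_prob,
    "kernel": kde_interval_prob,
    "beta": beta_fit_interval_prob,
}


def bootstrap_se(
    survey: SurveyTable,
    estimator: str,
    lo: float,
    hi: float,
    B: int = 1000,
    seed: int | None = None,
) -> BootstrapSummary:
    """Bootstrap standard error of an interval-probability estimator.

    Resamples the SAs (rows) with replacement ``B`` times and re-evaluates
    the estimator on each replicate — the kernel bandwidth is recomputed
    and the Beta refitted per replicate.  Replicates where the estimator
    fails are counted in ``n_failed`` and excluded from the standard
    error.  The same seed reproduces the same summary exactly.
    """
    if estimator not in _ESTIMATOR_FUNCS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if B < 2:
        raise ValueError(f"bootstrap needs B >= 2 replicates; got {B}")
    if seed is None:
        raise ValueError("a seed is required so bootstrap results are reproducible")
    func = _ESTIMATOR_FUNCS[estimator]
    point = func(survey, lo, hi)
    rng = np.random.default_rng(seed)
    values = []
    n_failed = 0
    for _ in range(B):
        rows = rng.integers(0, survey.m, survey.m)
        try:
            values.append(func(survey.subset(rows), lo, hi))
        except (ValueError, FitConvergenceError):
            n_failed += 1
    if not values:
        raise FitConvergenceError(
            f"all {B} bootstrap replicates failed for the {estimator} estimator"
        )
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return BootstrapSummary(
        estimate=point, se=se, replicates=B, n_failed=n_failed, seed=int(seed)
    )


@dataclass(frozen=True)
class DensityEstimate:
    """A fitted coverage density with interval-probability queries."""

    method: str
    survey: SurveyTable
    bandwidth: float | None = None
    fit_method: str = "betabinomial_moments"

    def __post_init__(self) -> None:
        if self.method not in ESTIMATORS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {ESTIMATORS}"
            )

    def interval_probability(self, lo: float, hi: float) -> float:
        if self.method == "histogram":
            return histogram_interval_prob(self.survey, lo, hi)
        if self.method == "kernel":
            return kde_interval_prob(self.survey, lo, hi, bandwidth=self.bandwidth)
        return beta_fit_interval_prob(self.survey, lo, hi, method=self.fit_method)


def density_curves(
    survey: SurveyTable,
    grid_size: int = 201,
    n_bins: int | None = None,
    fit_method: str = "betabinomial_moments",
) -> pd.DataFrame:
    """Histogram, kernel and fitted-Beta densities on an even grid over [0, 1].

    Returns a tidy frame with columns ``method``, ``p``, ``density`` for
    external plotting.  The histogram uses ``n_bins`` equal-width bins on
    [0, 1] (Sturges' count by default) rendered as step heights; its step
    areas integrate to one.  A failed Beta fit simply omits the ``beta``
    curve rather than aborting the other two.
    """
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2; got {grid_size}")
    props = survey.proportions
    grid = np.linspace(0.0, 1.0, grid_size)
    if n_bins is None:
        n_bins = int(np.ceil(np.log2(survey.m) + 1))
    heights, edges = np.histogram(props, bins=n_bins, range=(0.0, 1.0), density=True)
    idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, n_bins - 1)
    pieces = [pd.DataFrame({"method": "histogram", "p": grid, "density": heights[idx]})]

    bw = kde_bandwidth(props)
    kde = np.mean(stats.norm.pdf((grid[:, None] - props[None, :]) / bw), axis=1) / bw
    pieces.append(pd.DataFrame({"method": "kernel", "p": grid, "density": kde}))

    try:
        prior = fit_beta(survey, method=fit_method)
    except FitConvergenceError:
        prior = None
    if prior is not None:
        pieces.append(
            pd.DataFrame({"method": "beta", "p": grid, "density": prior.pdf(grid)})
        )
    return pd.concat(pieces, ignore_index=True)
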