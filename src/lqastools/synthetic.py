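"""Synthetic surveys with the structure the post-survey estimators assume.

True coverages are drawn from a Beta coverage distribution and counts from
conditionally independent binomials: ``p_i ~ Beta(a, b)``,
``X_i ~ Binomial(n, p_i)``.  The simulation harness replays the post-survey
estimators over many such surveys to measure their finite-sample bias and
spread against the closed-form truth of the generating prior — small
numbers of SAs and small per-SA samples both bias every estimator, which
is the regime the Nepal geometry (m = 7, n = 19) sits in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posthoc import (
    beta_fit_interval_prob,
    bootstrap_se,
    histogram_interval_prob,
    kde_interval_prob,
)
from .priors import BetaPrior, FitConvergenceError, SurveyTable

__all__ = ["SimulationResult", "generate_survey", "simulation_study"]

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


@dataclass(frozen=True)
class SimulationResult:
    """Bias/spread summary of the post-survey estimators on synthetic data.

    ``frame`` is tidy: one row per (estimator, quantity) with the
    closed-form truth, mean estimate, bias, empirical sd over replicates,
    mean bootstrap se (NaN when bootstrapping was disabled) and the number
    of replicates on which the estimator failed.
    """

    frame: pd.DataFrame
    reps: int
    prior: BetaPrior
    m: int
    n: int
    seed: int
    B: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def generate_survey(prior: BetaPrior, m: int, n: int, seed) -> SurveyTable:
    """One synthetic survey: m SAs, n sampled per SA, coverages from the prior.

    ``seed`` may be an integer, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`; the same seed yields the same table.
    """
    if m < 1 or n < 1:
        raise ValueError(f"need m >= 1 and n >= 1; got m={m}, n={n}")
    rng = np.random.default_rng(seed)
    p = rng.beta(prior.a, prior.b, size=m)
    x = rng.binomial(n, p)
    return SurveyTable.from_counts(x, n)


def _interval_estimates(
    survey: SurveyTable, intervals: dict[str, tuple[float, float]]
) -> dict[tuple[str, str], float | None]:
    out: dict[tuple[str, str], float | None] = {}
    for qty, (lo, hi) in intervals.items():
        for est, func in (
            ("histogram", histogram_interval_prob),
            ("kernel", kde_interval_prob),
            ("beta", beta_fit_interval_prob),
        ):
            try:
                out[(est, qty)] = func(survey, lo, hi)
            except (ValueError, FitConvergenceError):
                out[(est, qty)] = None
    return out


def simulation_study(
    prior: BetaPrior,
    m: int = 7,
    n: int = 19,
    reps: int = 500,
    B: int = 0,
    seed: int = 0,
    p_l: float = 0.35,
    p_u: float = 0.65,
) -> SimulationResult:
    """Monte-Carlo bias study of the three density estimators.

    For each replicate a survey is generated from the prior and the
    histogram, kernel and Beta estimators are evaluated for the three
    target probabilities ``P(p < p_l)``, ``P(p > p_u)`` and
    ``P(p_l < p < p_u)``; their truths come from the generating Beta.
    With ``B >= 2`` each replicate additionally carries a bootstrap
    standard error (expensive; disabled by default with ``B = 0``).

    A single root seed spawns one substream per replicate, so results do
    not depend on evaluation order.  Estimator failures are counted per
    cell, never fatal.
    """
    if reps < 2:
        raise ValueError(f"need reps >= 2 to average over replicates; got {reps}")
    if not 0 < p_l < p_u < 1:
        raise ValueError(f"need 0 < p_l < p_u < 1; got {p_l}, {p_u}")
    intervals = {"low": (0.0, p_l), "grey": (p_l, p_u), "high": (p_u, 1.0)}
    truths = {qty: prior.interval_mass(lo, hi) for qty, (lo, hi) in intervals.items()}

    root = np.random.SeedSequence(seed)
    children = root.spawn(reps)
    estimates: dict[tuple[str, str], list[float]] = {
        (est, qty) for est in ("histogram", "kernel", "beta") for qty in intervals
    }
    estimates = {key: [] for key in estimates}
    boot_ses: dict[tuple[str, str], list[float]] = {key: [] for key in estimates}
    failures = {key: 0 for key in estimates}

    for child in children:
        survey = generate_survey(prior, m, n, child)
        values = _interval_estimates(survey, intervals)
        for key, value in values.items():
            if value is None:
                failures[key] += 1
            else:
                estimates[key].append(value)
        if B >= 2:
            boot_seed = int(child.generate_state(1)[0] % (2**31))
            for (est, qty), value in values.items():
                if value is None:
                    continue
                lo, hi = intervals[qty]
                try:
                    summary = bootstrap_se(survey, est, lo, hi, B=B, seed=boot_seed)
                    boot_ses[(est, qty)].append(summary.se)
                except (ValueError, FitConvergenceError):
                    pass

    rows = []
    for (est, qty), values in estimates.items():
        mean_est = float(np.mean(values)) if values else np.nan
        sd_est = float(np.std(values, ddof=1)) if len(values) > 1 else np.nan
        ses = boot_ses[(est, qty)]
        rows.append(
            {
                "estimator": est,
                "quantity": qty,
                "truth": truths[qty],
                "mean_estimate": mean_est,
                "bias": mean_est - truths[qty],
                "sd": sd_est,
                "mean_boot_se": float(np.mean(ses)) if ses else np.nan,
                "n_failed": failures[(est, qty)],
            }
        )
    order = {"histogram": 0, "kernel": 1, "beta": 2}
    rows.sort(key=lambda r: (order[r["estimator"]], r["quantity"]))
    frame = pd.DataFrame(rows)
    return SimulationResult(
        frame=frame, reps=reps, prior=prior, m=m, n=n, seed=seed, B=B
    )
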