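"""Bayesian accuracy of a frequentist LQAS design.

With true coverage ``p ~ Beta(a, b)`` and ``X | p ~ Binomial(n, p)``, the
marginal count ``X`` is beta-binomial and the coverage posterior after
observing ``X = k`` is ``Beta(a + k, b + n - k)``.  Every quantity here —
positive and negative predictive value with respect to a programmatic
target ``p*``, grey-region probabilities conditional on the classification,
and the Bayesian risks — is therefore a ratio of finite sums of
beta-binomial probabilities times incomplete-beta tails.  This conjugate
closed form is exact up to floating point; no quadrature is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, _validate_rule
from .priors import BetaPrior

__all__ = [
    "AccuracyReport",
    "marginal_acceptance",
    "ppv",
    "npv",
    "grey_given_classification",
    "bayes_risks",
    "accuracy_report",
]


def _betabinom_pmf(n: int, prior: BetaPrior) -> np.ndarray:
    """pmf of the beta-binomial count over k = 0..n."""
    k = np.arange(n + 1)
    return stats.betabinom.pmf(k, n, prior.a, prior.b)


def _posterior_survivor(n: int, prior: BetaPrior, p_star: float) -> np.ndarray:
    """P(p > p_star | X = k) for k = 0..n under the conjugate posterior."""
    k = np.arange(n + 1)
    return stats.beta.sf(p_star, prior.a + k, prior.b + n - k)


def _posterior_interval(n: int, prior: BetaPrior, lo: float, hi: float) -> np.ndarray:
    k = np.arange(n + 1)
    a, b = prior.a + k, prior.b + n - k
    return stats.beta.cdf(hi, a, b) - stats.beta.cdf(lo, a, b)


def _conditional(
    n: int, d: int, prior: BetaPrior, event: np.ndarray, accepted: bool
) -> float:
    """P(event about p | classification), with event given per count k."""
    _validate_rule(n, d)
    pmf = _betabinom_pmf(n, prior)
    k = np.arange(n + 1)
    side = k > d if accepted else k <= d
    denom = float(pmf[side].sum())
    if denom <= 0.0:
        label = "accepts" if accepted else "rejects"
        raise ValueError(
            f"the design (n={n}, d={d}) never {label}; the conditional "
            "probability is undefined"
        )
    return float(np.dot(pmf[side], event[side])) / denom


def marginal_acceptance(n: int, d: int, prior: BetaPrior) -> float:
    """P(X > d) when the coverage is drawn from the prior (beta-binomial tail)."""
    _validate_rule(n, d)
    pmf = _betabinom_pmf(n, prior)
    return float(pmf[np.arange(n + 1) > d].sum())


def ppv(n: int, d: int, p_star: float, prior: BetaPrior) -> float:
    """Positive predictive value: P(p > p_star | X > d)."""
    if not (0.0 <= p_star <= 1.0):
        raise ValueError(f"p_star must lie in [0, 1]; got {p_star}")
    return _conditional(n, d, prior, _posterior_survivor(n, prior, p_star), True)


def npv(n: int, d: int, p_star: float, prior: BetaPrior) -> float:
    """Negative predictive value: P(p < p_star | X <= d)."""
    if not (0.0 <= p_star <= 1.0):
        raise ValueError(f"p_star must lie in [0, 1]; got {p_star}")
    event = 1.0 - _posterior_survivor(n, prior, p_star)
    return _conditional(n, d, prior, event, False)


def grey_given_classification(
    n: int, d: int, p_l: float, p_u: float, prior: BetaPrior, accepted: bool
) -> float:
    """P(p_l < p < p_u | classification): grey-region mass given the decision."""
    if not p_l < p_u:
        raise ValueError(f"p_l must be smaller than p_u; got {p_l}, {p_u}")
    event = _posterior_interval(n, prior, p_l, p_u)
    return _conditional(n, d, prior, event, accepted)


def bayes_risks(
    n: int, d: int, p_l: float, p_u: float, prior: BetaPrior
) -> tuple[float, float]:
    """Bayesian risks (alpha_B, beta_B) of the classification rule.

    ``alpha_B = P(p >= p_u | X <= d)``: the area was classified low but its
    coverage is at or above the upper threshold.  ``beta_B = P(p <= p_l |
    X > d)``: classified high with coverage at or below the lower threshold.
    The boundary points carry zero mass under a continuous Beta prior, so
    the weak inequalities are numerically indistinguishable from strict
    ones; they are kept as stated.
    """
    if not p_l < p_u:
        raise ValueError(f"p_l must be smaller than p_u; got {p_l}, {p_u}")
    alpha_b = _conditional(n, d, prior, _posterior_survivor(n, prior, p_u), False)
    beta_b = _conditional(n, d, prior, 1.0 - _posterior_survivor(n, prior, p_l), True)
    return alpha_b, beta_b


@dataclass(frozen=True)
class AccuracyReport:
    """Classification-accuracy summary of one design under several priors.

    One row per prior; for each of ``p* = p_l`` and ``p* = p_u`` the prior
    survivor S(p*), PPV and NPV, then the grey-region mass, the grey mass
    conditional on each classification, and the Bayesian risks.
    """

    n: int
    d: int
    p_l: float
    p_u: float
    frame: pd.DataFrame

    COLUMNS = (
        "prior",
        "S_pl",
        "ppv_pl",
        "npv_pl",
        "S_pu",
        "ppv_pu",
        "npv_pu",
        "p_grey",
        "grey_given_accept",
        "grey_given_reject",
        "alpha_B",
        "beta_B",
    )

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """The report rendered at fixed precision (3 decimals by default)."""
        out = self.frame.copy()
        num = out.columns.drop("prior")
        out[num] = out[num].round(decimals)
        return out

    def to_csv(self, path, decimals: int = 3) -> None:
        self.rounded(decimals).to_csv(path, index=False)

    def to_json(self, path=None) -> str | None:
        """Full-precision machine-readable report."""
        payload = self.frame.to_json(orient="records", double_precision=15)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload)
        return None


def accuracy_report(
    n: int,
    d: int,
    spec: DesignSpec,
    priors: Sequence[BetaPrior],
    labels: Sequence[str] | None = None,
) -> AccuracyReport:
    """Evaluate a design's classification accuracy under a list of priors.

    For each prior the report carries, at both thresholds, the prior mass
    above the target, PPV and NPV; plus the grey-region probabilities and
    Bayesian risks.  All entries come from the conjugate closed form.
    """
    priors = list(priors)
    if not priors:
        raise ValueError("accuracy_report needs at least one prior")
    if labels is None:
        labels = [str(p) for p in priors]
    if len(labels) != len(priors):
        raise ValueError("labels and priors must have equal length")
    rows = []
    for label, prior in zip(labels, priors):
        alpha_b, beta_b = bayes_risks(n, d, spec.p_l, spec.p_u, prior)
        row = {"prior": label}
        for tag, p_star in (("pl", spec.p_l), ("pu", spec.p_u)):
            row[f"S_{tag}"] = prior.survivor(p_star)
            row[f"ppv_{tag}"] = ppv(n, d, p_star, prior)
            row[f"npv_{tag}"] = npv(n, d, p_star, prior)
        row["p_grey"] = prior.interval_mass(spec.p_l, spec.p_u)
        row["grey_given_accept"] = grey_given_classification(
            n, d, spec.p_l, spec.p_u, prior, accepted=True
        )
        row["grey_given_reject"] = grey_given_classification(
            n, d, spec.p_l, spec.p_u, prior, accepted=False
        )
        row["alpha_B"] = alpha_b
        row["beta_B"] = beta_b
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(AccuracyReport.COLUMNS))
    return AccuracyReport(n=n, d=d, p_l=spec.p_l, p_u=spec.p_u, frame=frame)
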