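"""Information criteria and per-replicate ranking of candidate models.

All seven selection criteria used in the study share the "lower is better"
convention: the four information criteria (AIC, AICc, BIC, HQ) score
penalized badness of fit, and the three out-of-sample criteria (LOO-CV,
blocked CV, population MSPE) score squared prediction error.  ``T`` in the
sample-size-dependent penalties is the number of *predictable* time points
(series length minus one), the observation count the conditional likelihood
is computed over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


__all__ = [
    "IC_CRITERIA",
    "CV_CRITERIA",
    "ALL_CRITERIA",
    "CriterionValue",
    "Ranking",
    "aic",
    "aicc",
    "bic",
    "hq",
    "ic_value",
    "rank_models",
]

IC_CRITERIA = ("AIC", "AICc", "HQ", "BIC")
CV_CRITERIA = ("LOOCV", "BlockedCV")
ALL_CRITERIA = IC_CRITERIA + CV_CRITERIA + ("OOS",)


def aic(loglik: float, p: float) -> float:
    """Akaike information criterion: -2 loglik + 2p."""
    if p < 1:
        raise ValueError("parameter count must be >= 1")
    return -2.0 * loglik + 2.0 * p

def aicc(loglik: float, p: float, T: int) -> float:
    """Small-sample-corrected AIC: AIC + 2p(p+1)/(T-p-1)."""
    if T <= p + 1:
        raise ValueError("AICc correction undefined: T must exceed p + 1")
    return aic(loglik, p) + 2.0 * p * (p + 1.0) / (T - p - 1.0)

def bic(loglik: float, p: float, T: int) -> float:
    """Bayesian information criterion: -2 loglik + log(T) p."""
    if p < 1:
        raise ValueError("parameter count must be >= 1")
    if T < 2:
        raise ValueError("BIC requires T >= 2")
    return -2.0 * loglik + math.log(T) * p

def hq(loglik: float, p: float, T: int) -> float:
    """Hannan-Quinn criterion: -2 loglik + 2 log(log(T)) p."""
    if p < 1:
        raise ValueError("parameter count must be >= 1")
    if T <= math.e:
        raise ValueError("HQ requires T > e so that log(log(T)) is positive")
    return -2.0 * loglik + 2.0 * math.log(math.log(T)) * p


def ic_value(criterion: str, loglik: float, p: float, T: int) -> float:
    """Evaluate one of the four information criteria by name."""
    if criterion == "AIC":
        return aic(loglik, p)
    if criterion == "AICc":
        return aicc(loglik, p, T)
    if criterion == "BIC":
        return bic(loglik, p, T)
    if criterion == "HQ":
        return hq(loglik, p, T)
    raise ValueError(f"unknown information criterion {criterion!r}")


@dataclass(frozen=True)
class CriterionValue:
    """One (candidate, criterion, value) triple; ``value=None`` marks a
    failed or unavailable fit.  ``p`` is carried along for tie-breaking."""

    candidate: str
    criterion: str
    value: float | None
    p: float = math.nan

    @property
    def missing(self) -> bool:
        return self.value is None or (isinstance(self.value, float) and math.isnan(self.value))


@dataclass
class Ranking:
    """Ordered candidates for one criterion on one replicate (rank 1 = best)."""

    criterion: str
    order: list  # candidate names, best first
    ranks: dict  # candidate -> rank (permutation of 1..len(order))
    rank_of_true: int | None = None
    replicate: int | None = None


def rank_models(values: list, true_candidate: str | None = None, replicate: int | None = None) -> Ranking:
    """Rank candidates by ascending criterion value.

    Missing (failed) candidates are placed after all ranked ones; exact
    ties are broken by smaller parameter count, then lexicographically by
    candidate name, so the ranking is a deterministic permutation.
    """
    if not values:
        raise ValueError("no criterion values to rank")
    criteria = {v.criterion for v in values}
    if len(criteria) != 1:
        raise ValueError("rank_models expects values for a single criterion")
    if all(v.missing for v in values):
        raise ValueError("all candidates missing; nothing to rank")

    def key(v: CriterionValue):
        val = math.inf if v.missing else float(v.value)
        pk = math.inf if math.isnan(v.p) else v.p
        return (v.missing, val, pk, v.candidate)

    ordered = sorted(values, key=key)
    order = [v.candidate for v in ordered]
    ranks = {name: i + 1 for i, name in enumerate(order)}
    rank_of_true = ranks.get(true_candidate) if true_candidate is not None else None
    return Ranking(
        criterion=values[0].criterion,
        order=order,
        ranks=ranks,
        rank_of_true=rank_of_true,
        replicate=replicate,
    )
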