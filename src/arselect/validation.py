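"""Out-of-sample selection criteria: cross-validation and population MSPE.

Two cross-validation schemes estimate a candidate's one-step mean squared
prediction error from a single series:

* leave-one-out (LOO) removes one predictable observation at a time *as a
  regression target only* -- its observed value remains available as the
  lag regressor of its successor -- refits the candidate, and predicts the
  held-out value from the training fit and the observed lag;
* blocked CV partitions the time axis 1..T into K contiguous blocks of
  near-equal length (earlier blocks take any remainder) and holds out all
  predictable targets inside one block per fold.  With K = T-1 the scheme
  reduces exactly to LOO.

Candidates are fully refitted on every fold (the Markov-switching
candidates via EM with the held-out rows masked out of the likelihood;
their held-out predictions come from the forward filter run over the
observed past with frozen parameters).  Both schemes are deterministic
functions of (series, candidate, scheme, K) up to the EM restart seed.

The population MSPE evaluates a *fitted* model on a long, independently
generated series from the true process (default length 100,000), giving a
near-exact measure of out-of-sample predictive accuracy that is available
only in simulation settings where the generating process is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import ConditionSpec, GeneratedSeries, generate_series
from .estimators import (
    DegenerateSeriesError,
    EMConfig,
    FittedModel,
    fit_candidate,
    predict_one_step,
)

__all__ = [
    "CVError",
    "CVResult",
    "PopulationSeries",
    "loo_cv",
    "blocked_cv",
    "make_population",
    "oos_mspe",
]

#: study default: population series length for the out-of-sample criterion
POPULATION_SIZE = 100_000

#: folds are skipped when the training fit degenerates; more than this
#: fraction of skipped target points invalidates the CV value
MAX_SKIP_FRACTION = 0.2


class CVError(RuntimeError):
    """Raised when too many folds fail for the CV value to be meaningful."""


@dataclass
class CVResult:
    """Mean squared held-out one-step error, CV(1), for one candidate."""

    scheme: str           # "loo" or "blocked"
    K: int                # number of folds
    cv_value: float       # mean of squared held-out errors
    n_predicted: int      # held-out points actually predicted
    n_skipped: int = 0    # held-out points lost to degenerate training folds

    def __post_init__(self) -> None:
        if self.cv_value < 0:
            raise ValueError("cv_value must be non-negative")


@dataclass
class PopulationSeries:
    """A long series from the true process, independent of all training data."""

    values: np.ndarray
    condition: ConditionSpec
    seed: int


def _time_blocks(T: int, K: int) -> list:
    """Partition the time axis 1..T into K contiguous blocks (1-based,
    inclusive bounds); earlier blocks take the remainder."""
    if not 2 <= K <= T - 1:
        raise ValueError("K must be between 2 and T-1")
    base, extra = divmod(T, K)
    blocks = []
    start = 1
    for i in range(K):
        size = base + (1 if i < extra else 0)
        blocks.append((start, start + size - 1))
        start += size
    return blocks


def _cv(name: str, y: np.ndarray, K: int, scheme: str, seed, em_config) -> CVResult:
    y = np.asarray(y, dtype=float)
    T = y.size
    blocks = _time_blocks(T, K)
    n_rows = T - 1
    sq_errors: list = []
    n_skipped = 0
    for lo, hi in blocks:
        # held-out target rows: predictable points t in [lo, hi] (t >= 2);
        # row index i corresponds to target t = i + 2
        held = np.zeros(n_rows, dtype=bool)
        i_lo = max(lo, 2) - 2
        i_hi = hi - 2
        if i_hi < i_lo:
            continue  # block contains no predictable target (only t = 1)
        held[i_lo : i_hi + 1] = True
        train_mask = ~held
        try:
            model = fit_candidate(name, y, mask=train_mask, seed=seed, em_config=em_config)
        except DegenerateSeriesError:
            n_skipped += int(held.sum())
            continue
        yhat = predict_one_step(model, y)
        err = y[1:][held] - yhat[held]
        sq_errors.append(err**2)
    n_predicted = sum(e.size for e in sq_errors)
    if n_skipped > MAX_SKIP_FRACTION * n_rows or n_predicted == 0:
        raise CVError(
            f"{n_skipped} of {n_rows} held-out points lost to degenerate training folds"
        )
    cv_value = float(np.concatenate(sq_errors).mean())
    return CVResult(scheme=scheme, K=K, cv_value=cv_value, n_predicted=n_predicted, n_skipped=n_skipped)


def loo_cv(name: str, y, seed=0, em_config: EMConfig | None = None) -> CVResult:
    """Leave-one-out CV(1) for one candidate (full refit per fold)."""
    y = np.asarray(y, dtype=float)
    return _cv(name, y, y.size - 1, "loo", seed, em_config)


def blocked_cv(name: str, y, K: int = 10, seed=0, em_config: EMConfig | None = None) -> CVResult:
    """K-block CV(1) for one candidate (full refit per fold; K=10 in the study)."""
    return _cv(name, np.asarray(y, dtype=float), K, "blocked", seed, em_config)


def make_population(condition: ConditionSpec, size: int = POPULATION_SIZE, seed=0) -> PopulationSeries:
    """Generate the 'population' series used by the out-of-sample criterion."""
    gen: GeneratedSeries = generate_series(condition, size, seed)
    return PopulationSeries(values=gen.values, condition=condition, seed=gen.seed)


def oos_mspe(model: FittedModel, population: PopulationSeries | np.ndarray) -> float:
    """Mean squared one-step prediction error of a fitted model on the
    population series (frozen parameters, all predictable points)."""
    values = population.values if isinstance(population, PopulationSeries) else np.asarray(population, dtype=float)
    yhat = predict_one_step(model, values)
    err = values[1:] - yhat
    return float(np.mean(err**2))
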