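"""Synthetic time-series generation for AR(1)-based (non)stationary processes.

Nine data-generating processes are supported, all built on the lag-1
autoregression ``y_t = intercept(t) + phi(t) * y_{t-1} + eps_t``:

* ``white_noise`` -- i.i.d. innovations (AR(1) with phi = 0);
* ``ar1`` -- stationary AR(1);
* ``random_walk`` -- unit root (phi = 1);
* ``ar1_trend`` -- AR(1) plus a linear deterministic trend ``beta * t``;
* ``tvar_intercept`` / ``tvar_phi`` -- time-varying AR(1) where the
  intercept or the autoregressive coefficient follows
  ``amplitude * sin(2 pi t / T)`` (one full period over the series);
* ``setar`` -- two-regime self-exciting threshold AR(1), switching on
  whether ``y_{t-1} <= tau``;
* ``hmm`` -- two white-noise regimes with different means, switching
  deterministically at fixed time points;
* ``rs_ar1`` -- two AR(1) regimes, switching deterministically at fixed
  time points.

Innovations are unit-variance normal by default; a skew-normal family
(location xi, scale omega, slant ``shape``) is available to emulate the
positively skewed distributions typical of negative-affect measures.

The condition registry enumerates the 33 study conditions (31 with normal
innovations plus 2 skew-normal ones) used by the Monte-Carlo harness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODELS",
    "InvalidSpecError",
    "InnovationSpec",
    "ConditionSpec",
    "GeneratedSeries",
    "draw_innovations",
    "generate_series",
    "condition_registry",
    "get_condition",
    "registry_to_json",
    "read_series",
]

#: the nine data-generating (and candidate) model names
MODELS = (
    "white_noise",
    "ar1",
    "random_walk",
    "ar1_trend",
    "tvar_intercept",
    "tvar_phi",
    "setar",
    "hmm",
    "rs_ar1",
)


class InvalidSpecError(ValueError):
    """Raised for an invalid innovation or condition specification."""


@dataclass(frozen=True)
class InnovationSpec:
    """Distribution of the innovation term eps_t.

    Parameters
    ----------
    family : {"normal", "skew_normal"}
    location : float
        Location xi (0 in all study conditions).
    scale : float
        Scale omega (> 0); the normal family draws N(location, scale^2).
    shape : float
        Skew-normal slant; ignored for the normal family.  A large positive
        value (the study uses 40) gives a near-half-normal, strongly
        right-skewed distribution.
    """

    family: str = "normal"
    location: float = 0.0
    scale: float = 1.0
    shape: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "skew_normal"):
            raise InvalidSpecError(f"unknown innovation family {self.family!r}")
        if not self.scale > 0:
            raise InvalidSpecError(f"innovation scale must be positive, got {self.scale}")


NORMAL_INNOVATIONS = InnovationSpec()
SKEWED_INNOVATIONS = InnovationSpec(family="skew_normal", location=0.0, scale=2.0, shape=40.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One data-generating configuration (one registry row).

    Only the fields relevant to ``model`` are meaningful; the remaining
    fields keep their neutral defaults.  Regime models store per-regime
    values as tuples; ``switch_points`` holds switch times as fractions of
    the series length.
    """

    model: str
    label: str
    intercepts: tuple = (0.0,)
    ar_coefficients: tuple = (0.0,)
    trend_slope: float = 0.0
    sine_amplitude: float = 0.0
    threshold: float | None = None
    regime_means: tuple | None = None
    switch_points: tuple = ()
    innovation: InnovationSpec = field(default_factory=InnovationSpec)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InvalidSpecError(f"unknown model {self.model!r}")
        for f in self.switch_points:
            if not 0.0 < f < 1.0:
                raise InvalidSpecError("switch points must be fractions in (0, 1)")
        if self.model in ("white_noise", "ar1", "ar1_trend", "tvar_intercept"):
            if abs(self.ar_coefficients[0]) >= 1:
                raise InvalidSpecError("stationary AR conditions require |phi| < 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["innovation"] = asdict(self.innovation)
        return d


@dataclass
class GeneratedSeries:
    """A simulated series with its provenance.

    ``values`` holds the observations (1-based time index ``t = 1..T`` is
    implicit in position); ``regime_path`` records the generating regime
    (1 or 2) per time point for setar/hmm/rs_ar1 conditions.
    """

    values: np.ndarray
    condition: ConditionSpec
    regime_path: np.ndarray | None
    seed: int

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": np.arange(1, len(self.values) + 1), "y": self.values})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_series(path) -> np.ndarray:
    """Read a two-column ``t,y`` CSV written by :meth:`GeneratedSeries.write_csv`."""
    frame = pd.read_csv(path)
    return frame["y"].to_numpy(dtype=float)


def draw_innovations(n: int, spec: InnovationSpec, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. innovations from ``spec``; same seed, same vector."""
    if n < 0:
        raise ValueError("n must be non-negative")
    # spec validity re-checked so dicts built outside the dataclass still fail loudly
    if not spec.scale > 0:
        raise InvalidSpecError("innovation scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "normal":
        return rng.normal(spec.location, spec.scale, size=n)
    return np.atleast_1d(
        stats.skewnorm.rvs(spec.shape, loc=spec.location, scale=spec.scale, size=n, random_state=rng)
    )


def _deterministic_regimes(T: int, switch_points: tuple) -> np.ndarray:
    """Regime index (1/2) per time point for fixed switch schedules.

    A switch scheduled at fraction f takes effect from t = ceil(f*T)
    onward; the series starts in regime 1.
    """
    t = np.arange(1, T + 1)
    switches = np.sort([math.ceil(f * T) for f in switch_points])
    n_past = np.searchsorted(switches, t, side="right")
    return 1 + (n_past % 2)


def generate_series(condition: ConditionSpec, T: int, seed) -> GeneratedSeries:
    """Simulate a series of length ``T`` from ``condition``.

    The first value is drawn as ``intercept(1) / (1 - phi(1))`` plus one
    innovation for stationary processes, and as a single innovation for the
    random walk and the regime models; no burn-in is used, so the output
    length is exactly ``T``.
    """
    if T < 2:
        raise ValueError("series length must be at least 2")
    eps = draw_innovations(T, condition.innovation, seed)
    m = condition.model
    y = np.empty(T, dtype=float)
    regime: np.ndarray | None = None

    if m == "white_noise":
        y[:] = eps
    elif m == "random_walk":
        y[:] = np.cumsum(eps)
    elif m in ("ar1", "ar1_trend"):
        alpha = condition.intercepts[0]
        phi = condition.ar_coefficients[0]
        beta = condition.trend_slope if m == "ar1_trend" else 0.0
        y[0] = (alpha + beta * 1) / (1.0 - phi) + eps[0]
        for t in range(1, T):
            y[t] = alpha + beta * (t + 1) + phi * y[t - 1] + eps[t]
    elif m == "tvar_intercept":
        alpha = condition.intercepts[0]
        phi = condition.ar_coefficients[0]
        amp = condition.sine_amplitude
        tt = np.arange(1, T + 1)
        intercept = alpha + amp * np.sin(2.0 * np.pi * tt / T)
        y[0] = intercept[0] / (1.0 - phi) + eps[0]
        for t in range(1, T):
            y[t] = intercept[t] + phi * y[t - 1] + eps[t]
    elif m == "tvar_phi":
        alpha = condition.intercepts[0]
        phi = condition.ar_coefficients[0]
        amp = condition.sine_amplitude
        tt = np.arange(1, T + 1)
        phis = phi + amp * np.sin(2.0 * np.pi * tt / T)
        y[0] = alpha / (1.0 - phis[0]) + eps[0]
        for t in range(1, T):
            y[t] = alpha + phis[t] * y[t - 1] + eps[t]
    elif m == "setar":
        tau = condition.threshold
        a = condition.intercepts
        phi = condition.ar_coefficients
        regime = np.ones(T, dtype=int)
        y[0] = eps[0]
        for t in range(1, T):
            r = 0 if y[t - 1] <= tau else 1
            regime[t] = r + 1
            y[t] = a[r] + phi[r] * y[t - 1] + eps[t]
    elif m == "hmm":
        regime = _deterministic_regimes(T, condition.switch_points)
        means = condition.regime_means
        y[0] = eps[0]
        for t in range(1, T):
            y[t] = means[regime[t] - 1] + eps[t]
    elif m == "rs_ar1":
        regime = _deterministic_regimes(T, condition.switch_points)
        a = condition.intercepts if len(condition.intercepts) == 2 else (0.0, 0.0)
        phi = condition.ar_coefficients
        y[0] = eps[0]
        for t in range(1, T):
            r = regime[t] - 1
            y[t] = a[r] + phi[r] * y[t - 1] + eps[t]
    else:  # pragma: no cover - guarded by ConditionSpec
        raise InvalidSpecError(f"unknown model {m!r}")

    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return GeneratedSeries(values=y, condition=condition, regime_path=regime, seed=int(seed_int))


# ---------------------------------------------------------------------------
# Condition registry: the 33 study conditions
# ---------------------------------------------------------------------------

def _ar1(phi: float, label: str, innovation=NORMAL_INNOVATIONS) -> ConditionSpec:
    model = "white_noise" if phi == 0.0 else "ar1"
    return ConditionSpec(model=model, label=label, ar_coefficients=(phi,), innovation=innovation)


def _trend(beta: float, phi: float, label: str, innovation=NORMAL_INNOVATIONS) -> ConditionSpec:
    return ConditionSpec(
        model="ar1_trend", label=label, trend_slope=beta, ar_coefficients=(phi,), innovation=innovation
    )


def condition_registry() -> list[ConditionSpec]:
    """The 33 simulation conditions, in registry row order.

    31 normal-innovation conditions varying the process type, the average
    autocorrelation and the extent of nonstationarity, plus two skew-normal
    conditions (AR(1) with phi=.3 and AR(1)+trend with beta=.1, phi=.3).
    """
    conds: list[ConditionSpec] = []
    conds.append(_ar1(0.0, "white_noise"))
    conds.append(_ar1(0.3, "ar1_phi.3"))
    conds.append(_ar1(0.7, "ar1_phi.7"))
    conds.append(ConditionSpec(model="random_walk", label="random_walk", ar_coefficients=(1.0,)))
    conds += [
        _trend(0.1, 0.3, "trend_b.1_phi.3"),
        _trend(0.5, 0.3, "trend_b.5_phi.3"),
        _trend(0.1, 0.7, "trend_b.1_phi.7"),
        _trend(0.5, 0.7, "trend_b.5_phi.7"),
    ]
    for phi in (0.3, 0.7):
        for amp in (0.5, 2.5):
            conds.append(
                ConditionSpec(
                    model="tvar_intercept",
                    label=f"tvar_int_a{amp}_phi{phi}",
                    ar_coefficients=(phi,),
                    sine_amplitude=amp,
                )
            )
    for phi in (0.3, 0.7):
        for amp in (0.05, 0.25):
            conds.append(
                ConditionSpec(
                    model="tvar_phi",
                    label=f"tvar_phi_a{amp}_phi{phi}",
                    ar_coefficients=(phi,),
                    sine_amplitude=amp,
                )
            )
    setar_rows = [
        ((1.0, 2.0), (0.4, 0.4), "setar_int"),
        ((1.0, 1.0), (0.8, 0.4), "setar_ar"),
        ((1.0, 2.0), (0.8, 0.4), "setar_both"),
    ]
    for intercepts, phis, label in setar_rows:
        conds.append(
            ConditionSpec(
                model="setar",
                label=label,
                intercepts=intercepts,
                ar_coefficients=phis,
                threshold=3.0,
            )
        )
    for switches, tag in (((0.5,), "sw1"), ((0.25, 0.5, 0.75), "sw3")):
        for means in ((-0.5, 0.5), (-2.5, 2.5)):
            conds.append(
                ConditionSpec(
                    model="hmm",
                    label=f"hmm_m{means[1]}_{tag}",
                    regime_means=means,
                    switch_points=switches,
                )
            )
    rs_phis = [(0.25, 0.35), (0.05, 0.55), (0.65, 0.75), (0.45, 0.95)]
    for switches, tag in (((0.5,), "sw1"), ((0.25, 0.5, 0.75), "sw3")):
        for phis in rs_phis:
            conds.append(
                ConditionSpec(
                    model="rs_ar1",
                    label=f"rsar_{phis[0]}_{phis[1]}_{tag}",
                    intercepts=(0.0, 0.0),
                    ar_coefficients=phis,
                    switch_points=switches,
                )
            )
    conds.append(_ar1(0.3, "ar1_phi.3_skew", innovation=SKEWED_INNOVATIONS))
    conds.append(_trend(0.1, 0.3, "trend_b.1_phi.3_skew", innovation=SKEWED_INNOVATIONS))
    return conds


def get_condition(label: str) -> ConditionSpec:
    """Look up a registry condition by its label."""
    for cond in condition_registry():
        if cond.label == label:
            return cond
    raise KeyError(f"no registry condition labelled {label!r}")


def registry_to_json(path=None) -> str:
    """Serialize the registry as a JSON list (in registry row order)."""
    text = json.dumps([c.to_dict() for c in condition_registry()], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
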