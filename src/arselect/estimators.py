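"""Fitting the nine candidate models under a common conditional-likelihood contract.

Every candidate is fitted to the same set of *predictable* time points of a
complete series -- the targets t = 2..T, conditioning on y_1 -- so that all
nine report a Gaussian conditional log-likelihood over an identical
observation set and can be compared by information criteria on equal
footing.  Each fit returns a :class:`FittedModel` carrying the parameter
estimates, the conditional log-likelihood, the free-parameter count ``p``
(non-integer for the spline-based time-varying models, where it is the
effective degrees of freedom of the penalized fit), a convergence flag, and
enough state to form one-step-ahead predictions on any series.

Estimation is regression-based throughout: ordinary least squares for the
white-noise, AR(1), random-walk and AR(1)+trend candidates; penalized
B-spline (P-spline) least squares with GCV-selected smoothness for the
time-varying AR(1) candidates; an exhaustive threshold grid search with
per-regime OLS for the SETAR candidate; and expectation-maximization with a
forward-backward (Hamilton-filter) recursion for the two Markov-switching
candidates (HMM and RS-AR(1)).

Parameter counts (sigma^2 counted as free everywhere): random walk 1,
white noise 2, AR(1) 3, AR(1)+trend 4, SETAR 6 (two intercepts, two AR
coefficients, two variances; the threshold is not penalized), HMM 6,
RS-AR(1) 8, TV-AR edf + 1.

All fitters accept an optional boolean ``mask`` over the regression rows
(targets t = 2..T); masked-out rows are removed as *targets* only -- their
observed values remain available as lag regressors -- which is exactly the
refit needed by the cross-validation schemes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.interpolate import BSpline

__all__ = [
    "CANDIDATES",
    "DegenerateSeriesError",
    "EMConfig",
    "FittedModel",
    "fit_candidate",
    "fit_white_noise",
    "fit_ar1",
    "fit_random_walk",
    "fit_ar1_trend",
    "fit_tvar",
    "fit_setar",
    "fit_hmm",
    "fit_rsar",
    "predict_one_step",
    "prediction_basis",
]

#: candidate model names (identical to the generator model names)
CANDIDATES = (
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

_LOG2PI = math.log(2.0 * math.pi)


class DegenerateSeriesError(ValueError):
    """Raised when a series carries no information for a fit (e.g. zero variance)."""


@dataclass(frozen=True)
class EMConfig:
    """Settings for the EM fits of the hmm and rs_ar1 candidates."""

    n_restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-6        # relative log-likelihood change
    var_floor: float = 1e-6  # guards against variance collapse


@dataclass
class FittedModel:
    """A fitted candidate model.

    ``loglik`` is the Gaussian conditional log-likelihood over the
    ``T_pred`` predictable points used in fitting; ``p`` is the free
    parameter count entering the information criteria.
    """

    name: str
    params: dict
    loglik: float
    p: float
    T_pred: int
    converged: bool = True
    fit_info: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return json.dumps(
            {
                "name": self.name,
                "params": _clean(self.params),
                "loglik": self.loglik,
                "p": self.p,
                "T_pred": self.T_pred,
                "converged": self.converged,
            }
        )


def _gauss_ll(sse: float, n: int) -> float:
    """Maximized Gaussian log-likelihood given a residual sum of squares."""
    if n <= 0:
        return 0.0
    if sse <= 0.0:
        return math.inf  # exact interpolation: likelihood unbounded
    return -0.5 * n * (_LOG2PI + math.log(sse / n) + 1.0)


def _rows(y: np.ndarray, mask: np.ndarray | None):
    """Lag/target regression rows for targets t = 2..T, optionally masked."""
    y = np.asarray(y, dtype=float)
    lag = y[:-1]
    z = y[1:]
    tt = np.arange(2, len(y) + 1, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != z.size:
            raise ValueError("mask must cover the T-1 regression rows")
        lag, z, tt = lag[mask], z[mask], tt[mask]
    return lag, z, tt


def _check_series(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("series must be a 1-d array of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if np.ptp(y) == 0.0:
        raise DegenerateSeriesError("zero-variance series")
    return y


# ---------------------------------------------------------------------------
# OLS candidates
# ---------------------------------------------------------------------------

def fit_white_noise(y, mask=None) -> FittedModel:
    """i.i.d. Gaussian fit: mean and variance over the predictable points."""
    y = np.asarray(y, dtype=float)
    _, z, _ = _rows(y, mask)
    if z.size < 2:
        raise DegenerateSeriesError("too few predictable points")
    mu = float(z.mean())
    sse = float(((z - mu) ** 2).sum())
    if sse == 0.0:
        raise DegenerateSeriesError("zero residual variance in white-noise fit")
    n = z.size
    return FittedModel(
        name="white_noise",
        params={"mean": mu, "sigma2": sse / n},
        loglik=_gauss_ll(sse, n),
        p=2.0,
        T_pred=n,
        fit_info={"sse": sse},
    )


def _ols(X: np.ndarray, z: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sse = float(resid @ resid)
    # clip float dust so exact fits report SSE 0
    if sse < 1e-12 * max(1.0, float(z @ z)):
        sse = 0.0
    return beta, sse


def fit_ar1(y, mask=None) -> FittedModel:
    """OLS of y_t on {1, y_{t-1}}."""
    y = _check_series(y)
    lag, z, _ = _rows(y, mask)
    if np.ptp(lag) == 0.0:
        raise DegenerateSeriesError("constant lag regressor")
    X = np.column_stack([np.ones_like(lag), lag])
    beta, sse = _ols(X, z)
    n = z.size
    return FittedModel(
        name="ar1",
        params={"alpha": float(beta[0]), "phi": float(beta[1]), "sigma2": sse / n},
        loglik=_gauss_ll(sse, n),
        p=3.0,
        T_pred=n,
        fit_info={"sse": sse},
    )


def fit_random_walk(y, mask=None) -> FittedModel:
    """phi fixed at 1, no drift: only the innovation variance of first
    differences (about zero) is estimated."""
    y = _check_series(y)
    lag, z, _ = _rows(y, mask)
    d = z - lag
    sse = float(d @ d)
    n = z.size
    if sse == 0.0:
        raise DegenerateSeriesError("zero innovation variance in random-walk fit")
    return FittedModel(
        name="random_walk",
        params={"sigma2": sse / n},
        loglik=_gauss_ll(sse, n),
        p=1.0,
        T_pred=n,
        fit_info={"sse": sse},
    )


def fit_ar1_trend(y, mask=None) -> FittedModel:
    """OLS of y_t on {1, t, y_{t-1}} with raw integer time t = 2..T."""
    y = _check_series(y)
    lag, z, tt = _rows(y, mask)
    if np.ptp(lag) == 0.0:
        raise DegenerateSeriesError("constant lag regressor")
    X = np.column_stack([np.ones_like(lag), tt, lag])
    beta, sse = _ols(X, z)
    n = z.size
    return FittedModel(
        name="ar1_trend",
        params={
            "alpha": float(beta[0]),
            "beta": float(beta[1]),
            "phi": float(beta[2]),
            "sigma2": sse / n,
        },
        loglik=_gauss_ll(sse, n),
        p=4.0,
        T_pred=n,
        fit_info={"sse": sse},
    )


# ---------------------------------------------------------------------------
# Time-varying AR(1): penalized B-spline (P-spline) regression
# ---------------------------------------------------------------------------

_N_BASIS = 10   # cubic B-spline basis functions over scaled time [0, 1]
_DEGREE = 3
_LAMBDA_GRID = np.logspace(-6.0, 4.0, 26)


_INNER_KNOTS = np.linspace(0.0, 1.0, _N_BASIS - _DEGREE + 1)
_KNOTS = np.r_[np.zeros(_DEGREE), _INNER_KNOTS, np.ones(_DEGREE)]


def _bspline_design(x: np.ndarray) -> np.ndarray:
    """Cubic B-spline design on [0, 1] with equally spaced interior knots."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return BSpline.design_matrix(x, _KNOTS, _DEGREE, extrapolate=False).toarray()


def _curvature_penalty() -> np.ndarray:
    """Integrated squared second derivative of the basis (O'Sullivan
    penalty), P_ij = int B_i'' B_j'' dx.  Its null space is exactly the
    affine functions of scaled time, so at infinite penalty the smooth
    collapses to a straight line.  B'' is piecewise linear, making the
    piecewise-quadratic integrand exact under 2-point Gauss-Legendre."""
    P = np.zeros((_N_BASIS, _N_BASIS))
    gauss = np.array([-1.0, 1.0]) / math.sqrt(3.0)
    eye = np.eye(_N_BASIS)
    for a, b in zip(_INNER_KNOTS[:-1], _INNER_KNOTS[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for gx in gauss:
            x = np.array([mid + half * gx])
            row = np.array([float(BSpline(_KNOTS, eye[i], _DEGREE)(x, nu=2)[0]) for i in range(_N_BASIS)])
            P += half * np.outer(row, row)
    return P


_PEN = _curvature_penalty()


def fit_tvar(y, varying: str, mask=None) -> FittedModel:
    """Penalized-spline fit of a time-varying AR(1).

    ``varying="intercept"`` fits y_t = f(t/T) + phi * y_{t-1} + eps_t;
    ``varying="phi"`` fits y_t = alpha + g(t/T) * y_{t-1} + eps_t.  The
    smooth is a cubic P-spline over scaled time with its roughness penalty
    weight chosen by generalized cross-validation; ``p`` is the effective
    degrees of freedom (trace of the hat matrix) plus one for the variance.
    """
    if varying not in ("intercept", "phi"):
        raise ValueError("varying must be 'intercept' or 'phi'")
    y = _check_series(y)
    T = len(y)
    lag, z, tt = _rows(y, mask)
    if np.ptp(lag) == 0.0:
        raise DegenerateSeriesError("constant lag regressor")
    x = tt / T
    B = _bspline_design(x)
    if varying == "intercept":
        # B-splines sum to one, so the smooth absorbs the intercept
        Z = np.hstack([B, lag[:, None]])
        pen = slice(0, _N_BASIS)
    else:
        Z = np.hstack([np.ones((len(z), 1)), B * lag[:, None]])
        pen = slice(1, _N_BASIS + 1)
    d = Z.shape[1]
    P = np.zeros((d, d))
    P[pen, pen] = _PEN
    ZtZ = Z.T @ Z
    Ztz = Z.T @ z
    n = z.size

    # exact infinite-penalty limit: the smooth restricted to the penalty's
    # null space (affine in scaled time), fitted by OLS.  Including it in
    # the grid makes a fully collapsed smooth coincide *exactly* with the
    # corresponding parametric model, so downstream comparisons tie cleanly
    # instead of differing by numerical dust.
    null_candidates = []
    greville = np.array(
        [_KNOTS[i + 1 : i + 1 + _DEGREE].mean() for i in range(_N_BASIS)]
    )
    # the raw-time design makes the collapsed intercept-varying fit
    # *bit-identical* to the AR(1)+trend OLS fit, so equal-model ties are
    # exact and resolve by the ranking tie-break instead of float dust
    if varying == "intercept":
        Z_inf = np.column_stack([np.ones_like(z), tt, lag])
    else:
        Z_inf = np.column_stack([np.ones_like(z), lag, tt * lag])
    beta_inf, sse_inf = _ols(Z_inf, z)
    edf_inf = float(Z_inf.shape[1])
    if n - edf_inf > 1.0:
        gcv_inf = n * sse_inf / (n - edf_inf) ** 2
        # re-express the affine smooth a + b*t = a + (b*T)*x in basis
        # coefficients via the Greville abscissae
        if varying == "intercept":
            coef = np.r_[beta_inf[0] + beta_inf[1] * T * greville, beta_inf[2]]
        else:
            coef = np.r_[beta_inf[0], beta_inf[1] + beta_inf[2] * T * greville]
        null_candidates.append((gcv_inf, np.inf, coef, edf_inf, sse_inf))

    best = None
    # iterate from the stiffest fit down so near-ties resolve to the
    # smoother (lower-variance) fit
    candidates = null_candidates + [None] * len(_LAMBDA_GRID)
    for j, lam in enumerate(_LAMBDA_GRID[::-1]):
        A = ZtZ + lam * P
        try:
            beta = np.linalg.solve(A, Ztz)
            edf = float(np.trace(np.linalg.solve(A, ZtZ)))
        except np.linalg.LinAlgError:
            continue
        resid = z - Z @ beta
        sse = float(resid @ resid)
        if n - edf <= 1.0:
            continue
        gcv = n * sse / (n - edf) ** 2
        candidates[len(null_candidates) + j] = (gcv, lam, beta, edf, sse)
    for cand in candidates:
        if cand is None:
            continue
        if best is None or cand[0] < best[0] * (1.0 - 1e-7):
            best = cand
    if best is None:
        raise DegenerateSeriesError("penalized spline system singular at all penalties")
    gcv, lam, beta, edf, sse = best
    if sse < 1e-12 * max(1.0, float(z @ z)):
        sse = 0.0
    params: dict = {"varying": varying, "sigma2": sse / n if n else 0.0}
    if varying == "intercept":
        params["smooth_coef"] = beta[:_N_BASIS].copy()
        params["phi"] = float(beta[_N_BASIS])
    else:
        params["alpha"] = float(beta[0])
        params["smooth_coef"] = beta[1:].copy()
    name = "tvar_intercept" if varying == "intercept" else "tvar_phi"
    return FittedModel(
        name=name,
        params=params,
        loglik=_gauss_ll(sse, n),
        p=edf + 1.0,
        T_pred=n,
        fit_info={"lambda": float(lam), "edf": edf, "gcv": float(gcv), "sse": sse},
    )


def _tvar_smooth(model: FittedModel, x: np.ndarray) -> np.ndarray:
    """Evaluate the fitted smooth at scaled times ``x``."""
    return _bspline_design(x) @ model.params["smooth_coef"]


# ---------------------------------------------------------------------------
# SETAR(2,1,1): exhaustive threshold grid with per-regime OLS
# ---------------------------------------------------------------------------

_SETAR_MIN_PER_REGIME = 5
_SETAR_TRIM = (0.15, 0.85)


def fit_setar(y, mask=None) -> FittedModel:
    """Two-regime threshold AR(1), threshold on the lag-1 value.

    The threshold tau is searched exhaustively over the observed lag values
    between the 15th and 85th percentiles, requiring at least five rows per
    regime; tau-hat minimizes the total SSE (ties: smallest tau).  The
    threshold itself is not counted in ``p`` (p = 6: two intercepts, two AR
    coefficients, two variances).  If no admissible threshold exists, the
    fit falls back to a plain AR(1) and is flagged non-converged.
    """
    y = _check_series(y)
    lag, z, _ = _rows(y, mask)
    n = z.size
    order = np.argsort(lag, kind="stable")
    xs = lag[order]
    zs = z[order]

    # prefix sums for the per-regime normal equations
    ones = np.ones(n)
    c_n = np.cumsum(ones)
    c_x = np.cumsum(xs)
    c_z = np.cumsum(zs)
    c_xx = np.cumsum(xs * xs)
    c_xz = np.cumsum(xs * zs)
    c_zz = np.cumsum(zs * zs)

    def _sse_from_sums(k, Sx, Sz, Sxx, Sxz, Szz):
        det = k * Sxx - Sx * Sx
        with np.errstate(divide="ignore", invalid="ignore"):
            b0 = (Sz * Sxx - Sx * Sxz) / det
            b1 = (k * Sxz - Sx * Sz) / det
            sse = Szz - b0 * Sz - b1 * Sxz
            # constant lag within a regime: slope unidentified, project on the mean
            sse_mean = Szz - Sz * Sz / k
        singular = np.abs(det) <= 1e-10 * np.maximum(k * Sxx, 1.0)
        sse = np.where(singular, sse_mean, sse)
        sse = np.where(np.isfinite(sse), np.maximum(sse, 0.0), np.inf)
        return sse

    k = c_n  # regime-1 size when splitting after each sorted row
    sse1 = _sse_from_sums(k, c_x, c_z, c_xx, c_xz, c_zz)
    sse2 = _sse_from_sums(
        n - k, c_x[-1] - c_x, c_z[-1] - c_z, c_xx[-1] - c_xx, c_xz[-1] - c_xz, c_zz[-1] - c_zz
    )
    total = sse1 + sse2

    lo, hi = np.quantile(lag, _SETAR_TRIM)
    kk = np.arange(1, n + 1)
    admissible = (
        (kk >= _SETAR_MIN_PER_REGIME)
        & (kk <= n - _SETAR_MIN_PER_REGIME)
        & (xs >= lo)
        & (xs <= hi)
    )
    # a split after row k-1 is well defined only where the lag value strictly increases
    admissible[:-1] &= xs[:-1] < xs[1:]
    admissible[-1] = False

    if not admissible.any() or not np.isfinite(total[admissible]).any():
        base = fit_ar1(y, mask)
        return FittedModel(
            name="setar",
            params=dict(base.params),
            loglik=base.loglik,
            p=base.p,
            T_pred=base.T_pred,
            converged=False,
            fit_info={"fallback": "ar1", "sse": base.fit_info["sse"]},
        )

    total = np.where(admissible, total, np.inf)
    k_best = int(np.argmin(total))  # first minimum = smallest tau (xs ascending)
    tau = float(xs[k_best])

    in1 = lag <= tau
    res = {"threshold": tau}
    loglik = 0.0
    sse_total = 0.0
    for r, sel in ((1, in1), (2, ~in1)):
        Xr = np.column_stack([np.ones(sel.sum()), lag[sel]])
        beta, sse = _ols(Xr, z[sel])
        nr = int(sel.sum())
        res[f"alpha{r}"] = float(beta[0])
        res[f"phi{r}"] = float(beta[1])
        res[f"sigma2_{r}"] = sse / nr if nr else 0.0
        loglik += _gauss_ll(sse, nr)
        sse_total += sse
    return FittedModel(
        name="setar",
        params=res,
        loglik=loglik,
        p=6.0,
        T_pred=n,
        fit_info={"sse": sse_total, "n_regime1": int(in1.sum()), "n_regime2": int((~in1).sum())},
    )


# ---------------------------------------------------------------------------
# 2-state Markov-switching candidates (HMM, RS-AR(1)) via EM
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_backward(b, P, pi):  # pragma: no cover - exercised via python wrappers
    """Scaled forward-backward for a 2-state chain.

    ``b`` holds per-row emission likelihoods rescaled so each row's maximum
    is 1 (masked rows: both entries 1).  Returns the scaled log-likelihood
    (caller adds back the row scalings), smoothed state probabilities and
    summed transition expectations.
    """
    n = b.shape[0]
    alpha = np.empty((n, 2))
    c = np.empty(n)
    a0 = pi[0] * b[0, 0]
    a1 = pi[1] * b[0, 1]
    c[0] = a0 + a1
    alpha[0, 0] = a0 / c[0]
    alpha[0, 1] = a1 / c[0]
    for t in range(1, n):
        a0 = (alpha[t - 1, 0] * P[0, 0] + alpha[t - 1, 1] * P[1, 0]) * b[t, 0]
        a1 = (alpha[t - 1, 0] * P[0, 1] + alpha[t - 1, 1] * P[1, 1]) * b[t, 1]
        ct = a0 + a1
        c[t] = ct
        alpha[t, 0] = a0 / ct
        alpha[t, 1] = a1 / ct
    beta = np.empty((n, 2))
    beta[n - 1, 0] = 1.0
    beta[n - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(n - 2, -1, -1):
        bb0 = b[t + 1, 0] * beta[t + 1, 0]
        bb1 = b[t + 1, 1] * beta[t + 1, 1]
        beta[t, 0] = (P[0, 0] * bb0 + P[0, 1] * bb1) / c[t + 1]
        beta[t, 1] = (P[1, 0] * bb0 + P[1, 1] * bb1) / c[t + 1]
        denom = c[t + 1]
        xi[0, 0] += alpha[t, 0] * P[0, 0] * bb0 / denom
        xi[0, 1] += alpha[t, 0] * P[0, 1] * bb1 / denom
        xi[1, 0] += alpha[t, 1] * P[1, 0] * bb0 / denom
        xi[1, 1] += alpha[t, 1] * P[1, 1] * bb1 / denom
    gamma = alpha * beta
    for t in range(n):
        s = gamma[t, 0] + gamma[t, 1]
        gamma[t, 0] /= s
        gamma[t, 1] /= s
    loglik = 0.0
    for t in range(n):
        loglik += np.log(c[t])
    return loglik, gamma, xi


@njit(cache=True)
def _filter_predict(b, P, pi, mu):  # pragma: no cover - exercised via python wrappers
    """One-step predictive means E[y_t | y_{<t}] under frozen parameters.

    ``mu[t, k]`` is the state-k conditional mean of row t.  Returns the
    predictions and the one-step-ahead state probabilities P(s_t | y_{<t}).
    """
    n = b.shape[0]
    yhat = np.empty(n)
    pred = np.empty((n, 2))
    p0, p1 = pi[0], pi[1]
    for t in range(n):
        pred[t, 0] = p0
        pred[t, 1] = p1
        yhat[t] = p0 * mu[t, 0] + p1 * mu[t, 1]
        f0 = p0 * b[t, 0]
        f1 = p1 * b[t, 1]
        s = f0 + f1
        f0 /= s
        f1 /= s
        p0 = f0 * P[0, 0] + f1 * P[1, 0]
        p1 = f0 * P[0, 1] + f1 * P[1, 1]
    return yhat, pred


#: initial state distribution of the switching candidates (fixed, not estimated)
_PI0 = np.array([0.5, 0.5])


def _emission_scaled(z, W, betas, sig2, obs_mask):
    """Row-rescaled emission likelihoods and the log of the scaling."""
    mu = W @ betas.T  # (n, 2)
    logb = -0.5 * (_LOG2PI + np.log(sig2)[None, :]) - (z[:, None] - mu) ** 2 / (2.0 * sig2[None, :])
    logb[~obs_mask, :] = 0.0
    m = logb.max(axis=1)
    b = np.exp(logb - m[:, None])
    return b, float(m.sum()), mu


@njit(cache=True)
def _em_kernel(z, W, obs, betas, sig2, P, max_iter, tol, var_floor):  # pragma: no cover
    """Full EM loop for the 2-state switching-regression model.

    ``obs`` is a float 0/1 mask over rows; masked rows contribute emission
    likelihood 1 (transition propagation only) and are excluded from the
    M-step.  Returns the parameter arrays, the log-likelihood trace and a
    convergence flag.
    """
    n = z.shape[0]
    d = W.shape[1]
    trace = np.empty(max_iter)
    b = np.empty((n, 2))
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        # emission likelihoods, row-rescaled for numerical stability
        scale = 0.0
        for t in range(n):
            if obs[t] > 0.0:
                l0 = -0.5 * (_LOG2PI + np.log(sig2[0])) - (z[t] - (W[t] * betas[0]).sum()) ** 2 / (2.0 * sig2[0])
                l1 = -0.5 * (_LOG2PI + np.log(sig2[1])) - (z[t] - (W[t] * betas[1]).sum()) ** 2 / (2.0 * sig2[1])
            else:
                l0 = 0.0
                l1 = 0.0
            m = l0 if l0 > l1 else l1
            b[t, 0] = np.exp(l0 - m)
            b[t, 1] = np.exp(l1 - m)
            scale += m
        # fixed uniform initial distribution: keeping pi independent of P
        # preserves the exact EM ascent property (a pi tied to the updated
        # transition matrix can decrease the likelihood between iterations)
        pi = np.array([0.5, 0.5])
        ll, gamma, xi = _forward_backward(b, P, pi)
        ll += scale
        trace[it] = ll
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-10):
            converged = True
            break
        ll_prev = ll
        # M-step: weighted least squares per state (d <= 2, closed form)
        for k in range(2):
            sw = 0.0
            a00 = 0.0
            a01 = 0.0
            a11 = 0.0
            b0 = 0.0
            b1 = 0.0
            for t in range(n):
                w = gamma[t, k] * obs[t]
                sw += w
                a00 += w * W[t, 0] * W[t, 0]
                b0 += w * W[t, 0] * z[t]
                if d == 2:
                    a01 += w * W[t, 0] * W[t, 1]
                    a11 += w * W[t, 1] * W[t, 1]
                    b1 += w * W[t, 1] * z[t]
            if sw < 1e-8:
                continue  # starving state: keep previous parameters
            if d == 1:
                if a00 <= 1e-12:
                    continue
                beta0 = b0 / a00
                beta1 = 0.0
            else:
                det = a00 * a11 - a01 * a01
                if abs(det) <= 1e-12 * max(a00 * a11, 1.0):
                    continue
                beta0 = (b0 * a11 - a01 * b1) / det
                beta1 = (a00 * b1 - a01 * b0) / det
            s2 = 0.0
            for t in range(n):
                w = gamma[t, k] * obs[t]
                if w > 0.0:
                    mu_t = beta0 * W[t, 0]
                    if d == 2:
                        mu_t += beta1 * W[t, 1]
                    s2 += w * (z[t] - mu_t) ** 2
            betas[k, 0] = beta0
            if d == 2:
                betas[k, 1] = beta1
            sig2[k] = max(s2 / sw, var_floor)
        for j in range(2):
            row = xi[j, 0] + xi[j, 1]
            if row > 1e-12:
                P[j, 0] = xi[j, 0] / row
                P[j, 1] = xi[j, 1] / row
        for j in range(2):
            for k in range(2):
                if P[j, k] < 1e-8:
                    P[j, k] = 1e-8
                elif P[j, k] > 1.0 - 1e-8:
                    P[j, k] = 1.0 - 1e-8
            rs = P[j, 0] + P[j, 1]
            P[j, 0] /= rs
            P[j, 1] /= rs
    return betas, sig2, P, trace[n_iter - 1], trace[:n_iter].copy(), converged, n_iter


def _em_run(z, W, obs_mask, betas, sig2, P, cfg: EMConfig):
    """One EM run from a given start; returns final params and the trace."""
    betas, sig2, P, ll, trace, converged, n_iter = _em_kernel(
        z,
        np.ascontiguousarray(W),
        obs_mask.astype(np.float64),
        betas.astype(np.float64),
        sig2.astype(np.float64),
        P.astype(np.float64),
        cfg.max_iter,
        cfg.tol,
        cfg.var_floor,
    )
    return betas, sig2, P, float(ll), list(trace), converged, n_iter


def _em_fit(y, name: str, mask, cfg: EMConfig, seed) -> FittedModel:
    y = _check_series(y)
    z = y[1:]
    n = z.size
    if name == "hmm":
        W = np.ones((n, 1))
    else:
        W = np.column_stack([np.ones(n), y[:-1]])
    obs_mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if obs_mask.sum() < 8:
        raise DegenerateSeriesError("too few observed rows for EM fit")
    rng = np.random.default_rng(seed)

    zo = z[obs_mask]
    pooled_var = max(float(zo.var()), cfg.var_floor)
    if name == "rs_ar1":
        base = fit_ar1(y, mask)
        base_beta = np.array([base.params["alpha"], base.params["phi"]])
        base_var = max(base.params["sigma2"], cfg.var_floor)

    best = None
    for r in range(cfg.n_restarts):
        if name == "hmm":
            if r == 0:
                q = np.quantile(zo, [0.25, 0.75])
            else:
                q = np.quantile(zo, np.sort(rng.uniform(0.05, 0.95, 2)))
                if q[0] == q[1]:
                    q = q + np.array([-0.1, 0.1]) * math.sqrt(pooled_var)
            betas = q[:, None].copy()
            sig2 = np.array([pooled_var, pooled_var])
        else:
            if r == 0:
                jitter = np.array([[0.0, -0.2], [0.0, 0.2]])
            else:
                jitter = rng.normal(0.0, 0.3, size=(2, 2)) * np.array([math.sqrt(base_var), 1.0])
            betas = base_beta[None, :] + jitter
            sig2 = np.array([base_var, base_var])
        stay = 0.9 if r == 0 else float(rng.uniform(0.7, 0.98))
        P = np.array([[stay, 1.0 - stay], [1.0 - stay, stay]])
        out = _em_run(z, W.copy(), obs_mask.copy(), betas, sig2, P, cfg)
        if best is None or out[3] > best[3]:
            best = out

    betas, sig2, P, loglik, trace, run_converged, n_iter = best
    # canonical state order: ascending mean for hmm, ascending phi for rs_ar1
    key = betas[:, 0] if name == "hmm" else betas[:, 1]
    order = np.argsort(key, kind="stable")
    betas = betas[order]
    sig2 = sig2[order]
    P = P[np.ix_(order, order)]

    # convergence also requires beating the corresponding single-regime fit
    try:
        single = fit_white_noise(y, mask) if name == "hmm" else fit_ar1(y, mask)
        single_ll = single.loglik
    except DegenerateSeriesError:
        single_ll = -np.inf
    converged = bool(run_converged and loglik >= single_ll - 1e-8)

    if name == "hmm":
        params = {
            "means": betas[:, 0].copy(),
            "sigma2": sig2.copy(),
            "p11": float(P[0, 0]),
            "p22": float(P[1, 1]),
            "P": P.copy(),
        }
        p = 6.0
    else:
        params = {
            "alphas": betas[:, 0].copy(),
            "phis": betas[:, 1].copy(),
            "sigma2": sig2.copy(),
            "p11": float(P[0, 0]),
            "p22": float(P[1, 1]),
            "P": P.copy(),
        }
        p = 8.0
    return FittedModel(
        name=name,
        params=params,
        loglik=float(loglik),
        p=p,
        T_pred=n,
        converged=converged,
        fit_info={"n_iter": n_iter, "loglik_trace": list(map(float, trace)), "single_state_loglik": single_ll},
    )


def fit_hmm(y, mask=None, em_config: EMConfig | None = None, seed=0) -> FittedModel:
    """2-state Gaussian hidden Markov model (state mean and variance, 2x2
    transitions; initial distribution fixed at uniform, not estimated),
    fitted by EM with random restarts.  States are ordered by ascending mean."""
    return _em_fit(y, "hmm", mask, em_config or EMConfig(), seed)


def fit_rsar(y, mask=None, em_config: EMConfig | None = None, seed=0) -> FittedModel:
    """2-state Markov-switching AR(1) (state intercept, AR coefficient and
    variance), fitted by EM over the Hamilton filtering recursion.  States
    are ordered by ascending AR coefficient."""
    return _em_fit(y, "rs_ar1", mask, em_config or EMConfig(), seed)


# ---------------------------------------------------------------------------
# Dispatch and prediction
# ---------------------------------------------------------------------------

def fit_candidate(
    name: str,
    y,
    mask=None,
    seed=0,
    em_config: EMConfig | None = None,
) -> FittedModel:
    """Fit one of the nine candidates to a series.

    ``seed`` only affects the EM candidates (restart initialization); all
    other fits are deterministic functions of the series.
    """
    y = np.asarray(y, dtype=float)
    if mask is None and y.size < 10:
        raise ValueError("series length must be >= 10")
    if name == "white_noise":
        return fit_white_noise(y, mask)
    if name == "ar1":
        return fit_ar1(y, mask)
    if name == "random_walk":
        return fit_random_walk(y, mask)
    if name == "ar1_trend":
        return fit_ar1_trend(y, mask)
    if name == "tvar_intercept":
        return fit_tvar(y, "intercept", mask)
    if name == "tvar_phi":
        return fit_tvar(y, "phi", mask)
    if name == "setar":
        return fit_setar(y, mask)
    if name == "hmm":
        return fit_hmm(y, mask, em_config, seed)
    if name == "rs_ar1":
        return fit_rsar(y, mask, em_config, seed)
    raise ValueError(f"unknown candidate {name!r}")


def prediction_basis(name: str) -> str:
    """How a candidate forms one-step predictions."""
    return "filtered_forecast" if name in ("hmm", "rs_ar1") else "plug_in_regression"


def _switching_predict(model: FittedModel, y: np.ndarray):
    z = y[1:]
    n = z.size
    if model.name == "hmm":
        betas = np.asarray(model.params["means"], dtype=float)[:, None]
        W = np.ones((n, 1))
    else:
        betas = np.column_stack(
            [np.asarray(model.params["alphas"], dtype=float), np.asarray(model.params["phis"], dtype=float)]
        )
        W = np.column_stack([np.ones(n), y[:-1]])
    sig2 = np.asarray(model.params["sigma2"], dtype=float)
    P = np.asarray(model.params["P"], dtype=float)
    obs_mask = np.ones(n, dtype=bool)
    b, _, mu = _emission_scaled(z, W, betas, sig2, obs_mask)
    return _filter_predict(b, P, _PI0, mu)


def predict_one_step(model: FittedModel, y) -> np.ndarray:
    """One-step-ahead predictions yhat_t for targets t = 2..len(y).

    Regression candidates plug the observed lag (and time, where relevant)
    into the fitted equation; the Markov-switching candidates return
    filtered forecasts E[y_t | y_1..y_{t-1}] under the frozen parameter
    estimates.  Time-varying candidates evaluate their smooth at the scaled
    time t/len(y) of the series being predicted.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("series too short to predict")
    lag = y[:-1]
    tt = np.arange(2, y.size + 1, dtype=float)
    p = model.params
    name = model.name
    if name == "setar" and model.fit_info.get("fallback") == "ar1":
        name = "ar1"
    if name == "white_noise":
        return np.full(lag.size, p["mean"])
    if name == "ar1":
        return p["alpha"] + p["phi"] * lag
    if name == "random_walk":
        return lag.copy()
    if name == "ar1_trend":
        return p["alpha"] + p["beta"] * tt + p["phi"] * lag
    if name in ("tvar_intercept", "tvar_phi"):
        x = tt / y.size
        smooth = _tvar_smooth(model, x)
        if name == "tvar_intercept":
            return smooth + p["phi"] * lag
        return p["alpha"] + smooth * lag
    if name == "setar":
        in1 = lag <= p["threshold"]
        return np.where(
            in1, p["alpha1"] + p["phi1"] * lag, p["alpha2"] + p["phi2"] * lag
        )
    if name in ("hmm", "rs_ar1"):
        yhat, _ = _switching_predict(model, y)
        return yhat
    raise ValueError(f"unknown candidate {model.name!r}")


def predicted_state_probabilities(model: FittedModel, y) -> np.ndarray:
    """One-step-ahead state probabilities P(s_t | y_{<t}) for hmm/rs_ar1."""
    if model.name not in ("hmm", "rs_ar1"):
        raise ValueError("state probabilities are defined for hmm/rs_ar1 only")
    _, pred = _switching_predict(model, np.asarray(y, dtype=float))
    return pred
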