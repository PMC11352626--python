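"""Exponential decay-to-plateau ("cure fraction") survival model.

The model is

    S(t) = P + (S0 - P) * exp(-k * t)

where ``S0`` is the survival probability at time zero (fixed at 1 by
default), ``P`` the survival plateau -- the fraction of patients who never
experience the event -- and ``k`` the rate constant of the event process
among non-cured patients.  The half-life ln(2)/k is the time for survival
to fall halfway from S0 to the plateau.

Fitting is unweighted least squares on the Kaplan-Meier survival values at
the distinct event times (plus the anchor point (0, S0) when S0 is fixed).
Internally the decay is parameterised by the half-life rather than by k, so
the reported half-life standard error comes directly from the Jacobian at
the optimum instead of a delta-method propagation.  A censored-data
maximum-likelihood route for the same model is available separately
(:func:`fit_plateau_mle`); the least-squares route is the default because
the AIC comparisons downstream are defined on the regression residuals.

AIC for least squares: AIC = N ln(RSS/N) + 2K with K counting the free
curve parameters plus one for the error variance; the small-sample AICc
correction is available by flag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize

from .errors import InsufficientDataError, ValidationError
from .survival import KMCurve, SurvivalRecord, _endpoint_columns

__all__ = [
    "PlateauParams",
    "FitConfig",
    "PlateauFit",
    "survival_function",
    "half_life",
    "aic_least_squares",
    "fit_points",
    "fit_plateau",
    "fit_exponential_to_zero",
    "fit_plateau_mle",
]

LN2 = math.log(2.0)

# k in [1e-6, 1e3] per month  <=>  half-life in [ln2/1e3, ln2/1e-6] months
_K_MIN, _K_MAX = 1e-6, 1e3
_T_MIN, _T_MAX = LN2 / _K_MAX, LN2 / _K_MIN


@dataclass(frozen=True)
class PlateauParams:
    """Parameters (S0, P, k) of the decay-to-plateau model."""

    s0: float
    plateau: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau <= self.s0 <= 1.0):
            raise ValidationError(
                f"need 0 <= plateau <= s0 <= 1, got plateau={self.plateau}, s0={self.s0}"
            )
        if self.k < 0:
            raise ValidationError(f"rate constant k must be >= 0, got {self.k}")

    @property
    def half_life(self) -> float:
        return half_life(self.k)


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    s0_mode: "fixed" anchors S(0) at ``s0_value`` (survival from diagnosis);
        "free" estimates it with bound (0, 1].
    plateau_mode: "free" estimates the plateau in [0, 1]; "zero" pins it at
        0, the no-plateau rival model.
    aic: "plain" or "aicc" (small-sample correction).
    loss: "km_ls" (default, least squares on KM points) or "mle"
        (censored-data likelihood; see fit_plateau_mle).
    """

    s0_mode: str = "fixed"
    s0_value: float = 1.0
    plateau_mode: str = "free"
    aic: str = "plain"
    loss: str = "km_ls"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0_mode not in ("fixed", "free"):
            raise ValidationError(f"s0_mode must be 'fixed' or 'free', got {self.s0_mode!r}")
        if self.plateau_mode not in ("free", "zero"):
            raise ValidationError(f"plateau_mode must be 'free' or 'zero', got {self.plateau_mode!r}")
        if self.aic not in ("plain", "aicc"):
            raise ValidationError(f"aic must be 'plain' or 'aicc', got {self.aic!r}")
        if self.loss not in ("km_ls", "mle"):
            raise ValidationError(f"loss must be 'km_ls' or 'mle', got {self.loss!r}")
        if not (0.0 < self.s0_value <= 1.0):
            raise ValidationError(f"s0_value must lie in (0, 1], got {self.s0_value}")


@dataclass
class PlateauFit:
    """A fitted decay-to-plateau model with fit diagnostics."""

    params: PlateauParams
    se: Dict[str, Optional[float]]   # per-parameter standard errors (None if fixed)
    rss: float
    n_points: int
    n_free: int                      # free curve parameters (variance not counted)
    aic: float
    half_life: float
    converged: bool
    at_bounds: List[str] = field(default_factory=list)
    degenerate: bool = False
    loglik: Optional[float] = None   # set by the MLE route only

    @property
    def aic_k(self) -> int:
        """K used in the AIC formula: free curve parameters + error variance."""
        return self.n_free + 1


def survival_function(t, params: PlateauParams):
    """Model survival probability S(t) = P + (S0 - P) exp(-k t).

    Accepts a scalar or array time; continuous and non-increasing in t.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be non-negative")
    out = params.plateau + (params.s0 - params.plateau) * np.exp(-params.k * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def half_life(k: float) -> float:
    """ln(2)/k, the time to fall halfway from S0 to the plateau; inf if k = 0
    (no decay)."""
    if k < 0:
        raise ValidationError(f"rate constant k must be >= 0, got {k}")
    if k == 0:
        return math.inf
    return LN2 / k


def aic_least_squares(rss: float, n: int, n_free: int, kind: str = "plain") -> float:
    """AIC for a least-squares fit: N ln(RSS/N) + 2K, K = n_free + 1.

    ``kind='aicc'`` adds the small-sample correction 2K(K+1)/(N-K-1)
    (infinite when N <= K + 1).
    """
    if rss < 0 or n <= 0:
        raise ValidationError("rss must be >= 0 and n > 0")
    k = n_free + 1
    if rss == 0.0:
        return -math.inf
    aic = n * math.log(rss / n) + 2 * k
    if kind == "aicc":
        denom = n - k - 1
        aic += math.inf if denom <= 0 else 2 * k * (k + 1) / denom
    return aic


def _model(ts: np.ndarray, plateau: float, t_half: float, s0: float) -> np.ndarray:
    return plateau + (s0 - plateau) * np.exp(-(LN2 / t_half) * ts)


def _initial_half_life(ts: np.ndarray, ys: np.ndarray, s0: float, plateau0: float) -> float:
    """First time the curve drops below halfway to the provisional plateau;
    fallback: median event time."""
    target = 0.5 * (s0 + plateau0)
    below = ts[ys < target]
    t0 = float(below[0]) if below.size else float(np.median(ts[ts > 0])) if np.any(ts > 0) else 1.0
    return float(np.clip(t0 if t0 > 0 else 1.0, _T_MIN, _T_MAX))


def fit_points(ts: Sequence[float], ys: Sequence[float], config: FitConfig = FitConfig()) -> PlateauFit:
    """Least-squares decay-to-plateau fit to (time, survival) points.

    This is the shared fitting engine: :func:`fit_plateau` feeds it a single
    KM curve, and the model-selection layer feeds it pooled multi-group
    point sets.  Deterministic 3-point multi-start over the half-life.
    """
    ts = np.asarray(ts, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if ts.shape != ys.shape or ts.ndim != 1:
        raise ValidationError("ts and ys must be 1-D arrays of equal length")

    free: List[str] = []
    if config.plateau_mode == "free":
        free.append("plateau")
    free.append("half_life")
    if config.s0_mode == "free":
        free.append("s0")

    n, n_free = len(ts), len(free)
    s0_fixed = config.s0_value

    # No variation in the data (e.g. a group with no events): the plateau
    # sits at the common value and the rate is unidentified.  Report the
    # boundary fit honestly rather than failing.
    if n >= 1 and np.ptp(ys) == 0.0:
        value = float(ys[0])
        s0 = s0_fixed if config.s0_mode == "fixed" else value
        plateau = 0.0 if config.plateau_mode == "zero" else min(value, s0)
        params = PlateauParams(s0=s0, plateau=plateau, k=_K_MIN)
        rss = float(np.sum((_model(ts, plateau, LN2 / _K_MIN, s0) - ys) ** 2))
        return PlateauFit(
            params=params,
            se={name: None for name in ("plateau", "half_life", "k", "s0")},
            rss=rss,
            n_points=n,
            n_free=n_free,
            aic=aic_least_squares(rss, n, n_free, config.aic),
            half_life=half_life(_K_MIN),
            converged=True,
            at_bounds=["plateau", "half_life"],
            degenerate=True,
        )

    # exactly-determined fits (n == n_free) are allowed and give RSS ~ 0
    if n < n_free:
        raise InsufficientDataError(
            f"need at least {n_free} points for {n_free} free parameters, got {n}"
        )

    plateau0 = float(np.clip(ys[np.argmax(ts)], 0.0, 0.99))
    if config.plateau_mode == "zero":
        plateau0 = 0.0
    t_half0 = _initial_half_life(ts, ys, s0_fixed, plateau0)

    lo, hi, x0 = [], [], []
    for name in free:
        if name == "plateau":
            lo.append(0.0); hi.append(1.0); x0.append(plateau0)
        elif name == "half_life":
            lo.append(_T_MIN); hi.append(_T_MAX); x0.append(t_half0)
        else:  # s0
            lo.append(1e-6); hi.append(1.0); x0.append(min(1.0, max(float(ys[np.argmin(ts)]), 1e-3)))
    lo = np.array(lo); hi = np.array(hi); x0 = np.array(x0)
    i_t = free.index("half_life")

    def unpack(x: np.ndarray) -> Tuple[float, float, float]:
        plateau = x[free.index("plateau")] if "plateau" in free else 0.0
        s0 = x[free.index("s0")] if "s0" in free else s0_fixed
        return float(plateau), float(x[i_t]), float(s0)

    def residuals(x: np.ndarray) -> np.ndarray:
        plateau, t_half, s0 = unpack(x)
        return _model(ts, plateau, t_half, s0) - ys

    # deterministic multi-start: three decay-rate scales, each from the
    # data-driven plateau guess and (when the plateau is free) from the
    # plateau-at-zero corner, so the free fit always dominates the pinned one
    starts = []
    for factor in (1.0 / 3.0, 1.0, 3.0):
        start = x0.copy()
        start[i_t] = float(np.clip(t_half0 * factor, _T_MIN, _T_MAX))
        starts.append(start)
        if "plateau" in free:
            corner = start.copy()
            corner[free.index("plateau")] = 0.0
            starts.append(corner)

    best = None
    converged = False
    for start in starts:
        res = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        if best is None or res.cost < best.cost:
            best = res
        converged = converged or bool(res.success)

    plateau, t_half, s0 = unpack(best.x)
    plateau = min(plateau, s0)  # guard tiny bound violations when s0 is free
    rss = float(2.0 * best.cost)
    k = LN2 / t_half

    # Asymptotic SEs: sqrt(diag(RSS/(N-K) * (J^T J)^-1)) at the optimum.
    se: Dict[str, Optional[float]] = {"plateau": None, "half_life": None, "k": None, "s0": None}
    dof = n - n_free
    if dof > 0 and rss > 0:
        jac = best.jac
        try:
            cov = rss / dof * np.linalg.inv(jac.T @ jac)
            diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for name, s in zip(free, diag):
                se[name] = float(s)
            if se["half_life"] is not None:
                se["k"] = LN2 / t_half**2 * se["half_life"]
        except np.linalg.LinAlgError:
            pass

    at_bounds = []
    for name, value, lo_v, hi_v in zip(free, best.x, lo, hi):
        scale = max(abs(hi_v - lo_v), 1.0)
        if min(abs(value - lo_v), abs(value - hi_v)) < 1e-6 * scale:
            at_bounds.append(name)

    params = PlateauParams(s0=s0, plateau=plateau, k=k)
    return PlateauFit(
        params=params,
        se=se,
        rss=rss,
        n_points=n,
        n_free=n_free,
        aic=aic_least_squares(rss, n, n_free, config.aic),
        half_life=t_half,
        converged=converged,
        at_bounds=at_bounds,
    )


def _curve_points(curve: KMCurve, config: FitConfig) -> Tuple[np.ndarray, np.ndarray]:
    ts = np.asarray(curve.times, dtype=float)
    ys = np.asarray(curve.survival, dtype=float)
    if config.s0_mode == "fixed":
        # anchor the curve at S(0) = s0, mirroring the KM start
        ts = np.concatenate([[0.0], ts])
        ys = np.concatenate([[config.s0_value], ys])
    return ts, ys


def fit_plateau(curve: KMCurve, config: FitConfig = FitConfig()) -> PlateauFit:
    """Fit the decay-to-plateau model to a Kaplan-Meier curve."""
    ts, ys = _curve_points(curve, config)
    return fit_points(ts, ys, config)


def fit_exponential_to_zero(curve: KMCurve, config: FitConfig = FitConfig()) -> PlateauFit:
    """Fit the no-plateau rival model (plateau pinned at 0) to a KM curve."""
    cfg = FitConfig(
        s0_mode=config.s0_mode,
        s0_value=config.s0_value,
        plateau_mode="zero",
        aic=config.aic,
        loss=config.loss,
        seed=config.seed,
    )
    return fit_plateau(curve, cfg)


def fit_plateau_mle(
    records: Sequence[SurvivalRecord],
    endpoint: str = "OS",
    config: FitConfig = FitConfig(),
) -> PlateauFit:
    """Censored-data maximum-likelihood fit of the same cure model.

    Likelihood per subject (S0 = 1): events contribute the density
    (1-P) k exp(-k t), censored subjects the survival P + (1-P) exp(-k t).
    AIC here is the likelihood form 2K - 2 ln L.  This is a proper i.i.d.
    likelihood, so its AIC differences are calibrated -- the model-selection
    layer uses this route by default, while single-curve fitting uses the
    least-squares route.

    Parameterised in (plateau, half-life); standard errors come from the
    inverse of a finite-difference Hessian of the negative log-likelihood.
    """
    times, events = _endpoint_columns(list(records), endpoint)
    n = len(times)
    if n < 2:
        raise InsufficientDataError("MLE fit needs at least 2 records")

    def nll(x: np.ndarray) -> float:
        plateau, t_half = x
        k = LN2 / t_half
        out = 0.0
        if events.any():
            out -= np.sum(
                math.log(max(1.0 - plateau, 1e-300)) + math.log(k) - k * times[events]
            )
        if (~events).any():
            surv = plateau + (1.0 - plateau) * np.exp(-k * times[~events])
            out -= np.sum(np.log(np.maximum(surv, 1e-300)))
        return float(out)

    t_half0 = float(np.clip(np.median(times), _T_MIN, _T_MAX))
    plateau0 = float(np.clip(1.0 - events.mean(), 1e-3, 1.0 - 1e-3))
    best = None
    converged = False
    for factor in (1.0 / 3.0, 1.0, 3.0):
        res = minimize(
            nll,
            x0=np.array([plateau0, float(np.clip(t_half0 * factor, _T_MIN, _T_MAX))]),
            bounds=[(0.0, 1.0), (_T_MIN, _T_MAX)],
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    plateau, t_half = (float(v) for v in best.x)
    k = LN2 / t_half
    n_free = 2
    loglik = -float(best.fun)
    aic = 2 * n_free - 2 * loglik

    se: Dict[str, Optional[float]] = {"plateau": None, "half_life": None, "k": None, "s0": None}
    at_bounds = [
        name
        for name, value, lo, hi in (
            ("plateau", plateau, 0.0, 1.0),
            ("half_life", t_half, _T_MIN, _T_MAX),
        )
        if min(abs(value - lo), abs(value - hi)) < 1e-6 * max(hi - lo, 1.0)
    ]
    if not at_bounds:
        hess = _numerical_hessian(nll, np.array([plateau, t_half]))
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se["plateau"], se["half_life"] = (float(v) for v in np.sqrt(diag))
                se["k"] = LN2 / t_half**2 * se["half_life"]
        except np.linalg.LinAlgError:
            pass

    params = PlateauParams(s0=1.0, plateau=min(plateau, 1.0), k=k)
    return PlateauFit(
        params=params,
        se=se,
        rss=float("nan"),
        n_points=n,
        n_free=n_free,
        aic=aic,
        half_life=t_half,
        converged=converged,
        at_bounds=at_bounds,
        loglik=loglik,
    )


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for the 2-parameter likelihood."""
    m = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    hess = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return hess
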