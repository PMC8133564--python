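"""Michaelis–Menten uptake kinetics: forward depletion model and fitting.

Uptake by a root system in a closed chamber follows saturable kinetics

    v(C) = I_max * (C - C_min) / (K_m + (C - C_min)),   v in µmol cm⁻¹ h⁻¹

where ``I_max`` is the maximum specific uptake rate, ``K_m`` the
half-saturation concentration (µM), and ``C_min`` an optional concentration
floor at which influx balances efflux (0 by default). With root length ``L``
(cm) in volume ``V`` (mL) the chamber concentration obeys

    dC/dt = -k (C - C_min) / (K_m + (C - C_min)),   k = I_max * L / (V/1000)

(k in µM h⁻¹), whose integral is the implicit relation

    K_m * ln((C_0 - C_min)/(C - C_min)) + (C_0 - C) = k t.

Writing u = C - C_min this is solved in closed form by the principal branch
of the Lambert W function, u = K_m * W(z) with
z = (u_0/K_m) * exp((u_0 - k t)/K_m). For low-affinity regimes
(C_0 ≫ K_m) the argument overflows double precision, so the solver works
from ln z and switches to a Newton iteration on w + ln w = ln z.

Fitting is nonlinear least squares on the *observed concentrations* (not on
derived rates, whose errors are correlated), with bounds, a data-driven
deterministic start and an optional seeded multistart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .errors import FitError, ValidationError
from .uptake_core import DepletionSeries

#: QC / diagnostic flags
FLAG_NO_CONVERGENCE = "no_convergence"
FLAG_KM_UNRELIABLE = "km_unreliable"


@dataclass
class FitDiagnostics:
    residual_norm: float
    converged: bool
    n_points: int
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class MMParams:
    """Fitted or assumed Michaelis–Menten parameters for one ion."""

    ion: str
    i_max: float  # µmol cm^-1 h^-1
    k_m: float  # µM
    c_min: float = 0.0  # µM
    diagnostics: FitDiagnostics | None = None

    def __post_init__(self) -> None:
        if not (self.i_max >= 0):
            raise ValidationError(f"I_max must be >= 0, got {self.i_max}")
        if not (self.k_m > 0):
            raise ValidationError(f"K_m must be > 0, got {self.k_m}")
        if not (self.c_min >= 0):
            raise ValidationError(f"C_min must be >= 0, got {self.c_min}")


def mm_rate(c, params: MMParams):
    """Specific uptake rate at concentration ``c`` (µM); vectorized."""
    c = np.asarray(c, dtype=float)
    u = np.maximum(c - params.c_min, 0.0)
    out = params.i_max * u / (params.k_m + u)
    return float(out) if out.ndim == 0 else out


def depletion_rate_constant(i_max: float, length: float, volume: float) -> float:
    """k = I_max·L/V in µM h⁻¹ (length in cm, volume in mL)."""
    if length <= 0 or volume <= 0:
        raise ValidationError("root length and volume must be > 0")
    return i_max * length / (volume / 1000.0)


def _lambertw_from_log(ln_z: np.ndarray) -> np.ndarray:
    """W₀(z) given ln z, stable for arbitrarily large arguments.

    For moderate ln z defers to scipy's lambertw; above the overflow range
    solves w + ln w = ln z by Newton from the asymptotic start
    w ≈ ln z − ln ln z.
    """
    ln_z = np.asarray(ln_z, dtype=float)
    w = np.empty_like(ln_z)
    small = ln_z < 700.0  # exp still finite
    if np.any(small):
        w[small] = np.real(special.lambertw(np.exp(ln_z[small])))
    big = ~small
    if np.any(big):
        x = ln_z[big]
        wb = x - np.log(x)
        for _ in range(50):
            f = wb + np.log(wb) - x
            step = f / (1.0 + 1.0 / wb)
            wb = wb - step
            if np.all(np.abs(step) <= 1e-14 * np.abs(wb)):
                break
        w[big] = wb
    return w


def mm_depletion_conc(
    t, c0: float, params: MMParams, length: float, volume: float
):
    """Chamber concentration C(t) under Michaelis–Menten depletion (µM).

    Closed-form solution of the integrated rate law; non-increasing in t,
    bounded below by ``C_min``. Vectorized over ``t``.
    """
    for name, v in (("c0", c0), ("i_max", params.i_max), ("k_m", params.k_m)):
        if not np.isfinite(v):
            raise ValidationError(f"non-finite parameter {name}={v}")
    if c0 <= params.c_min:
        raise ValidationError(
            f"C_0={c0} must exceed C_min={params.c_min}"
        )
    t = np.asarray(t, dtype=float)
    u0 = c0 - params.c_min
    k = depletion_rate_constant(params.i_max, length, volume)
    km = params.k_m
    # ln z = ln(u0/km) + (u0 - k t)/km
    ln_z = np.log(u0 / km) + (u0 - k * t) / km
    u = km * _lambertw_from_log(ln_z)
    u = np.clip(u, 0.0, u0)
    out = params.c_min + u
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _covariance(res: optimize.OptimizeResult) -> np.ndarray | None:
    """Gauss-Newton covariance estimate from the final Jacobian."""
    try:
        J = res.jac
        dof = max(J.shape[0] - J.shape[1], 1)
        s2 = 2.0 * res.cost / dof
        JTJ = J.T @ J
        return s2 * np.linalg.pinv(JTJ)
    except Exception:
        return None


def fit_depletion(
    series: DepletionSeries,
    length: float,
    volume: float | None = None,
    fix_cmin: bool = True,
    multistart: int = 0,
    seed: int = 0,
    km_max_factor: float = 10.0,
) -> MMParams:
    """Estimate (I_max, K_m[, C_min]) from one depletion time series.

    Least squares on observed concentrations against the closed-form
    trajectory. Initialization: I_max from the steepest early two-point
    slope scaled by V/L, K_m at C_0/2, C_min (if free) at the observed
    minimum. K_m is bounded above at ``km_max_factor`` × C_0: half-saturation
    constants far beyond the observed concentration range are structurally
    unidentifiable and unbounded fits diverge along the I_max/K_m ridge.
    Poor fits set a non-convergence flag in the diagnostics rather than
    raising.

    With 8-point series and multiplicative noise the single-fit dispersion
    of I_max is large whenever concentrations stay well above K_m (weak
    curvature information); the estimator is median-unbiased, so population
    summaries over many chambers remain accurate. See the diagnostics flags
    for the saturating-regime guard.
    """
    volume = series.volume if volume is None else volume
    t = series.times
    c = series.concentrations
    n_par = 2 if fix_cmin else 3
    if len(t) < n_par + 2:
        raise FitError(
            f"need at least {n_par + 2} timepoints for {n_par} parameters, "
            f"got {len(t)}"
        )
    if np.all(c == c[0]):
        raise FitError("constant concentration series: no depletion signal")
    c0 = float(c[0])

    # data-driven start: steepest early slope -> I_max; K_m at C0/2
    slopes = (c[:-1] - c[1:]) / (t[1:] - t[:-1])
    slope0 = max(float(np.max(slopes[: max(2, len(slopes) // 2)])), 1e-9)
    imax0 = slope0 * (volume / 1000.0) / length
    km0 = max(c0 / 2.0, 1e-6)
    cmin_hi = max(float(np.min(c)), 1e-9)

    def residuals(p: np.ndarray) -> np.ndarray:
        imax, km = p[0], p[1]
        cmin = 0.0 if fix_cmin else p[2]
        params = MMParams(series.ion, max(imax, 0.0), max(km, 1e-12), max(cmin, 0.0))
        if c0 <= params.c_min:
            return np.full_like(c, 1e6)
        model = mm_depletion_conc(t, c0, params, length, volume)
        return model - c

    km_ub = km_max_factor * c0 if km_max_factor and c0 > 0 else np.inf
    if fix_cmin:
        x0 = np.array([imax0, min(km0, 0.9 * km_ub)])
        lb = np.array([1e-12, 1e-9])
        ub = np.array([np.inf, km_ub])
    else:
        x0 = np.array([imax0, min(km0, 0.9 * km_ub), 0.5 * cmin_hi])
        lb = np.array([1e-12, 1e-9, 0.0])
        ub = np.array([np.inf, km_ub, cmin_hi * (1 - 1e-9)])

    starts = [x0]
    if multistart > 0:
        rng = np.random.default_rng(seed)
        for _ in range(multistart):
            jitter = np.exp(rng.normal(0.0, 1.0, size=2))
            extra = x0.copy()
            extra[0] *= jitter[0]
            extra[1] *= jitter[1]
            starts.append(np.clip(extra, lb + 1e-15, None))

    best: optimize.OptimizeResult | None = None
    for s0 in starts:
        try:
            res = optimize.least_squares(
                residuals, s0, bounds=(lb, ub), x_scale=np.maximum(s0, 1e-9)
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("optimizer failed from every start")

    imax_hat, km_hat = float(best.x[0]), float(best.x[1])
    cmin_hat = 0.0 if fix_cmin else float(best.x[2])
    flags: list[str] = []
    converged = bool(best.success)
    if not converged:
        flags.append(FLAG_NO_CONVERGENCE)
    # identifiability guard: series never left the saturating regime
    if float(np.min(c)) - cmin_hat > 10.0 * km_hat:
        flags.append(FLAG_KM_UNRELIABLE)
    diag = FitDiagnostics(
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=converged,
        n_points=len(t),
        covariance=_covariance(best),
        flags=flags,
    )
    return MMParams(series.ion, imax_hat, km_hat, cmin_hat, diag)


def fit_rates(
    concentrations,
    rates,
    ion: str = "",
) -> MMParams:
    """Fit the rate form v = I_max·C/(K_m + C) to (C, v) pairs.

    Used for across-concentration characterization where each chamber
    contributes a specific uptake rate at a known concentration.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if c.shape != v.shape or c.ndim != 1:
        raise FitError("concentrations and rates must be equal-length 1-D")
    if len(c) < 3:
        raise FitError(f"need at least 3 (C, rate) pairs, got {len(c)}")
    if len(np.unique(c)) != len(c):
        raise FitError("concentrations must be distinct")

    imax0 = max(float(np.max(v)), 1e-9)
    half = imax0 / 2.0
    km0 = max(float(np.interp(half, np.sort(v), c[np.argsort(v)])), 1e-6)

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] * c / (p[1] + c) - v

    res = optimize.least_squares(
        residuals,
        np.array([imax0, km0]),
        bounds=(np.array([1e-12, 1e-9]), np.array([np.inf, np.inf])),
        x_scale=np.array([imax0, km0]),
    )
    flags: list[str] = []
    converged = bool(res.success)
    if not converged:
        flags.append(FLAG_NO_CONVERGENCE)
    cov = _covariance(res)
    # saturated designs leave K_m unidentified: flag via relative uncertainty
    if cov is not None:
        km_se = float(np.sqrt(max(cov[1, 1], 0.0)))
        if not np.isfinite(km_se) or km_se > abs(res.x[1]):
            flags.append(FLAG_KM_UNRELIABLE)
    if float(np.min(c)) > 10.0 * float(res.x[1]):
        if FLAG_KM_UNRELIABLE not in flags:
            flags.append(FLAG_KM_UNRELIABLE)
    diag = FitDiagnostics(
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=converged,
        n_points=len(c),
        covariance=cov,
        flags=flags,
    )
    return MMParams(ion, float(res.x[0]), float(res.x[1]), 0.0, diag)
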