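"""1-tissue compartment model: forward solution and weighted least-squares fit.

The extravascular cortical concentration obeys

    dC_EC/dt = K1 * C_P(t) - k2 * C_EC(t),        C_EC(0) = 0

with K1 the plasma-to-cortex influx rate (glomerular filtration per unit
extravascular cortical volume, 1/min) and k2 the urinary washout rate
(1/min).  Its solution is the convolution C_EC = K1 * (C_P (x) exp(-k2 t)).
The measured cortical signal additionally contains a fractional blood volume
vB, giving the operational curve fitted to the data:

    C_model(t) = (1 - vB) * C_EC(t) + vB * C_aorta(t)

The convolution is evaluated exactly for a piecewise-linear plasma input
(linear between frame mid-times, zero at t = 0), which is stable for
k2 -> 0 and cheap.  Fits can truncate the acquisition (15- vs 30-min data)
and exclude the 2-10 min interval dominated by urine spill-over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .frames import FrameSchedule, SampledCurve, ValidationError, require_same_schedule

__all__ = [
    "CompartmentCurves",
    "FitWindow",
    "KineticFit",
    "solve_model",
    "fit_1tc",
    "apply_window",
    "window_mask",
    "goodness_of_fit",
    "FIT_VARIANTS",
]

#: Parameter bounds (K1 1/min, k2 1/min, vB): generous physiologic envelope.
BOUNDS_LO = np.array([0.0, 0.0, 0.0])
BOUNDS_HI = np.array([2.0, 1.0, 1.0])

#: Deterministic multi-start grid: log-spaced K1 x k2, vB always 0.1.
_K1_STARTS = np.array([0.01, 0.05, 0.2, 0.8])
_K2_STARTS = np.array([0.01, 0.1])
_VB_START = 0.1


@dataclass(frozen=True)
class CompartmentCurves:
    """Forward-model output: extravascular and operational curves."""

    c_ec: SampledCurve
    c_model: SampledCurve


@dataclass(frozen=True)
class FitWindow:
    """Which frames enter the fit.

    ``t_max`` truncates the acquisition (900 s for 15-min, 1800 s for 30-min
    variants); ``excluded`` is an optional closed [t_lo, t_hi] mid-time
    interval removed to suppress urine spill-over (default exclusion used in
    the "w/o 2 to 10 min" variants is (120, 600) s).
    """

    t_max: float = 1800.0
    excluded: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValidationError("t_max must be positive")
        if self.excluded is not None:
            lo, hi = self.excluded
            if not 0 <= lo < hi:
                raise ValidationError(f"invalid exclusion interval {self.excluded}")


#: The four fitting variants reported per kidney.
FIT_VARIANTS: dict[str, FitWindow] = {
    "PET-30": FitWindow(1800.0, None),
    "PET-30_wo2to10": FitWindow(1800.0, (120.0, 600.0)),
    "PET-15": FitWindow(900.0, None),
    "PET-15_wo2to10": FitWindow(900.0, (120.0, 600.0)),
}


@dataclass(frozen=True)
class KineticFit:
    """Fitted 1-tissue-compartment parameters with goodness of fit."""

    k1: float  # 1/min
    k2: float  # 1/min (urinary washout)
    vb: float  # dimensionless blood volume fraction
    chi2: float
    aic: float
    n_points: int
    window: FitWindow
    weights: str = "uniform"
    converged: bool = True
    n_starts_converged: int = 0


def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, accurate near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs * xs / 6.0
    xl = x[~small]
    out[~small] = -np.expm1(-xl) / xl
    return out


def _psi(x: np.ndarray) -> np.ndarray:
    """(1 - phi1(x)) / x  ->  1/2 as x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = 0.5 - xs / 6.0 + xs * xs / 24.0
    xl = x[~small]
    out[~small] = (1.0 - _phi1(xl)) / xl
    return out


def plasma_nodes(c_p: SampledCurve) -> tuple[np.ndarray, np.ndarray]:
    """Interpolation nodes for the piecewise-linear plasma input.

    Frame values sit at mid-times; a (0, 0) node is prepended (tracer-free
    blood before the scan start / bolus arrival).
    """
    t = c_p.mid_times
    p = c_p.values
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        p = np.concatenate(([0.0], p))
    return t, p


def _convolve_exp(t: np.ndarray, p: np.ndarray, k2_per_s: float) -> np.ndarray:
    """Exact convolution of piecewise-linear p(t) with exp(-k2 t) at the nodes.

    Returns u(t_i) = int_0^{t_i} p(tau) exp(-k2 (t_i - tau)) dtau  (units of
    p times seconds).  Recurrence with per-interval analytic integrals.
    """
    dt = np.diff(t)
    a = p[:-1]
    b = np.diff(p) / dt
    x = k2_per_s * dt
    seg = a * dt * _phi1(x) + b * dt * dt * _psi(x)
    decay = np.exp(-x)
    u = np.empty_like(t)
    u[0] = 0.0
    for i in range(dt.size):
        u[i + 1] = u[i] * decay[i] + seg[i]
    return u


def solve_model(
    k1: float,
    k2: float,
    vb: float,
    c_p: SampledCurve,
    c_aorta: SampledCurve,
) -> CompartmentCurves:
    """Forward-evaluate the model for K1, k2 (1/min) and blood fraction vB."""
    if k1 < 0 or k2 < 0:
        raise ValidationError("rate constants must be non-negative")
    if not 0 <= vb <= 1:
        raise ValidationError("vB must lie in [0, 1]")
    schedule = require_same_schedule(c_p, c_aorta)
    t, p = plasma_nodes(c_p)
    u = _convolve_exp(t, p, k2 / 60.0)  # internal rates in 1/s
    c_ec_nodes = (k1 / 60.0) * u
    c_ec = c_ec_nodes[-schedule.n_frames :]
    c_model = (1.0 - vb) * c_ec + vb * c_aorta.values
    return CompartmentCurves(
        c_ec=SampledCurve(schedule, c_ec),
        c_model=SampledCurve(schedule, c_model),
    )


def window_mask(schedule: FrameSchedule, window: FitWindow) -> np.ndarray:
    """Boolean mask of frames retained by a fit window (mid-time convention).

    A frame is kept if its mid-time is <= t_max and not inside the closed
    excluded interval.
    """
    mid = schedule.mid_times
    mask = mid <= window.t_max
    if window.excluded is not None:
        lo, hi = window.excluded
        mask &= ~((mid >= lo) & (mid <= hi))
    return mask


def apply_window(
    curve: SampledCurve, window: FitWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Return the (mid_times, values) retained by the window; error if empty."""
    mask = window_mask(curve.schedule, window)
    if not mask.any():
        raise ValidationError("fit window retains no frames")
    return curve.mid_times[mask], curve.values[mask]


def goodness_of_fit(
    residuals: np.ndarray, weights: np.ndarray, n_params: int = 3
) -> tuple[float, float]:
    """Weighted chi-square and AIC.

    chi2 = sum(w_i r_i^2); AIC = n ln(chi2 / n) + 2 k (may be negative).  A
    perfect fit (chi2 = 0) reports AIC = -inf.
    """
    residuals = np.asarray(residuals, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = residuals.size
    if n < n_params + 1:
        raise ValidationError(f"need at least {n_params + 1} points, got {n}")
    chi2 = float(np.sum(weights * residuals**2))
    aic = float("-inf") if chi2 == 0.0 else n * np.log(chi2 / n) + 2 * n_params
    return chi2, float(aic)


def _fit_weights(schedule: FrameSchedule, mask: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        return np.ones(int(mask.sum()))
    if scheme == "duration":
        return schedule.durations[mask].copy()
    raise ValidationError(f"unknown weighting scheme {scheme!r}")


def fit_1tc(
    tac: SampledCurve,
    plasma: SampledCurve,
    aorta: SampledCurve,
    window: FitWindow = FitWindow(),
    weights: str = "uniform",
) -> KineticFit:
    """Fit (K1, k2, vB) to a cortical TAC by bounded multi-start least squares.

    The objective is the weighted chi-square over the frames retained by
    ``window``; the forward model is always evaluated on the full schedule so
    the convolution sees the complete plasma history.  Eight deterministic
    starts on a log-spaced (K1, k2) grid guard against the local minima the
    operational curve develops under spill-over; ties break to the lowest
    chi-square, then the lowest K1.
    """
    schedule = require_same_schedule(tac, plasma, aorta)
    mask = window_mask(schedule, window)
    n_used = int(mask.sum())
    if n_used < 6:
        raise ValidationError(f"only {n_used} usable frames after windowing; need >= 6")
    w = _fit_weights(schedule, mask, weights)
    sqrt_w = np.sqrt(w)
    y = tac.values[mask]

    t, p = plasma_nodes(plasma)
    n_frames = schedule.n_frames
    aorta_v = aorta.values

    def model_masked(theta: np.ndarray) -> np.ndarray:
        k1, k2, vb = theta
        u = _convolve_exp(t, p, k2 / 60.0)
        c_ec = (k1 / 60.0) * u[-n_frames:]
        return ((1.0 - vb) * c_ec + vb * aorta_v)[mask]

    def residuals(theta: np.ndarray) -> np.ndarray:
        return sqrt_w * (y - model_masked(theta))

    best: tuple[float, float, np.ndarray] | None = None
    n_ok = 0
    for k1_0 in _K1_STARTS:
        for k2_0 in _K2_STARTS:
            x0 = np.array([k1_0, k2_0, _VB_START])
            res = least_squares(
                residuals, x0, bounds=(BOUNDS_LO, BOUNDS_HI), x_scale=[0.1, 0.05, 0.1]
            )
            if res.success:
                n_ok += 1
            chi2 = float(np.sum(res.fun**2))
            key = (chi2, float(res.x[0]))
            if best is None or key < best[:2]:
                best = (chi2, float(res.x[0]), res.x)
    assert best is not None
    theta = best[2]
    chi2, aic = goodness_of_fit(y - model_masked(theta), w)
    return KineticFit(
        k1=float(theta[0]),
        k2=float(theta[1]),
        vb=float(theta[2]),
        chi2=chi2,
        aic=aic,
        n_points=n_used,
        window=window,
        weights=weights,
        converged=n_ok > 0,
        n_starts_converged=n_ok,
    )
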