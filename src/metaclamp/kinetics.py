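"""Tracer-kinetic quantification of clamp and dynamic FDG-PET records.

This module implements the full quantification chain used on
hyperinsulinaemic-euglycaemic clamp + [18F]FDG studies:

* the Gjedde-Patlak graphical estimate of the fractional phosphorylation
  rate Ki from a tissue and a plasma time-activity curve,
* tissue glucose uptake from Ki, plasma glucose, tissue density and a
  lumped constant,
* the whole-body M value as the mean glucose infusion rate over three
  20-min steady-state intervals,
* the glucose rate of disappearance (Rd) from urinary-loss-corrected FDG
  plasma clearance, and
* endogenous glucose production as EGP = Rd - GIR.

A high-resolution forward solver for the irreversible two-tissue
compartment model is included as the independent oracle for the Patlak
estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .errors import ConfigurationError, DataError, EstimationError
from .records import ClampRecord, TimeActivityCurve

#: Lumped constants converting FDG trapping to glucose uptake per region.
LUMPED_CONSTANTS = {"muscle": 1.2, "liver": 1.0, "asat": 1.14}

#: Default tissue densities in kg/L; configurable in all public entry points.
TISSUE_DENSITIES = {"muscle": 1.04, "liver": 1.05, "asat": 0.92}

#: Default start of the Patlak linear window (min after injection).
DEFAULT_T_STAR = 20.0


# ---------------------------------------------------------------------------
# Gjedde-Patlak graphical analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatlakFit:
    """Result of a Gjedde-Patlak graphical fit.

    ``ki`` is the late-time slope (mL/min/mL), ``intercept`` the apparent
    initial distribution volume (mL/mL).
    """

    ki: float
    intercept: float
    t_star: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        return (
            f"Patlak fit: Ki = {self.ki:.5f} mL/min/mL, "
            f"V0 = {self.intercept:.3f} mL/mL, t* = {self.t_star:g} min, "
            f"R^2 = {self.r_squared:.4f}, n = {self.n_points}"
        )


def _plasma_running_integral(plasma: TimeActivityCurve) -> np.ndarray:
    """Trapezoidal running integral of Cp from time zero on the plasma grid.

    If the first sample is after t = 0 the curve is assumed to rise
    linearly from zero activity at injection.
    """
    integral = cumulative_trapezoid(plasma.activities, plasma.times, initial=0.0)
    if plasma.times[0] > 0:
        integral = integral + 0.5 * plasma.times[0] * plasma.activities[0]
    return integral


class PatlakModel:
    """Gjedde-Patlak graphical model for one tissue/plasma curve pair.

    The transformed coordinates are x(t) = int_0^t Cp dtau / Cp(t) and
    y(t) = Ct(t) / Cp(t); for an irreversibly trapped tracer y becomes
    linear in x beyond the free-compartment equilibration time t*, with
    slope Ki = K1 k3 / (k2 + k3).

    Examples
    --------
    >>> fit = PatlakModel(tissue, plasma).fit(t_star=20.0)
    >>> fit.ki
    """

    def __init__(self, tissue: TimeActivityCurve, plasma: TimeActivityCurve):
        if plasma.times[-1] < tissue.times[-1]:
            raise DataError("plasma curve must cover the tissue sampling window")
        self.tissue = tissue
        self.plasma = plasma

    def fit(self, t_star: float = DEFAULT_T_STAR) -> PatlakFit:
        plasma_int = _plasma_running_integral(self.plasma)
        cp = np.interp(self.tissue.times, self.plasma.times, self.plasma.activities)
        cp_int = np.interp(self.tissue.times, self.plasma.times, plasma_int)

        late = self.tissue.times >= t_star
        if late.sum() < 2:
            raise EstimationError(
                f"need >= 2 tissue samples at t >= t* = {t_star:g} min, "
                f"got {int(late.sum())}"
            )
        if np.any(cp[late] <= 0):
            raise DataError("plasma activity must be positive in the Patlak window")

        x = cp_int[late] / cp[late]
        y = self.tissue.activities[late] / cp[late]
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
        return PatlakFit(
            ki=float(slope),
            intercept=float(intercept),
            t_star=float(t_star),
            r_squared=min(1.0, r2),
            n_points=int(late.sum()),
        )


def patlak_ki(
    tissue: TimeActivityCurve,
    plasma: TimeActivityCurve,
    t_star: float = DEFAULT_T_STAR,
) -> PatlakFit:
    """Estimate the Patlak slope Ki; see :class:`PatlakModel`."""
    return PatlakModel(tissue, plasma).fit(t_star=t_star)


# ---------------------------------------------------------------------------
# Tissue glucose uptake
# ---------------------------------------------------------------------------

def tissue_glucose_uptake(
    fit: PatlakFit | float,
    plasma_glucose: float,
    region: str,
    densities: dict[str, float] | None = None,
    lumped_constants: dict[str, float] | None = None,
) -> float:
    """Glucose uptake in umol/(kg tissue)/min from a Patlak Ki.

    GU = Ki * [glucose] / (density * LC). Plasma glucose in mmol/L is
    converted to umol/L (factor 1000) so that dividing by the density in
    kg/L yields umol per kg of tissue per minute.
    """
    densities = TISSUE_DENSITIES if densities is None else densities
    lumped_constants = LUMPED_CONSTANTS if lumped_constants is None else lumped_constants
    if region not in lumped_constants or region not in densities:
        raise ConfigurationError(
            f"unknown region {region!r}; expected one of {sorted(lumped_constants)}"
        )
    ki = fit.ki if isinstance(fit, PatlakFit) else float(fit)
    if not np.isfinite(ki):
        raise DataError("Ki must be finite")
    if plasma_glucose <= 0:
        raise DataError("plasma glucose must be positive")
    glucose_umol_per_l = plasma_glucose * 1000.0
    return ki * glucose_umol_per_l / (densities[region] * lumped_constants[region])


# ---------------------------------------------------------------------------
# M value
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MValueResult:
    """Whole-body insulin-stimulated glucose uptake from the clamp trace."""

    m_value: float            # umol/kg/min
    steady_state_time: float  # min; first glucose sample at target
    tolerance: float          # mmol/L band used to declare steady state
    interval_means: tuple[float, float, float]


def m_value(
    clamp: ClampRecord,
    target: float = 5.0,
    tolerance: float = 0.3,
    interval_min: float = 20.0,
    n_intervals: int = 3,
) -> MValueResult:
    """Mean GIR over three consecutive 20-min intervals at euglycaemia.

    Steady state starts at the first glucose sample within
    ``target + tolerance``; an :class:`EstimationError` is raised when the
    clamp never reaches the target or ends before the averaging window.
    """
    at_target = clamp.glucose_values <= target + tolerance
    if not np.any(at_target):
        raise EstimationError(
            f"plasma glucose never reached {target:g} +/- {tolerance:g} mmol/L"
        )
    t0 = float(clamp.glucose_times[np.argmax(at_target)])
    window = interval_min * n_intervals
    if clamp.gir_times[-1] < t0 + window - 1e-9:
        raise EstimationError(
            f"GIR trace ends at {clamp.gir_times[-1]:g} min, "
            f"< {window:g} min after steady state at {t0:g} min"
        )
    means = []
    for i in range(n_intervals):
        lo, hi = t0 + i * interval_min, t0 + (i + 1) * interval_min
        sel = (clamp.gir_times >= lo) & (clamp.gir_times < hi)
        if not np.any(sel):
            raise EstimationError(f"no GIR samples in interval [{lo:g}, {hi:g}) min")
        means.append(float(clamp.gir_values[sel].mean()))
    return MValueResult(
        m_value=float(np.mean(means)),
        steady_state_time=t0,
        tolerance=tolerance,
        interval_means=tuple(means),
    )


# ---------------------------------------------------------------------------
# Rd from FDG clearance and EGP
# ---------------------------------------------------------------------------

def plasma_auc_with_tail(plasma: TimeActivityCurve, tail_points: int = 3) -> float:
    """Trapezoidal AUC of the plasma curve extrapolated to infinity.

    The tail beyond the last sample is the integral of a mono-exponential
    fitted by log-linear least squares to the final ``tail_points``
    samples. Units: kBq*min/mL.
    """
    if np.any(plasma.activities < 0):
        raise DataError("plasma activities must be non-negative")
    auc = float(np.trapezoid(plasma.activities, plasma.times))
    if plasma.times[0] > 0:
        auc += 0.5 * plasma.times[0] * plasma.activities[0]
    tail = plasma.activities[-tail_points:]
    times = plasma.times[-tail_points:]
    if np.all(tail > 0):
        slope, _ = np.polyfit(times, np.log(tail), 1)
        lam = -slope
        if lam > 1e-9:
            auc += float(tail[-1]) / lam
    return auc


def rate_of_disappearance(
    dose_mbq: float,
    urine_mbq: float,
    plasma: TimeActivityCurve,
    avg_glucose: float,
    weight: float,
    tail_points: int = 3,
) -> float:
    """Glucose rate of disappearance (umol/kg/min) from FDG clearance.

    Rd = (dose - urinary loss) / AUC(plasma FDG) * average plasma glucose,
    normalised per kg body weight. The dose is given in MBq and the plasma
    curve in kBq/mL, so the clearance is (dose - urine) * 1000 / AUC in
    mL/min; multiplying by glucose in mmol/L (= umol/mL) and dividing by
    the weight yields umol/kg/min.
    """
    if urine_mbq < 0 or dose_mbq <= urine_mbq:
        raise DataError("require dose > urine activity >= 0")
    if weight <= 0:
        raise DataError("weight must be positive")
    if avg_glucose <= 0:
        raise DataError("average plasma glucose must be positive")
    auc = plasma_auc_with_tail(plasma, tail_points=tail_points)
    if auc <= 0:
        raise DataError("plasma AUC must be positive")
    clearance_ml_min = (dose_mbq - urine_mbq) * 1000.0 / auc
    return clearance_ml_min * avg_glucose / weight


@dataclass(frozen=True)
class EGPResult:
    """Endogenous glucose production split into its defining terms."""

    rd: float          # umol/kg/min
    gir_steady: float  # umol/kg/min
    egp: float         # umol/kg/min; rd - gir_steady exactly


def endogenous_glucose_production(rd: float, gir_steady: float) -> EGPResult:
    """EGP = Rd - steady-state GIR; negative values are legal and preserved."""
    if not (np.isfinite(rd) and np.isfinite(gir_steady)):
        raise DataError("Rd and GIR must be finite")
    return EGPResult(rd=float(rd), gir_steady=float(gir_steady),
                     egp=float(rd) - float(gir_steady))


# ---------------------------------------------------------------------------
# Forward model: irreversible two-tissue compartment
# ---------------------------------------------------------------------------

def solve_irreversible_2tc(
    params: tuple[float, float, float],
    plasma: TimeActivityCurve,
    eval_times,
    dt: float = 0.05,
) -> TimeActivityCurve:
    """Exact-solution tissue curve for the irreversible two-tissue model.

    dC1/dt = K1 Cp - (k2 + k3) C1, dC2/dt = k3 C1, Ct = C1 + C2. The
    convolution is evaluated on a high-resolution grid (``dt`` minutes)
    with an exponentially-exact recursion, then interpolated at
    ``eval_times``. Serves both as the simulator's tissue forward model and
    as the independent oracle for :func:`patlak_ki`.
    """
    k1, k2, k3 = (float(v) for v in params)
    if min(k1, k2) <= 0 or k3 < 0:
        raise ConfigurationError("K1, k2 must be positive and k3 non-negative")
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.size == 0:
        raise DataError("eval_times must be non-empty")
    if eval_times.min() < 0:
        raise DataError("eval times must be non-negative")
    if eval_times.max() > plasma.times[-1] + 1e-9:
        raise DataError("eval time beyond plasma support")
    grid = np.arange(0.0, eval_times.max() + dt, dt)
    cp = np.interp(grid, plasma.times, plasma.activities, left=0.0)
    if plasma.times[0] > 0:
        # linear rise from zero at injection up to the first plasma sample
        rising = grid < plasma.times[0]
        cp[rising] = plasma.activities[0] * grid[rising] / plasma.times[0]

    beta = k2 + k3
    decay = math.exp(-beta * dt)
    # trapezoidal update of the linear ODE, exact in the homogeneous part:
    # C1[n] = decay*C1[n-1] + K1*dt/2 * (decay*Cp[n-1] + Cp[n])
    b = [k1 * dt / 2.0, k1 * dt / 2.0 * decay]
    a = [1.0, -decay]
    c1 = lfilter(b, a, cp)
    c1[0] = 0.0
    c2 = k3 * cumulative_trapezoid(c1, grid, initial=0.0)
    ct = np.interp(eval_times, grid, c1 + c2)
    return TimeActivityCurve(times=eval_times, activities=ct, label="tissue")


def patlak_ki_true(params: tuple[float, float, float]) -> float:
    """Closed-form net trapping rate K1*k3/(k2+k3) for the 2TC model."""
    k1, k2, k3 = params
    return k1 * k3 / (k2 + k3)
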