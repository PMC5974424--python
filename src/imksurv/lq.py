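"""Closed-form limits: continuous constant-dose-rate survival and the acute LQ.

When the cell state is constant during exposure, the fractionated
lethal-lesion yield collapses, in the limit of infinitely many infinitesimal
fractions, to the linear-quadratic model with the Lea-Catcheside dose-
protraction factor:

    -ln S = (alpha0 + gamma*beta0) D + q(rT) * beta0 * D^2,
    q(x)  = 2 (x + e^-x - 1) / x^2,   x = (a+c) T,  T = D / dose_rate.

q is the (0,1] multiplier on the quadratic coefficient accounting for repair
between the two lesions of a pair; T -> 0 recovers the acute LQ model.

This module also contains the regimen designer: the fractionation pattern
(fraction dose, uniform interval) whose mean dose-rate equals a prescribed
continuous dose-rate, plus the R^2 check that the two survival curves agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import CellStateTrajectory, DoseSchedule, IMKParameters, lethal_lesion_yield
from .errors import ConfigurationError, DataValidationError

__all__ = [
    "LQCoefficients",
    "lea_catcheside_factor",
    "lq_coefficients",
    "continuous_survival",
    "acute_lq",
    "design_equivalent_regimen",
    "regimen_equivalence_r2",
]


@dataclass(frozen=True)
class LQCoefficients:
    """Effective LQ coefficients of a protracted exposure of duration T."""

    alpha: float
    beta_eff: float
    delivery_time: float


def lea_catcheside_factor(repair_rate: float, duration: float) -> float:
    """Dose-protraction factor q in (0,1] for first-order repair.

    Parameters
    ----------
    repair_rate
        Composite lesion-removal rate (a + c), h^-1; must be > 0.
    duration
        Delivery time T, h; must be >= 0. T = 0 returns the acute limit 1.
    """
    if not (repair_rate > 0):
        raise DataValidationError(f"repair_rate must be > 0, got {repair_rate}")
    if duration < 0:
        raise DataValidationError(f"duration must be >= 0, got {duration}")
    x = repair_rate * duration
    if x < 1e-4:
        # series of 2(x + e^-x - 1)/x^2 about x = 0
        return 1.0 - x / 3.0 + x * x / 12.0
    return 2.0 * (x + math.expm1(-x)) / (x * x)


def lq_coefficients(params: IMKParameters, duration: float) -> LQCoefficients:
    """Effective (alpha, beta) of a constant-state exposure lasting T hours."""
    q = lea_catcheside_factor(params.repair_rate0, duration)
    return LQCoefficients(
        alpha=params.alpha_lq, beta_eff=q * params.beta0, delivery_time=duration
    )


def continuous_survival(dose, dose_rate: float, params: IMKParameters):
    """Survival after continuous exposure at a constant dose-rate.

    -ln S = (alpha0 + gamma*beta0) D + q((a+c) D/dose_rate) beta0 D^2.
    ``dose`` may be a scalar or array (Gy). Delivery ends with the dose: no
    post-irradiation repair term is included.
    """
    if not (dose_rate > 0):
        raise DataValidationError(f"dose_rate must be > 0, got {dose_rate}")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DataValidationError("dose must be >= 0")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    q = np.array([lea_catcheside_factor(params.repair_rate0, t) for t in d / dose_rate])
    neg_ln_s = params.alpha_lq * d + q * params.beta0 * d * d
    s = np.exp(-neg_ln_s)
    return float(s[0]) if scalar else s


def acute_lq(dose, params: IMKParameters):
    """Acute-exposure LQ survival: -ln S = (alpha0+gamma*beta0) D + beta0 D^2."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DataValidationError("dose must be >= 0")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    s = np.exp(-(params.alpha_lq * d + params.beta0 * d * d))
    return float(s[0]) if scalar else s


def design_equivalent_regimen(
    dose_rate: float, fraction_dose: float, total_time: float
) -> DoseSchedule:
    """Fractionation regimen whose mean dose-rate matches a continuous one.

    dT = fraction_dose / dose_rate and N = total_time / dT; N must come out
    integral (to within 1e-9 relative), otherwise the requested combination
    cannot tile the delivery time and a ConfigurationError is raised.
    """
    if dose_rate <= 0 or fraction_dose <= 0 or total_time <= 0:
        raise DataValidationError(
            "dose_rate, fraction_dose and total_time must all be > 0"
        )
    interval = fraction_dose / dose_rate
    n_exact = total_time / interval
    n = round(n_exact)
    if n < 1 or abs(n_exact - n) > 1e-9 * max(1.0, n_exact):
        raise ConfigurationError(
            f"total_time {total_time} h is not an integer number of "
            f"{interval} h intervals"
        )
    return DoseSchedule.uniform(fraction_dose, n, interval)


def regimen_equivalence_r2(schedule: DoseSchedule, params: IMKParameters) -> float:
    """R^2 between fractionated and continuous -lnS along the schedule.

    At each fraction boundary k the cumulative -lnS of the first k fractions
    (constant cell state) is compared with the continuous closed form at the
    same cumulative dose and T = D_k / mean dose-rate. The comparison grid is
    this package's convention for making the equivalence check reproducible.
    """
    from .evaluation import r_squared

    n = schedule.n_fractions
    if n < 2:
        raise ConfigurationError("R^2 needs at least two fractions")
    dose_rate = schedule.mean_dose_rate
    traj = CellStateTrajectory.constant(n, params.sldr_rate0)
    frac = np.empty(n)
    cont = np.empty(n)
    cum_dose = np.cumsum(schedule.fraction_doses)
    for k in range(1, n + 1):
        sub = schedule.truncated(k)
        sub_traj = CellStateTrajectory.constant(k, params.sldr_rate0)
        frac[k - 1] = lethal_lesion_yield(sub, sub_traj, params).w_mean
        d = cum_dose[k - 1]
        q = lea_catcheside_factor(params.repair_rate0, d / dose_rate)
        cont[k - 1] = params.alpha_lq * d + q * params.beta0 * d * d
    return r_squared(frac, cont)
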