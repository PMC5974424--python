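"""Cell-cycle-driven cell state: SLDR rate and DNA content during exposure.

Flow-cytometric time courses give, at each sampling time during a protracted
exposure, the percentage of cells in S phase N_S(t) and the relative mean DNA
content per nucleus <G>(t). Cells in S phase repair sub-lethal damage faster,
so the SLDR rate is modelled as linear in the S-phase fraction:

    c(t) = c0 + (dc/dN_S) * [N_S(t) - N_S(0)],

with the differential rate dc/dN_S obtained by differencing two steady cell
states of known SLDR rate and S-phase fraction (density-arrested plateau
culture vs actively cycling logarithmic-growth culture).

This module interpolates measured time courses (shape-preserving cubic,
constant beyond the sampled window), samples them at the fraction times of a
dose schedule to build a :class:`~imksurv.core.CellStateTrajectory`, and
converts baseline model parameters between the two growth phases via the
ratios of DNA moments and repair rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import CellStateTrajectory, DoseSchedule, IMKParameters
from .errors import ConfigurationError, DataValidationError, EstimationError

__all__ = [
    "CellPhaseStats",
    "CellCycleTimecourse",
    "differential_sldr_rate",
    "sldr_rate_at",
    "interpolate_timecourse",
    "build_trajectory",
    "convert_phase_parameters",
]

# repair can slow but never reverse: floor for the clamped SLDR rate, h^-1
_C_FLOOR = 1e-6


@dataclass(frozen=True)
class CellPhaseStats:
    """Cell-cycle distribution and cell state of a steady growth phase.

    ``g0g1``, ``s`` and ``g2m`` are the percentages of cells in G0/G1, S and
    G2/M (summing to ~100); ``g_rel`` and ``g2_rel`` are the mean DNA content
    per nucleus and its second moment relative to the reference (plateau)
    phase; ``c`` is the phase's SLDR rate in h^-1.
    """

    g0g1: float
    s: float
    g2m: float
    g_rel: float
    g2_rel: float
    c: float

    def __post_init__(self) -> None:
        for name in ("g0g1", "s", "g2m"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} percentage must be >= 0")
        total = self.g0g1 + self.s + self.g2m
        if not 98.0 <= total <= 102.0:
            raise DataValidationError(
                f"phase percentages must sum to ~100, got {total}"
            )
        for name in ("g_rel", "g2_rel", "c"):
            if not getattr(self, name) > 0:
                raise DataValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class CellCycleTimecourse:
    """Sampled S-phase fraction (%) and relative mean DNA during exposure."""

    times: tuple[float, ...]
    s_fraction_pct: tuple[float, ...]
    g_rel: tuple[float, ...]
    sd_s: tuple[float, ...] | None = None
    sd_g: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.times)
        ns = tuple(float(v) for v in self.s_fraction_pct)
        g = tuple(float(v) for v in self.g_rel)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "s_fraction_pct", ns)
        object.__setattr__(self, "g_rel", g)
        if not (len(t) == len(ns) == len(g)):
            raise ConfigurationError("times/s_fraction/g_rel lengths differ")
        arr = np.asarray(t)
        if len(t) and (arr[0] < 0 or np.any(np.diff(arr) <= 0)):
            raise DataValidationError("times must be >= 0 and strictly increasing")
        if any(v < 0 or v > 100 for v in ns):
            raise DataValidationError("S-phase fraction must lie in [0, 100] %")
        if any(v <= 0 for v in g):
            raise DataValidationError("relative DNA content must be > 0")

    def __len__(self) -> int:
        return len(self.times)


def differential_sldr_rate(phase_a: CellPhaseStats, phase_b: CellPhaseStats) -> float:
    """dc/dN_S (h^-1 per %) from differencing two steady growth phases.

    Order-invariant: the sign of both differences cancels.
    """
    d_ns = phase_b.s - phase_a.s
    if d_ns == 0:
        raise EstimationError(
            "phases have equal S-phase fractions; dc/dN_S is undefined"
        )
    return (phase_b.c - phase_a.c) / d_ns


def _interpolator(x: tuple[float, ...], y: tuple[float, ...]):
    """Shape-preserving cubic through the samples, constant outside."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    pchip = PchipInterpolator(x_arr, y_arr, extrapolate=False)

    def f(q):
        q = np.asarray(q, dtype=float)
        return pchip(np.clip(q, x_arr[0], x_arr[-1]))

    return f


def interpolate_timecourse(
    timecourse: CellCycleTimecourse, query_times
) -> tuple[np.ndarray, np.ndarray]:
    """(N_S, <G>) at the query times.

    Monotone-segment (shape-preserving) cubic interpolation, exact at the
    samples; queries outside the sampled window return the nearest endpoint
    value (constant extrapolation).
    """
    if len(timecourse) < 2:
        raise DataValidationError("interpolation needs >= 2 samples")
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    ns = _interpolator(timecourse.times, timecourse.s_fraction_pct)(q)
    g = _interpolator(timecourse.times, timecourse.g_rel)(q)
    return ns, g


def sldr_rate_at(
    t,
    timecourse: CellCycleTimecourse,
    c0: float,
    dc_dns: float,
):
    """SLDR rate c(t) = c0 + dc/dN_S * [N_S(t) - N_S(0)], h^-1.

    N_S is read from the interpolated time course; N_S(0) is its value at
    t = 0. Non-positive results are clamped to a small positive floor with a
    warning (a negative repair rate is unphysical).
    """
    if not c0 > 0:
        raise DataValidationError(f"c0 must be > 0, got {c0}")
    ns_t, _ = interpolate_timecourse(timecourse, t)
    ns_0, _ = interpolate_timecourse(timecourse, 0.0)
    c = c0 + dc_dns * (ns_t - ns_0[0])
    if np.any(c <= 0):
        warnings.warn(
            "S-phase-driven SLDR rate fell to or below zero; clamping to "
            f"{_C_FLOOR} h^-1",
            RuntimeWarning,
            stacklevel=2,
        )
        c = np.maximum(c, _C_FLOOR)
    return float(c[0]) if np.ndim(t) == 0 else c


def build_trajectory(
    schedule: DoseSchedule,
    timecourse: CellCycleTimecourse,
    params: IMKParameters,
    dc_dns: float,
    g2_mode: str = "square",
    anchors: tuple[CellPhaseStats, CellPhaseStats] | None = None,
) -> CellStateTrajectory:
    """Per-fraction cell state sampled from a measured time course.

    The time course is evaluated at the fraction times t_n = (n-1)*dT; a
    schedule longer than the measured window continues with the last sample
    (constant extrapolation), and a time course measured at one dose-rate may
    be applied to a schedule at another (transfer of cell-cycle kinetics).

    g2_mode
        ``"square"`` (default): <G_n^2>/<G_1^2> = (<G_n>/<G_1>)^2, exact when
        the shape of the DNA distribution does not change during exposure.
        ``"anchor"``: linear in N_S between two steady-phase anchors whose
        (s, g2_rel) pairs are supplied via ``anchors``.
    """
    t_n = schedule.fraction_times
    ns, g = interpolate_timecourse(timecourse, t_n)
    g = g / g[0]  # relative to the state at the first fraction

    c0 = params.sldr_rate0
    c = sldr_rate_at(t_n, timecourse, c0, dc_dns)
    c = np.atleast_1d(c)

    if g2_mode == "square":
        g2 = g * g
    elif g2_mode == "anchor":
        if anchors is None:
            raise ConfigurationError("g2_mode='anchor' requires two phase anchors")
        a, b = anchors
        if a.s == b.s:
            raise ConfigurationError("anchor phases must differ in S-phase fraction")
        frac = (ns - a.s) / (b.s - a.s)
        g2 = a.g2_rel + frac * (b.g2_rel - a.g2_rel)
        if np.any(g2 <= 0):
            raise DataValidationError(
                "anchor interpolation produced non-positive <G^2>"
            )
        g2 = g2 / g2[0]  # relative to the state at the first fraction
    else:
        raise ConfigurationError(f"unknown g2_mode {g2_mode!r}")

    return CellStateTrajectory(tuple(g), tuple(g2), tuple(c))


def convert_phase_parameters(
    params: IMKParameters,
    from_phase: CellPhaseStats,
    to_phase: CellPhaseStats,
) -> IMKParameters:
    """Convert baseline coefficients between growth phases.

    The microscopic lesion rates are cell-specific, so the phase dependence
    of alpha0 and beta0 enters only through the DNA moments and the repair
    rate:

        alpha0' = alpha0 * (g'/g) * (a+c)/(a+c')
        beta0'  = beta0 * (g2'/g2) * (a+c)/(a+c')

    gamma (physics) and a (cell-specific) are unchanged; the composite
    repair_rate0 becomes a + c'.
    """
    r_from = params.a_rate + from_phase.c
    r_to = params.a_rate + to_phase.c
    ratio = r_from / r_to
    return IMKParameters(
        alpha0=params.alpha0 * (to_phase.g_rel / from_phase.g_rel) * ratio,
        beta0=params.beta0 * (to_phase.g2_rel / from_phase.g2_rel) * ratio,
        repair_rate0=r_to,
        gamma=params.gamma,
        a_rate=params.a_rate,
    )
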