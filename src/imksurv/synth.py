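"""Synthetic-data generators emulating the study's experimental inputs.

No raw measurements are distributed with the package, so tests and examples
work on synthetic stand-ins generated from the model itself:

* clonogenic survival curves read off a fractionated regimen (one point per
  cumulative dose after each fraction), with multiplicative lognormal
  counting noise of a chosen coefficient of variation;
* split-dose recovery curves from the two-dose closed form;
* cell-cycle time courses with a smooth logistic rise of the S-phase
  fraction (the pattern seen during intermediate-dose-rate exposure, where
  cells accumulate in S phase over ~6 h) and the DNA content tied linearly
  to N_S between the plateau and logarithmic-growth anchor states, sampled
  on the flow-cytometry grid of every 2 h with optional Gaussian noise.

All generators take an explicit seed and are bitwise reproducible. The
default seed used by the CLI is 20180529.
"""

from __future__ import annotations

import math

import numpy as np

from .cellcycle import CellCycleTimecourse
from .core import DoseSchedule, IMKParameters, lethal_lesion_yield, CellStateTrajectory
from .errors import ConfigurationError, DataValidationError
from .evaluation import SurvivalCurve
from .lq import acute_lq
from .presets import PHASE_STATS
from .sldr import RecoveryCurve, split_dose_survival

__all__ = [
    "DEFAULT_SEED",
    "generate_synthetic_survival",
    "generate_synthetic_acute_survival",
    "generate_synthetic_recovery",
    "generate_synthetic_timecourse",
]

DEFAULT_SEED = 20180529

# dN_S -> d<G> slope between the plateau and log-phase anchor states
_PLATEAU = PHASE_STATS["cho-k1-plateau"]
_LOG = PHASE_STATS["cho-k1-log"]
_G_PER_NS = (_LOG.g_rel - _PLATEAU.g_rel) / (_LOG.s - _PLATEAU.s)


def _noisy_curve(dose, s_model, noise_cv, rng) -> SurvivalCurve:
    s_model = np.asarray(s_model, dtype=float)
    if noise_cv < 0:
        raise DataValidationError("noise_cv must be >= 0")
    if noise_cv == 0:
        s_obs = s_model
    else:
        # lognormal with unit mean and coefficient of variation noise_cv
        sigma = math.sqrt(math.log1p(noise_cv**2))
        s_obs = s_model * rng.lognormal(-0.5 * sigma**2, sigma, size=s_model.shape)
    s_obs = np.minimum(s_obs, 1.0)
    sd = None if noise_cv == 0 else tuple(noise_cv * s_obs)
    return SurvivalCurve(
        dose=tuple(np.asarray(dose, dtype=float)),
        survival=tuple(s_obs),
        sd=sd,
        provenance="measured" if noise_cv > 0 else "modelled",
    )


def generate_synthetic_survival(
    params: IMKParameters,
    schedule: DoseSchedule,
    noise_cv: float = 0.0,
    seed: int = DEFAULT_SEED,
    trajectory: CellStateTrajectory | None = None,
) -> SurvivalCurve:
    """Survival-vs-cumulative-dose curve along a fractionated regimen.

    One point per fraction boundary: dose = sum of the first k fraction
    doses, survival = model value for the first k fractions, multiplied by
    lognormal noise with coefficient of variation ``noise_cv`` (SD column =
    noise_cv * S). ``noise_cv = 0`` returns the exact model curve.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_fractions
    doses = np.cumsum(schedule.fraction_doses)
    s = np.empty(n)
    for k in range(1, n + 1):
        sub = schedule.truncated(k)
        sub_traj = None
        if trajectory is not None:
            sub_traj = CellStateTrajectory(
                trajectory.g_rel[:k], trajectory.g2_rel[:k], trajectory.c[:k]
            )
        s[k - 1] = lethal_lesion_yield(sub, sub_traj, params).survival
    return _noisy_curve(doses, s, noise_cv, rng)


def generate_synthetic_acute_survival(
    params: IMKParameters,
    doses,
    noise_cv: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> SurvivalCurve:
    """Acute-exposure survival curve on an explicit dose grid."""
    rng = np.random.default_rng(seed)
    d = np.asarray(doses, dtype=float)
    return _noisy_curve(d, acute_lq(d, params), noise_cv, rng)


def generate_synthetic_recovery(
    params: IMKParameters,
    d1: float,
    d2: float,
    taus,
    noise_cv: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> RecoveryCurve:
    """Split-dose recovery curve, optionally with lognormal counting noise."""
    rng = np.random.default_rng(seed)
    tau = np.asarray(taus, dtype=float)
    s = split_dose_survival(d1, d2, tau, params)
    noisy = _noisy_curve(tau, s, noise_cv, rng)
    return RecoveryCurve(
        d1=d1, d2=d2, tau=tuple(tau), survival=noisy.survival, sd=noisy.sd
    )


def generate_synthetic_timecourse(
    pattern: str = "logistic",
    magnitude: float = 37.5,
    t_max: float = 12.0,
    seed: int = DEFAULT_SEED,
    *,
    ns0: float = 14.9,
    g_per_ns: float = _G_PER_NS,
    sample_interval: float = 2.0,
    noise_sd_ns: float = 0.0,
    noise_sd_g: float = 0.0,
) -> CellCycleTimecourse:
    """Cell-cycle time course with an S-phase rise of ``magnitude`` percent.

    ``pattern`` is ``"logistic"`` (smooth rise centred mid-exposure, the
    measured behaviour at intermediate dose-rates), ``"linear"``, or
    ``"flat"`` (no change). N_S starts at ``ns0`` (default: the plateau-phase
    value) and ends at ``ns0 + magnitude``; the relative mean DNA content is
    tied to N_S with slope ``g_per_ns`` (default: the plateau-to-log anchor
    slope, so a rise of 37.5 % ends exactly at the logarithmic-phase state).
    Samples fall every ``sample_interval`` h from 0 to ``t_max`` (default the
    flow-cytometry grid 0, 2, ..., 12 h); optional Gaussian noise is added to
    the sampled values.
    """
    if t_max <= 0 or sample_interval <= 0:
        raise DataValidationError("t_max and sample_interval must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + 1e-9, sample_interval)
    if pattern == "flat":
        shape = np.zeros_like(t)
    elif pattern == "linear":
        shape = t / t_max
    elif pattern == "logistic":
        scale = t_max / 8.0
        raw = 1.0 / (1.0 + np.exp(-(t - t_max / 2.0) / scale))
        lo = 1.0 / (1.0 + math.exp(t_max / 2.0 / scale))
        hi = 1.0 / (1.0 + math.exp(-t_max / 2.0 / scale))
        shape = (raw - lo) / (hi - lo)
    else:
        raise ConfigurationError(f"unknown pattern {pattern!r}")

    ns = ns0 + magnitude * shape
    g = 1.0 + g_per_ns * (ns - ns0)
    if noise_sd_ns > 0:
        ns = ns + rng.normal(0.0, noise_sd_ns, size=ns.shape)
    if noise_sd_g > 0:
        g = g + rng.normal(0.0, noise_sd_g, size=g.shape)
    ns = np.clip(ns, 0.0, 100.0)
    g = np.maximum(g, 1e-6)
    return CellCycleTimecourse(
        times=tuple(t), s_fraction_pct=tuple(ns), g_rel=tuple(g)
    )
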