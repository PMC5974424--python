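"""File I/O: CSV tables, TOML parameter configs and named presets.

All tables use a comma-separated, dot-decimal, header-required dialect.
Units are fixed throughout: times in hours, doses in Gy, rates in h^-1,
S-phase fractions in percent. Writers emit full double precision so every
table round-trips through its reader.
"""

from __future__ import annotations

import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .cellcycle import CellCycleTimecourse
from .core import DoseSchedule, CellStateTrajectory, IMKParameters
from .errors import ConfigurationError, DataValidationError
from .evaluation import SurvivalCurve
from .presets import PARAMETER_PRESETS
from .sldr import RecoveryCurve

__all__ = [
    "load_parameters",
    "read_schedule_csv",
    "write_schedule_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_recovery_csv",
    "write_recovery_csv",
    "read_survival_csv",
    "write_survival_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

logger = logging.getLogger("imksurv")

_FLOAT_FMT = "%.17g"

_PARAM_KEYS = {"alpha0", "beta0", "repair_rate0", "gamma", "a_rate"}


def load_parameters(source) -> IMKParameters:
    """Model parameters from a preset name, a TOML file path, or a mapping.

    TOML layout::

        [params]
        alpha0 = 0.155        # Gy^-1
        beta0 = 0.048         # Gy^-2
        repair_rate0 = 0.704  # h^-1
        gamma = 0.924         # Gy
        a_rate = 0.0          # h^-1, optional
    """
    if isinstance(source, IMKParameters):
        return source
    if isinstance(source, dict):
        return _params_from_mapping(source)
    name = str(source)
    if name in PARAMETER_PRESETS:
        logger.info("parameters loaded from preset %r", name)
        return PARAMETER_PRESETS[name]
    path = Path(name)
    if path.exists():
        with path.open("rb") as fh:
            try:
                doc = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
        table = doc.get("params")
        if table is None:
            raise ConfigurationError(f"{path} is missing the [params] table")
        logger.info("parameters loaded from file %s", path)
        return _params_from_mapping(table)
    raise ConfigurationError(
        f"{name!r} is neither a known preset "
        f"({', '.join(sorted(PARAMETER_PRESETS))}) nor an existing file"
    )


def _params_from_mapping(table: dict) -> IMKParameters:
    unknown = set(table) - _PARAM_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown parameter key(s): {', '.join(sorted(unknown))}"
        )
    missing = _PARAM_KEYS - {"a_rate"} - set(table)
    if missing:
        raise ConfigurationError(
            f"missing parameter key(s): {', '.join(sorted(missing))}"
        )
    try:
        values = {k: float(v) for k, v in table.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"non-numeric parameter value: {exc}") from exc
    return IMKParameters(**values)


def _read_csv(path, expected_cols: list[str], optional_cols: list[str] = ()):
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise DataValidationError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def read_schedule_csv(path) -> DoseSchedule:
    """Schedule table: ``fraction_index,dose_Gy,start_time_h`` (1-based index).

    Start times must be uniformly spaced; non-uniform schedules are rejected
    because the lesion-yield closed form assumes a single interval.
    """
    df = _read_csv(path, ["fraction_index", "dose_Gy", "start_time_h"])
    df = df.sort_values("fraction_index")
    idx = df["fraction_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise DataValidationError(f"{path}: fraction_index must be 1..N contiguous")
    t = df["start_time_h"].to_numpy(dtype=float)
    if len(t) == 1:
        if t[0] != 0:
            raise DataValidationError(f"{path}: the first fraction must start at 0 h")
        interval = 1.0  # arbitrary for a single acute fraction
    else:
        gaps = np.diff(t)
        if t[0] != 0 or np.any(gaps <= 0):
            raise DataValidationError(
                f"{path}: start times must begin at 0 and increase"
            )
        if np.max(gaps) - np.min(gaps) > 1e-9 * np.max(gaps):
            raise DataValidationError(
                f"{path}: non-uniform fraction intervals are not supported"
            )
        interval = float(np.mean(gaps))
    return DoseSchedule(tuple(df["dose_Gy"].to_numpy(dtype=float)), interval)


def write_schedule_csv(schedule: DoseSchedule, path) -> None:
    df = pd.DataFrame(
        {
            "fraction_index": np.arange(1, schedule.n_fractions + 1),
            "dose_Gy": schedule.fraction_doses,
            "start_time_h": schedule.fraction_times,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> CellStateTrajectory:
    """Trajectory table: ``fraction_index,g_rel,g2_rel,c_per_h``."""
    df = _read_csv(path, ["fraction_index", "g_rel", "g2_rel", "c_per_h"])
    df = df.sort_values("fraction_index")
    return CellStateTrajectory(
        tuple(df["g_rel"].to_numpy(dtype=float)),
        tuple(df["g2_rel"].to_numpy(dtype=float)),
        tuple(df["c_per_h"].to_numpy(dtype=float)),
    )


def write_trajectory_csv(trajectory: CellStateTrajectory, path) -> None:
    df = pd.DataFrame(
        {
            "fraction_index": np.arange(1, len(trajectory) + 1),
            "g_rel": trajectory.g_rel,
            "g2_rel": trajectory.g2_rel,
            "c_per_h": trajectory.c,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recovery_csv(path) -> RecoveryCurve:
    """Recovery table: ``# d1_Gy=``/``# d2_Gy=`` metadata then ``tau_h,survival[,sd]``."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    pass
    for key in ("d1_Gy", "d2_Gy"):
        if key not in meta:
            raise DataValidationError(f"{path}: missing '# {key}=' metadata line")
    df = _read_csv(path, ["tau_h", "survival"])
    sd = None
    if "sd" in df.columns and df["sd"].notna().all():
        sd = tuple(df["sd"].to_numpy(dtype=float))
    return RecoveryCurve(
        d1=meta["d1_Gy"],
        d2=meta["d2_Gy"],
        tau=tuple(df["tau_h"].to_numpy(dtype=float)),
        survival=tuple(df["survival"].to_numpy(dtype=float)),
        sd=sd,
    )


def write_recovery_csv(curve: RecoveryCurve, path) -> None:
    df = pd.DataFrame({"tau_h": curve.tau, "survival": curve.survival})
    if curve.sd is not None:
        df["sd"] = curve.sd
    with open(path, "w") as fh:
        fh.write(f"# d1_Gy={curve.d1!r}\n# d2_Gy={curve.d2!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_survival_csv(path, provenance: str = "measured") -> SurvivalCurve:
    """Survival table: ``dose_Gy,survival[,sd]``."""
    df = _read_csv(path, ["dose_Gy", "survival"])
    sd = None
    if "sd" in df.columns and df["sd"].notna().all():
        sd = tuple(df["sd"].to_numpy(dtype=float))
    return SurvivalCurve(
        dose=tuple(df["dose_Gy"].to_numpy(dtype=float)),
        survival=tuple(df["survival"].to_numpy(dtype=float)),
        sd=sd,
        provenance=provenance,
    )


def write_survival_csv(curve: SurvivalCurve, path) -> None:
    df = pd.DataFrame({"dose_Gy": curve.dose, "survival": curve.survival})
    if curve.sd is not None:
        df["sd"] = curve.sd
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_timecourse_csv(path) -> CellCycleTimecourse:
    """Time-course table: ``time_h,s_fraction_pct,g_rel[,sd_s,sd_g]``."""
    df = _read_csv(path, ["time_h", "s_fraction_pct", "g_rel"])
    kwargs = {}
    for col, name in (("sd_s", "sd_s"), ("sd_g", "sd_g")):
        if col in df.columns and df[col].notna().all():
            kwargs[name] = tuple(df[col].to_numpy(dtype=float))
    return CellCycleTimecourse(
        times=tuple(df["time_h"].to_numpy(dtype=float)),
        s_fraction_pct=tuple(df["s_fraction_pct"].to_numpy(dtype=float)),
        g_rel=tuple(df["g_rel"].to_numpy(dtype=float)),
        **kwargs,
    )


def write_timecourse_csv(timecourse: CellCycleTimecourse, path) -> None:
    df = pd.DataFrame(
        {
            "time_h": timecourse.times,
            "s_fraction_pct": timecourse.s_fraction_pct,
            "g_rel": timecourse.g_rel,
        }
    )
    if timecourse.sd_s is not None:
        df["sd_s"] = timecourse.sd_s
    if timecourse.sd_g is not None:
        df["sd_g"] = timecourse.sd_g
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
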