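"""Packaged parameter sets for the CHO-K1 cell line (250 kVp X-rays).

Two cell conditions ship as named presets: the density-arrested plateau
phase (mostly G0/G1, the reference state) and the actively cycling
logarithmic growth phase (high S-phase fraction, faster SLDR, more DNA per
nucleus). The logarithmic-phase coefficients follow from the plateau set via
the DNA-moment and repair-rate ratios (see
:func:`imksurv.cellcycle.convert_phase_parameters`).
"""

from __future__ import annotations

from .cellcycle import CellPhaseStats
from .core import IMKParameters, MicrodosimetryContext

__all__ = ["PARAMETER_PRESETS", "PHASE_STATS", "MICRODOSIMETRY"]

# domain radius 0.5 um in unit-density (water) tissue; gamma for 250 kVp X-rays
MICRODOSIMETRY = MicrodosimetryContext(
    y_d=0.924 * 3.141592653589793 * 0.25, rho=1.0, r_d=0.5
)

PARAMETER_PRESETS: dict[str, IMKParameters] = {
    "cho-k1-plateau": IMKParameters(
        alpha0=0.155,  # Gy^-1
        beta0=0.048,  # Gy^-2
        repair_rate0=0.704,  # h^-1 (a + c, dominated by SLDR)
        gamma=0.924,  # Gy
    ),
    "cho-k1-log": IMKParameters(
        alpha0=0.075,
        beta0=0.028,
        repair_rate0=1.782,
        gamma=0.924,
    ),
}

PHASE_STATS: dict[str, CellPhaseStats] = {
    "cho-k1-plateau": CellPhaseStats(
        g0g1=72.7, s=14.9, g2m=12.4, g_rel=1.0, g2_rel=1.0, c=0.704
    ),
    "cho-k1-log": CellPhaseStats(
        g0g1=37.6, s=52.4, g2m=11.4, g_rel=1.227, g2_rel=1.457, c=1.782
    ),
}
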