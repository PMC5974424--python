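# imksurv

Integrated microdosimetric-kinetic (IMK) modelling of clonogenic cell
survival under protracted and fractionated irradiation, for computational
radiobiologists studying dose-rate effects.

## The problem

During a long exposure, sub-lethal damage repair (SLDR) competes with lesion
induction, so survival depends not only on the total dose D but on how it is
spread over time. The classic microdosimetric-kinetic (MK) picture treats the
cell state as frozen during irradiation. In reality the cell-cycle
distribution shifts while the beam is on — at intermediate dose-rates cells
accumulate in S phase, which repairs sub-lethal damage faster — and this can
*reverse* the usual dose-rate sparing (inverse dose-rate effects).

## The model

The nucleus is divided into micron-scale domains. Fraction n deposits
specific energy z_n at time (n−1)ΔT and creates potentially lethal lesions
in proportion to the DNA mass in the domain; each cohort decays with its own
composite repair rate (a + c_n). The mean lethal-lesion yield per nucleus is

    ⟨w⟩_T = Σₙ [(αₙ + γβₙ) zₙ + βₙ zₙ²]
          + 2 Σ_{n<m} β_nm exp(−(m−n)(a+cₙ)ΔT) zₙ z_m ,

with per-fraction coefficients carried relative to the baseline state
(α₀ Gy⁻¹, β₀ Gy⁻², γ Gy):

    αₙ = α₀ · (⟨Gₙ⟩/⟨G₁⟩) · (a+c₁)/(a+cₙ),
    βₙ = β₀ · (⟨Gₙ²⟩/⟨G₁²⟩) · (a+c₁)/(a+cₙ),
    β_nm = β₀ · (⟨Gₙ⟩⟨G_m⟩/⟨G₁⟩²) · 2(a+c₁)/[(a+cₙ)+(a+c_m)],

and S = exp(−⟨w⟩_T) under Poisson-distributed lethal lesions. The SLDR rate
tracks the S-phase fraction, c(t) = c₀ + (dc/dN_S)·ΔN_S(t), with N_S(t) and
the relative DNA content ⟨G⟩(t) interpolated from flow-cytometry time
courses. With a constant cell state the model collapses to the LQ model with
the Lea-Catcheside protraction factor

    −ln S = (α₀ + γβ₀) D + q·β₀ D²,   q = 2[x + e⁻ˣ − 1]/x²,  x = (a+c)T,

and for T → 0 to the acute LQ model.

Companion tools: split-dose recovery curves and estimation of (a+c) from
them (exact and published finite-data conventions), mean inactivation dose
D̄ = ∫₀^∞ S(D) dD, reduced χ² and R² fit metrics, a designer for
fractionation regimens equivalent to a continuous dose-rate, and synthetic
generators for survival curves, recovery curves and cell-cycle time courses.
CHO-K1 parameter sets for plateau and logarithmic growth phases ship as the
presets `cho-k1-plateau` and `cho-k1-log`.

## Worked example

Design the fractionation regimen equivalent to continuous 3.0 Gy/h delivered
for 12 h, check its equivalence, and compare mean inactivation doses with
and without the S-phase-driven SLDR rise:

```sh
$ imk regimen --dose-rate 3.0 --fraction-dose 1.5 --time 12 --out sched.csv
n_fractions=24 interval_h=0.5 total_dose_Gy=36 equivalence_r2=0.999703

$ imk survive --schedule sched.csv
total_dose_Gy=36
neg_ln_S=20.3307
survival=1.48082e-09

$ imk dbar                      # acute exposure, plateau-phase CHO-K1
mean_inactivation_dose_Gy=2.58695

$ imk dbar --dose-rate 3.0      # constant SLDR during protracted delivery
mean_inactivation_dose_Gy=2.87014

$ imk synth timecourse --out tc.csv   # S-phase rise to the log-phase state
$ imk dbar --dose-rate 3.0 --timecourse tc.csv --dc-dns 0.0287
mean_inactivation_dose_Gy=2.91371
```

Reading the numbers: 24 fractions of 1.5 Gy every 30 min reproduce the
continuous 3.0 Gy/h survival curve with R² > 0.999, so the regimen is a
valid experimental stand-in for the continuous exposure. Protracting the
delivery raises D̄ from 2.59 Gy (acute) to 2.87 Gy (repair during delivery),
and letting the SLDR rate rise with the S-phase fraction raises it further
to 2.91 Gy — the radio-resistance that a constant-repair model misses.

The same operations are available as a library:

```python
from imksurv import (PARAMETER_PRESETS, design_equivalent_regimen,
                     survival, repair_half_time)

params = PARAMETER_PRESETS["cho-k1-plateau"]
schedule = design_equivalent_regimen(3.0, 1.5, 12.0)
print(survival(schedule, params=params))        # 1.4808e-09
print(repair_half_time(params.repair_rate0))    # 0.9846 h
```

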