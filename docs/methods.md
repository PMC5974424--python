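# Methods

## Model

The package implements the integrated microdosimetric-kinetic (IMK) model of
clonogenic survival. The nucleus is partitioned into domains (radius r_d =
0.5 µm, unit-density tissue); a dose fraction deposits specific energy z per
domain and induces potentially lethal lesions (PLLs) proportional to the DNA
mass g in the domain. PLLs convert to lethal lesions at first-order rate a,
pair into lethal lesions at a second-order rate, or are repaired (SLDR) at
first-order rate c. Because the pairing term is negligible in the PLL
balance, the cohort created by fraction n decays exponentially at the
composite rate (a + c_n) — crucially, the rate in force *at the fraction's
delivery*, so a cell-cycle shift changes how later cohorts, not earlier
ones, decay.

Summing lethal-lesion production over fractions and averaging over the
specific-energy and DNA-mass distributions gives

    <w>_T = sum_n [(alpha_n + gamma*beta_n) z_n + beta_n z_n^2]
          + 2 sum_{n<m} beta_nm exp(-(m-n)(a+c_n) dT) z_n z_m,

with survival S = exp(-<w>_T) under the Poisson assumption. The microscopic
constants (PLL induction coefficient k_d, pairing rate b_d, domain count p,
the densities f_z and f_g) are not identifiable from survival data; they are
absorbed into the baseline coefficients alpha0 = A_1<G_1>, beta0 =
B_1<G_1^2>/p and gamma = y_D/(rho*pi*r_d^2), and per-fraction coefficients
are carried relative to the baseline state (ratios of DNA moments and repair
rates). With a constant trajectory every coefficient reduces to its baseline
value and the model is the classic MK model; in the many-fraction limit it
is the LQ model with the Lea-Catcheside protraction factor, and for T -> 0
the acute LQ model.

### Assumptions

- Fractions are instantaneous impulses at the starts of uniform intervals;
  the yield is evaluated after the last fraction with full inter-fraction
  decay. Non-uniform intervals are rejected rather than silently
  generalized, since the closed form assumes one dT.
- The cross-term decay uses (a+c_n) of the *earlier* fraction, as the
  solution of the lesion kinetics prescribes. A symmetrized variant
  ((a+c_n)+(a+c_m))/2 is available via ``cross_rate="mean"`` for sensitivity
  analysis only; it is not part of the model.
- a defaults to 0 and the composite (a+c) is carried as one rate
  (``repair_rate0``), because a is known only to be a few percent of c. A
  nonzero a may be supplied; all exponents and coefficient ratios then use
  the exact (a+c_n).
- Lethal lesions are Poisson across nuclei; zero lethal lesions defines
  clonogenic survival.
- Only the moment summary gamma of the specific-energy distribution enters;
  per-domain stochastic sampling of microdosimetric spectra is out of scope.

## Parameters

| parameter | units | plateau preset | log preset | meaning |
|---|---|---|---|---|
| alpha0 | Gy^-1 | 0.155 | 0.075 | linear coefficient at baseline state |
| beta0 | Gy^-2 | 0.048 | 0.028 | quadratic coefficient at baseline state |
| repair_rate0 (a+c) | h^-1 | 0.704 | 1.782 | composite SLDR rate |
| gamma | Gy | 0.924 | 0.924 | single-event dose-mean specific energy (250 kVp X-rays, r_d = 0.5 µm) |
| a_rate | h^-1 | 0 | 0 | lethal-conversion rate (optional) |

The log-phase preset equals the plateau preset converted through the
measured DNA-moment ratios (<G> 1.227, <G^2> 1.457) and repair-rate ratio
(0.704/1.782), rounded to the printed precision. dc/dN_S = (1.782 −
0.704)/(52.4 − 14.9) ≈ 0.0287 h^-1 per percent S-phase.

## Cell-cycle-driven state

Measured time courses (S-phase percentage N_S(t), relative mean DNA content
<G>(t)) are interpolated with a shape-preserving monotone cubic (PCHIP) —
exact at samples, no overshoot between them — and held constant outside the
sampled window, so schedules longer than the measurement continue with the
last observed state. The SLDR rate is c(t) = c0 + (dc/dN_S)(N_S(t) −
N_S(0)), clamped at 1e-6 h^-1 with a warning if a strongly negative
differential rate would drive it non-positive. The trajectory samples the
splines at the fraction times (n−1)dT; sampling per fraction rather than per
measurement bin is this package's convention.

<G^2>(t) is not measured. Two conventions are implemented and exposed:
``square`` (default) sets <G_n^2>/<G_1^2> = (<G_n>/<G_1>)^2, exact when the
shape of the DNA distribution is invariant during exposure; ``anchor``
interpolates <G^2> linearly in N_S between the two steady-phase anchor
values. Both are conventions, not measurements; they differ by ~3 % at the
log-phase endpoint (1.227^2 = 1.506 vs 1.457).

## Estimators and conventions

**Split-dose SLDR rate.** (a+c) = [lim_{tau->0} d(lnS)/dtau] /
ln[S(inf)/S(0)]. The default ``paper`` mode follows the published
finite-data convention — secant slope of lnS over 0–1 h, S(inf) = maximum
survival up to the 2 h interval (longer intervals are confounded by
re-distribution and repopulation). On an exact model curve this estimator is
deterministically biased low by the factor (1 − e^{−r·tau1}) / (r·tau1·(1 −
e^{−r·tau2})) with tau1 = 1 h and tau2 = 2 h: the secant under-reads the
initial slope by (1 − e^{−r})/r and the 2 h plateau under-reads the full
recovery by (1 − e^{−2r}). The ``exact`` mode instead least-squares fits
lnS(tau) = A − B e^{−r·tau} and recovers the generating rate to machine
precision on model-generated curves; it exists for synthetic validation.
Both modes work on lnS ratios only, so a common plating-efficiency factor
cancels.

**Regimen equivalence.** The designer returns dT = fraction_dose/dose_rate
and N = total_time/dT (rejecting non-integral N). Equivalence to the
continuous closed form is scored by R^2 between the two −lnS series
evaluated at the cumulative dose after each fraction, with T = D/dose-rate
on the continuous side; the fraction-boundary grid is this package's
reproducible convention for what was originally a visual comparison. The
designed 3.0 Gy/h (1.5 Gy × 24, 30 min) and 6.0 Gy/h (2.0 Gy × 36, 20 min)
regimens score 0.99970 and 0.99992 with the plateau parameters.

**Mean inactivation dose.** Dbar = ∫ S dD by adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 1e-8); the upper limit doubles
from 1 Gy until S < 1e-12 and a non-decaying survival function raises
rather than returning a truncated integral. Protracted-exposure response
curves are evaluated by micro-fractionating the delivery (default 200
fractions per dose point, which reproduces the continuous closed form to
well under 0.1 %); Dbar sweeps in the test suite use 100 micro-fractions to
keep the full suite under a few seconds without changing any conclusion.

**Fit metrics.** Reduced chi-square (1/n) Σ (S_exp − S_model)^2/σ^2 on
matched dose grids, and the standard coefficient of determination R^2 = 1 −
SS_res/SS_tot.

## Numerical choices

- Exponents are clamped at −700 before exponentiation; a lethal-lesion yield
  whose survival would underflow 1e-300 reports S = 0 with a warning.
- The protraction factor uses a series expansion below x = 1e-4 to avoid
  cancellation in 2(x + e^{−x} − 1)/x^2.
- The cross term uses an O(N) backward recurrence when all composite rates
  are equal (constant-rate fast path, used by the micro-fraction limits) and
  a memory-chunked O(N^2) evaluation otherwise.
- Fractionated/continuous convergence is verified at N = 1000 (relative
  error < 1e-3) and N = 10^4; the lesion-kinetics profile is verified
  against direct numerical integration of the per-cohort decay ODE at
  relative tolerance 1e-8.

## Synthetic data

The generators emulate the study's inputs, not any particular dataset:
survival curves are read off a regimen at each fraction boundary with
multiplicative lognormal noise of chosen coefficient of variation (SD column
= cv·S); recovery curves come from the split-dose closed form; time courses
are logistic (or linear/flat) N_S rises sampled every 2 h over 0–12 h — the
flow-cytometry grid — with <G> tied to N_S by the plateau→log anchor slope,
so the default rise of 37.5 percentage points ends exactly at the
logarithmic-growth state. Defaults (plateau start N_S = 14.9 %, 12 h window)
are the plateau-phase study conditions. What synthetic data do *not*
emulate: redistribution and repopulation during split intervals, G2/M
accumulation at low dose-rates, checkpoint dynamics, or measurement-grade
flow-cytometry histogram noise. Passing parameter-recovery tests therefore
demonstrates estimator correctness under the model's own assumptions, not
robustness to those biological confounders.

All randomness flows through explicit seeds (`numpy.random.default_rng`);
the CLI default seed is 20180529.

## Known limitations

- Uniform fraction intervals only; arbitrary timing requires composing
  separate exposures by survival multiplication, which ignores cross-fraction
  pairing between the segments.
- The S-phase/SLDR link is linear with a single differential rate; saturation
  at high S fractions is not modelled.
- G2/M radio-sensitization (relevant near 1 Gy/h) is not represented — only
  the DNA-content and repair-rate channels are.
- The measured survival datasets behind the original parameter values are
  not redistributable; quantitative goodness-of-fit against them is outside
  the package's scope, and the fit metrics are provided for users' own data.
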