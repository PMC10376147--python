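# Methods

`strainchar` models batch and pulsed-batch cultivations of *Escherichia coli*
strains with impaired glucose uptake (W3110 ΔptsG derivatives WG, WGM, WGP),
generates realistic multi-platform synthetic datasets, and estimates the
strain parameters back from them. This note documents the model, its
assumptions, the numerical choices, and — importantly — which parameters the
different experiment types can and cannot identify.

## 1. Growth model

State variables: biomass `X` [g DCW/L], glucose `S` [g/L], acetate `A`
[g/L], dissolved oxygen tension `DOT` [% air saturation].

Specific rates (per g biomass per h):

```
q_S   = q_S_max · S/(S + K_S)                       glucose uptake (Monod)
q_Ap  = q_Ap_max · S/(S + K_S)                      overflow acetate production
q_Ac  = q_Ac_max · A/(A+K_A) · K_IS/(K_IS+S) · DOT/(DOT+K_O)
                                                    acetate re-consumption
q_m,eff = min(q_m, q_S)                             maintenance (glucose-borne)
µ_pot = (q_S − q_m,eff − q_Ap/Y_AS) · Y_XS_em + q_Ac · Y_XA
q_O,dem = max(Y_OX·µ_pot + c_Om·q_m,eff, 0) · DOT/(DOT+K_O)
```

If the respiratory demand exceeds the strain's capacity (`q_O,dem > q_O_max`)
the culture is respiration-limited: `q_O = q_O_max`,
`µ = (q_O_max − c_Om·q_m,eff)/Y_OX`, and the glucose flux that can no longer
be respired overflows to acetate, `q_Ap += Y_AS·(µ_pot − µ)/Y_XS_em`. A hard
growth-rate cap `µ ≤ mu_max` is applied the same way (surplus overflows to
acetate); for all eight library parameter sets the yield chain alone already
keeps `µ_pot` below `mu_max`, so the cap is inactive (see §5).

Balances:

```
dX/dt = µ·X          dS/dt = −q_S·X          dA/dt = (q_Ap − q_Ac)·X
dDOT/dt = kLa·(100 − DOT) − q_O·X·100/C_O2*
```

with `C_O2* = 7.2 mg/L` (air saturation at 37 °C), so DOT is carried in the
optode's % convention. Model off-gas rates: `OUR = q_O·X/M_O2·1000`
[mmol/(L·h)], `CPR = RQ·OUR` with a configurable respiratory quotient
(default 1.0, consistent with measured CPR/OUR peak ratios slightly above 1).

Assumptions and deliberate simplifications:

- **Maintenance is glucose-borne**: `q_m,eff = min(q_m, q_S)`. Maintenance
  and its oxygen demand vanish with glucose; during the pure acetate phase
  growth is `µ = q_Ac·Y_XA` with oxygen demand `Y_OX·µ`. This is the only
  reading consistent with requiring all rates to be zero when both
  substrates are gone *and* positive growth on acetate alone. Consequence:
  the acetate phase carries no information about `q_m`.
- **No death/decay term**: cultivations end at or shortly after depletion;
  starvation clamps `µ` at 0.
- **Growth is not throttled by low DOT directly**: the `DOT/(DOT+K_O)`
  factor scales the oxygen *uptake*, not growth. In an oxygen-limited well
  DOT settles into a quasi-steady value near zero at which transfer equals
  uptake; the realized OUR then respects the transfer ceiling
  `kLa·C_O2*/M_O2` automatically.
- Dry-gas off-gas balances (no humidity/pressure correction); molar gas
  volume 22.4 L/mol.

## 2. Auxiliary constants (never fitted)

| constant | default | meaning |
|---|---|---|
| Y_AS | 0.667 g/g | acetate per overflowed glucose (2 mol/mol ceiling) |
| Y_XA | 0.40 g/g | biomass yield on acetate |
| K_A | 0.05 g/L | acetate affinity |
| K_O | 1.0 % | DOT affinity of oxygen-dependent rates |
| c_Om | 1.067 g/g | O2 per g maintenance glucose (complete oxidation) |
| K_IS | 1e6 g/L | glucose inhibition of acetate uptake; the large default *enables* glucose/acetate co-consumption, as observed for WG and WGP |
| C_O2* | 7.2e-3 g/L | dissolved O2 at air saturation, 37 °C |
| OD→DCW | 0.37 g/L per OD600 | initial-biomass conversion |

All are configurable per run; a strain-specific `K_IS` can switch off
co-consumption (the double-knockout WGM shows it only weakly).

## 3. Simulation

`scipy.integrate.solve_ivp` with LSODA (the DOT balance makes the system
stiff: transfer time constants of seconds against batch dynamics of hours),
`rtol 1e-8 / atol 1e-10` for reference trajectories and `1e-6 / 1e-8` inside
optimization loops. Depletion-triggered glucose pulses are located by event
root-finding on the threshold crossing (default 0.05 g/L) and restore S to
the pulse target; logged pulse times can be replayed exactly ("timed" mode),
which is how fits treat pulses as known inputs. Aeration/kLa steps partition
the integration into segments with constant operating conditions. States are
clipped at 0 after each segment (integrator undershoot only). A work guard
(`max_rhs_evals`) aborts pathological integrations — parameter vectors that
optimization explores can otherwise make the stiff solver grind — and the
estimator converts such aborts into large finite penalty residuals.

## 4. Synthetic platforms

- **MTP** — 24-well plate, 1 mL, DOT only (1-min), kLa 133.3 1/h chosen so
  the oxygen-transfer ceiling is 30 mmol O2/(L·h); wells at ≥10 g/L glucose
  reproduce the extended DOT≈0 plateau with reaeration at depletion.
- **MBR** — 10 mL stirred mini-bioreactor, kLa 600 1/h, initial OD600 0.5
  (X0 = 0.185 g/L), 5 or 10 g/L glucose, depletion-triggered pulses (twice
  at 5, once at 10 g/L), 1-min DOT, atline X/S/A every 30 min, 12 h horizon.
- **STR** — 100 mL stirred tank, 20 g/L glucose, stepped aeration
  0.22 / 0.66 / 1.66 vvm at 0 / 2.75 / 6.8 h with kLa 300 / 500 / 900 1/h,
  1-min off-gas, hourly atline samples. Horizon 14 h: the slowest
  parameter set (WGP at 20 g/L, respiration-capped at µ ≈ 0.29 1/h) passes
  glucose depletion only after ~12 h, and the post-depletion acetate tail is
  what separates acetate production from consumption — a batch is monitored
  through the depletion DOT-jump, not cut off before it.

Noise model (sd = max(rel·|value|, abs), Gaussian, non-negative clipping):
X 5 % rel; S 3 % rel, floor 0.05 g/L; A 5 % rel, floor 0.02 g/L; DOT 2
points abs; outlet gas mole fractions 2e-4 abs (analyzer class). Outlet
fractions are *fabricated* by analytically inverting the inert-gas balance at
the model's OUR/CPR — the inversion is closed-form and round-trips to
machine precision — then perturbed; measured OUR/CPR are recomputed from the
noisy fractions, so gas-channel noise propagates the way it does through a
real analyzer. An optional lag phase (biology frozen for `lag_h`; default 0,
1 h for WGM presets in the pipeline) emulates the double knockout's slow
start.

What the generator does **not** emulate: sampling volume loss, evaporation,
pH excursions, humidity/pressure effects on the analyzers, day-to-day
instrument drift, and any real biological deviation from the rate laws
above. Passing recovery tests therefore demonstrates the estimation
machinery is unbiased and well-calibrated *under the model*, not that the
model is true.

## 5. Estimation and identifiability

Weighted least squares: residuals (model − data)/sd concatenated over
channels and datasets; DOT readings below 5 % saturation are excluded
(optode floor). Free parameters are optimized in log-space within box bounds
(`DEFAULT_BOUNDS`), multi-start from Latin-hypercube samples,
trust-region-reflective steps, at most 100 iterations per start. Mixed
sampling rates make the joint objective multimodal (the 1-min channels
dominate), so a pilot fit on the sparse atline channels alone seeds the full
fit. Uncertainties are the delta-method square roots of the linearized
covariance `σ²(JᵀJ)⁻¹` at the optimum. Everything is deterministic given the
seed.

The default free set encodes structural identifiability facts, all of which
follow from the rate algebra:

- `mu_max` never enters the observable dynamics while the growth cap is
  inactive — and the yield chain keeps it inactive for every library
  parameter set — so it is never free by default and cannot be recovered
  from data this model generates.
- `q_m` trades off flatly against `Y_XS_em` and `Y_OX` in a batch at
  S ≫ K_S (growth rate is constant, so only two composites of the three
  parameters are observable); it stays fixed at its reference value.
- `q_O_max` is estimable only where the respiratory cap binds — the
  20 g/L stirred tanks (and marginally WGP at 10 g/L) — and is free only
  for STR fits.
- When that cap binds, the *total* acetate overflow is set by the cap and is
  exactly independent of `q_Ap_max` (the routing parameter cancels), so
  `q_Ap_max` is free only for MBR/low-glucose fits.
- `K_S` is free for 5/10 g/L data, fixed for 20 g/L-only data; even when
  free it is pinned only to order of magnitude, because glucose traverses
  the affinity regime in minutes (profile over [0.005, 0.02] g/L is flat on
  atline data, while the `q_S_max` profile is sharp).

Under these defaults, synthetic recovery at the platforms' own noise returns
the free parameters within ~1–2 % (well under 5 %) with truth inside ±3
reported uncertainties; this is exercised for one MBR column (WG, 10 g/L)
and one STR column (WGP, 20 g/L) — one representative of each platform
class — to keep the default test run at minutes, not hours.

## 6. Soft sensor

Cumulative oxygen uptake `cOUR(t) = ∫ OUR dt` (trapezoid on the 1-min grid,
converted to g O2/L) relates to biomass by the Luedeking–Piret form
`cOUR = α(X − X0) + β∫X dt`; ignoring maintenance, `X_m = cOUR/α + X0`.
Two practical points, both visible in the package's own simulations:

- Because cumulative OUR *includes* maintenance respiration, the best
  single-coefficient α is the *effective* yield
  `≈ Y_OX·(1 + c_Om·q_m/(Y_OX·µ))`, some 10–13 % above the mechanistic
  `Y_OX`. The pipeline's "update" therefore re-estimates α from the
  stirred-tank run itself by least squares with the maintenance regressor
  dropped; plugging the mechanistic stirred-tank `Y_OX` into the estimator
  can *worsen* the RMSE.
- Under pure exponential growth `∫X dt ∝ (X − X0)`, so α and β are not
  jointly identifiable; `fit_alpha_beta` rejects such designs (rank guard).
  Deceleration (pulse phases, depletion) breaks the collinearity.

## 7. Pipeline

`run_full` executes campaign → per-run fits → parameter report
(rows = parameters, columns = strain(condition), `value ± sd`) → soft sensor
on the stirred-tank runs with the small-scale-derived α and the updated α,
reporting both RMSEs. All randomness flows from one config seed; a rerun
reproduces every number bitwise. The demo configuration (single strain,
reduced free set, one start) finishes in a few minutes on one core; the full
eight-column campaign is a matter of ~10 fits at one to a few minutes each.

## 8. Known limitations

- The growth cap and maintenance parameters are carried for completeness but
  are not learnable from the supported experiment types (see §5); chemostat
  or starvation experiments would be needed.
- DOT does not throttle growth, so fully anoxic wells still grow at the
  yield-chain rate; the model is not meant for sustained anaerobiosis.
- The acetate overflow under respiratory limitation uses a single routing
  stoichiometry (Y_AS); mixed-acid byproducts (lactate, ethanol, succinate)
  are not represented.
- RQ is constant per run; real CPR/OUR ratios drift with the acetate phase.
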