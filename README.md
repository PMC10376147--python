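# strainchar

Model-based characterization of *Escherichia coli* strains with impaired
glucose uptake, across cultivation scales.

Engineered *E. coli* hosts with knockouts in the phosphotransferase system
(W3110 ΔptsG and its ΔmanX / ΔgalP derivatives) take up glucose slowly enough
to suppress acetate overflow, which makes them attractive for simple
high-glucose batch processes. Characterizing such strains efficiently means
running them at several scales — microtiter plates with only dissolved-oxygen
optodes, 10 mL mini-bioreactors with atline analytics and glucose pulses,
100 mL stirred tanks with 1-min off-gas analysis — and pulling one consistent
parameter set out of all of it. `strainchar` packages that workflow for
people who build or study such pipelines: a macro-kinetic growth model,
off-gas mass balances with a biomass soft sensor, a synthetic multi-platform
data generator, and multi-experiment parameter estimation.

## The model in brief

Biomass X, glucose S, acetate A and dissolved oxygen tension (DOT, % air
saturation) evolve as

    dX/dt = µX,  dS/dt = −q_S X,  dA/dt = (q_Ap − q_Ac) X,
    dDOT/dt = kLa (100 − DOT) − q_O X · 100/C_O2*

with Monod glucose uptake q_S = q_Smax·S/(S+K_S), overflow acetate
production q_Ap driven by glucose saturation, acetate re-consumption q_Ac
(active even while glucose is present — the co-consumption these knockouts
show), growth from the glucose partition
µ = (q_S − q_m − q_Ap/Y_AS)·Y_XSem + q_Ac·Y_XA, and respiration
q_O = Y_OX·µ + c_Om·q_m capped at q_Omax — glucose flux that cannot be
respired overflows to extra acetate. Oxygen uptake and carbon dioxide
production rates follow from the inert-gas balance over the reactor
(V_mol = 22.4 L/mol), and cumulative OUR divided by the oxygen-on-biomass
yield α gives the soft-sensor biomass estimate X_m = cOUR/α + X0
(Luedeking–Piret form). Nine strain parameters (µ_max, K_S, q_Smax, q_Apmax,
q_Acmax, q_Omax, q_m, Y_XSem, Y_OX) are estimated by weighted multi-start
least squares; published estimates for eight strain×condition columns ship
as `STRAIN_LIBRARY`. See `docs/methods.md` for assumptions, identifiability
analysis and numerical choices.

## Worked example

```python
from strainchar import STRAIN_LIBRARY, preset, simulate

traj = simulate(STRAIN_LIBRARY["WG(10)"], None, preset("MBR", S0=10))
```

`examples/simulate_batch.py` prints, for this 10 mL mini-bioreactor batch of
WG at 10 g/L glucose:

```
pulse fired at          : 6.16 h
final glucose depletion : 7.43 h
final biomass           : 10.02 g/L
acetate peak            : 0.90 g/L
minimum DOT             : 1.2 % air saturation
```

Glucose runs out after ~6.2 h, the controller re-feeds to 10 g/L once (the
5 g/L protocol pulses twice), and two batches' worth of glucose end up as
~10 g/L biomass — the ~0.5 g/g net yield. The DOT minimum flags the
transient oxygen limitation after the pulse, when respiratory demand outruns
the 600 1/h mass transfer.

`examples/offgas_soft_sensor.py` runs the cross-platform soft-sensor
workflow on a synthetic 100 mL stirred-tank run of WG at 20 g/L:

```
peak OUR                 : 137 mmol O2/(L·h)
alpha initial (transfer) : 1.49 g/g
alpha updated (this run) : 1.35 g/g
biomass RMSE initial     : 0.52 g/L
biomass RMSE updated     : 0.12 g/L
```

The first estimate uses the oxygen yield transferred from the small-scale
characterization; re-estimating the effective yield on the tank's own
cumulative-OUR signal absorbs the maintenance share of respiration and
tightens the estimate. `examples/fit_strain.py` and
`examples/synthetic_campaign.py` show parameter recovery and a
multi-platform screening campaign; the `strainchar` command-line tool wraps
the same stages (`simulate`, `generate`, `fit`, `sensor`, `full`).

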