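# colefit

Cole-model bioimpedance spectroscopy analysis for organ-viability
monitoring: forward impedance models, genetic-algorithm fitting,
accuracy/repeatability statistics, ischemia time-series analysis, and a
synthetic measurement bench.

## Who this is for

Multifrequency bioimpedance spectroscopy measures a tissue's complex
electrical impedance Z(f) across a frequency band (here 22 log-spaced
points from 5 kHz to 1 MHz) and summarizes it with equivalent-circuit
parameters that track physiology: extracellular resistance rises as
cells swell, membrane capacitance tracks membrane area and integrity.
This package is for researchers building or analyzing such
measurements — in particular for monitoring kidney grafts during cold
ischemia, where the parameter dynamics (and the end of the
extracellular-resistance rise, a proposed "point of no return") carry
viability information.

## Models

All models derive from the single-dispersion Cole backbone

    ZC(f) = R∞ + (R0 − R∞) / (1 + (j·2πf·(RE + RI)·Cm)^α)

with RE = R0, RI = R∞R0/(R0 − R∞), and a hardware phase delay
Z = ZC·e^(−j2πf·TD):

| model | extra ingredient | use case |
|-------|-----------------|----------|
| Z0    | — | classic Cole fit |
| Z1    | parasitic shunt capacitance CP across the tissue | cables/probes with stray coupling |
| Z2    | frequency-dependent membrane capacitance Cm(f) = Cm,LF + A·f | better fits and more repeatable parameters on renal tissue |

Parameters are estimated by a seeded genetic algorithm (population
5000, 12 generations, 20% elitism, mutation probability ramped from
0.07% to 21%) minimizing the mean squared complex-plane error; see
`docs/methods.md` for the full algorithm and its measured accuracy.

## Worked example

Fit a noisy synthetic kidney spectrum and inspect the estimate:

```python
import colefit as cf

truth = cf.ColeParams(r0=100.0, rinf=50.0, cm=100e-9, alpha=0.85)
sp = cf.generate_spectrum(truth, noise_cv=0.01, seed=7)   # 1% noise

fit = cf.GAColeFitter(model="Z0", seed=1).fit(sp.frequencies, sp.z)
p = fit.params_
print(f"R0    = {p.r0:8.2f} ohm   (truth 100.00)")
print(f"Rinf  = {p.rinf:8.2f} ohm   (truth  50.00)")
print(f"Cm    = {p.cm*1e9:8.2f} nF    (truth 100.00)")
print(f"alpha = {p.alpha:8.3f}       (truth   0.850)")
print(f"MSE   = {fit.mse_:.4g} ohm^2")
```

prints

```
R0    =   101.61 ohm   (truth 100.00)
Rinf  =    49.64 ohm   (truth  50.00)
Cm    =   104.93 nF    (truth 100.00)
alpha =    0.837       (truth   0.850)
MSE   = 0.2025 ohm^2
```

— with 1% measurement noise the GA recovers R0 and R∞ to ~1–2% and the
reconstruction tracks the noiseless truth to well under 1% at every
frequency. `fit_all_models(sp)` fits Z0, Z1 and Z2 to the same
spectrum and flags the best by MSE; `reverse_repeatability` and
`compare_model_errors` implement the repeatability and paired-accuracy
statistics; `simulate_ischemia_series` + `fit_series` +
`summarize_evolution` run the full ischemia-monitoring pipeline on
synthetic data.

A command-line interface wraps the same functionality:

```bash
colefit simulate --kind ischemia --out series/ --noise-cv 0.01 --seed 5
colefit evolution --manifest series/series.json --model Z0 --seed 2
colefit validate-circuit        # reference-circuit accuracy check
```

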