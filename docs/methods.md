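# Methods

## Scope and models

`colefit` implements the computational core of multifrequency
bioimpedance spectroscopy for organ-viability monitoring: forward
Cole-family impedance models, genetic-algorithm (GA) parameter
estimation, accuracy and repeatability statistics, analysis of
parameter dynamics during cold ischemia, and a synthetic measurement
bench that emulates kidney-like measurements so the whole pipeline can
be exercised without hardware or tissue.

Three forward models are provided. All share the single-dispersion Cole
backbone

    ZC(f) = R∞ + (R0 − R∞) / (1 + (j·2πf·(RE + RI)·Cm)^α),

with `RE = R0` (extracellular resistance), `RI = R∞·R0/(R0 − R∞)`
(intracellular resistance, recomputed from (R0, R∞) on every evaluation
so a parameter object can never hold inconsistent values), `Cm` the
membrane capacitance and `α ∈ (0, 1]` the dispersion exponent. The
measured impedance additionally carries a hardware phase delay,
`Z = ZC·e^(−j2πf·TD)`.

* **Z0** — the backbone plus the TD rotation.
* **Z1** — Z0 with a parasitic shunt capacitance CP across the tissue
  (probes, cables, ground coupling). The parallel combination is
  evaluated as `ZC/(1 + jωCP·ZC)`, which is the analytic limit both at
  CP = 0 (no shunt) and f = 0 (shunt open), so neither case divides by
  zero.
* **Z2** — the backbone with a membrane capacitance that grows linearly
  with frequency, `Cm(f) = Cm,LF + A·f`. `A` may be negative but the
  effective capacitance must stay positive over the working band; the
  forward model rejects inputs that violate this.

Numerical conventions: frequencies are stored in Hz and ω = 2πf is
formed at evaluation time; the fractional power uses the principal
branch, `(jωτ)^α = (ωτ)^α·e^(jαπ/2)`, which keeps Re Z ∈ [R∞, R0] and
Im Z ≤ 0 (a depressed capacitive arc) for every α ∈ (0, 1]; capacitive
reactance is negative-imaginary. At f = 0 every model returns exactly
R0.

The default measurement grid is 22 logarithmically spaced frequencies
from 5 kHz to 1 MHz inclusive, the band in which the β-dispersion of
soft tissue is observable and hardware remains simple.

## Genetic-algorithm fitting

The objective is the mean squared error between measured and modelled
complex impedance, `MSE = (1/N)·Σ|Z_meas(fᵢ) − Z_model(fᵢ)|²` — a
complex-plane Euclidean metric, not separate modulus/phase terms.

Search space. R0 is encoded as `R∞ + ΔR` with ΔR > 0, so R0 > R∞ holds
for every candidate by construction. Capacitances (Cm, Cm,LF, CP) are
searched log10-uniformly; resistances, α and TD linearly. The
capacitance slope A is linear because it is signed. Default bounds are
kidney-scale and fully configurable: R∞ ∈ [1, 500] Ω, ΔR ∈ [1, 1000] Ω,
Cm, Cm,LF ∈ [0.1, 1000] nF, α ∈ [0.3, 1], TD ∈ [0, 2] µs,
CP ∈ [1e−13, 1e−8] F (the lower end is an effectively absent shunt,
|ZP| ≈ 1.6 MΩ at 1 MHz), A ∈ [−9e−17, 1e−13] F/Hz. The A lower bound is
tied to the smallest admissible Cm,LF and the top of the band so
`Cm,LF + A·f > 0` holds for every candidate the search can produce.

Algorithm. A population of 5000 parameter vectors is evolved for 12
generations. Each generation the population is ranked by MSE (ties keep
insertion order under the seeded generator):

1. the best 20% survive unchanged (elitism over whole parameter
   vectors, so the best objective value is non-increasing);
2. a proposal band is built from the elites: each child is an anchor
   drawn from the top 10 ranked vectors plus `F·(e₁ − e₂)`, where e₁,
   e₂ are random elites and the step scale F is log-uniform with a
   heavy tail (log10 F ∈ [−0.7, 0.5] early, annealed to [−1, 0]),
   clipped to the bounds. Difference vectors align proposals with the
   elite cloud's covariance, which matters because R0, Cm and α trade
   off along a curved valley (R0 is extrapolated below the 5 kHz grid
   edge); steps with F > 1 let the population walk along that valley
   even after it has contracted. On top of this, each gene is redrawn
   uniformly within its bound with a probability ramped linearly from
   0.07% in the first update to 21% in the last — cheap global
   exploration late in the run;
3. the remainder of the population is re-randomized uniformly within
   bounds; this restart fraction tapers from 50% to 10% across
   generations so late generations spend their budget on refinement.

There is no crossover operator and no gradient-based or local
refinement step: the GA output is the estimate. Measured behaviour at
the default budget (49 000 objective evaluations): median maximum
reconstruction error ~0.02% and no seed above 1% in 100 trials on
noiseless single-arc targets; median parameter errors on random
noiseless Cole spectra ~0.02% (R0, R∞) to ~0.1% (Cm). The stochastic
floor of the objective is around 1e−5–1e−4 Ω²; fits whose true optimum
is sharper than that (e.g. exactly noiseless data) will stop there.

Determinism: all randomness flows from `numpy.random.default_rng(seed)`
with the seed carried in `GAConfig`; identical (spectrum, config) gives
a bit-identical `FitResult`.

The fitter is exposed as a scikit-learn estimator (`GAColeFitter`) with
`fit(f, z)` / `predict(f)`, `get_params`/`set_params`, and fitted
attributes `params_`, `mse_`, `residuals_`, `residual_sd_`, `trace_`;
`fit_model` and `fit_all_models` are functional wrappers.

## Statistics

* **Relative error**: `100·|Z_meas − Z_ref|/|Z_ref|` per frequency,
  with max and mean aggregates. Invariant under joint phase rotation.
* **Residual summaries**: population (÷N) standard deviation, mean and
  max of residual magnitudes, in ohms. The ÷N convention is used for
  every SD in the package; since reverse repeatability is a ratio of
  SDs the choice cancels there.
* **Reverse repeatability**: per parameter,
  `100·SD(short-term consecutive estimates)/SD(long-term evolution
  study)`. Small values mean short-term scatter is negligible against
  the physiological excursion, i.e. the device can resolve the temporal
  evolution. A zero long-term SD is flagged undefined rather than
  reported as infinity. Protocol minima: ≥3 short-term records (taken
  within a ≤5-minute window, probe re-placed in between) and ≥15
  long-term records for the protocol flag (≥2 to compute at all).
  Default parameter subsets: {R0, R∞, Cm, α} for Z0 reports and
  {R0, Cm} — the parameters most stable in their dynamics — for Z2
  reports. Multi-organ results are reported per organ and averaged,
  never collapsed silently.
* **Paired model comparison**: mean error reduction
  `100·(mean(a) − mean(b))/mean(a)` with a two-sided paired t-test
  (scipy). Zero-variance differences yield a flagged undefined p-value.

## Ischemia dynamics

During cold ischemia, cellular edema compresses the extracellular
space (R0 rises) and enlarges membrane area (Cm rises); as membranes
rupture both decay toward a stationary value, while α (cell-size
heterogeneity) and R∞ (fluid uptake from the preservation bath) decay
monotonically. The end of the R0 increase phase is used as an
operational proxy for the point of no return of organ viability. It is
detected as the maximum of the trajectory after a centered moving
average (odd window, default 3; edges use the symmetric sub-window that
fits), ties resolved to the earliest time; a maximum on the series
boundary sets a monotone flag instead of claiming an interior peak.
This estimator is a pragmatic stand-in — no validated clinical
threshold is implied.

`summarize_evolution` classifies each parameter's net direction as
rise-fall, monotone-up, monotone-down or flat. A rise-fall label
requires the smoothed peak to stand above both endpoints by more than
20% of the trajectory's range; below that prominence the series is
treated as monotone. The threshold exists so that estimation noise on a
monotone trajectory (GA scatter on α is of order 1–2%) does not
manufacture a spurious peak; it is configurable.

## Synthetic bench

* **Reference circuit**: a Fricke-type 2R-1C core (extracellular branch
  in parallel with intracellular resistance + membrane capacitor;
  defaults 100 Ω, 100 Ω, 100 nF) with an electrode model of 50 Ω in
  series with 100 nF on each lead. The four-terminal mode returns the
  core alone (the voltage sense path carries no current); the
  two-terminal mode adds both electrode models. The core is *exactly* a
  single Cole arc with α = 1 — with the defaults, R0 = 100 Ω,
  R∞ = 50 Ω, Cm = 100 nF — which makes it the bench's self-consistency
  anchor: the algebraic identity is asserted to 1e−12, and a GA fit of
  the circuit must reconstruct it to below 1% everywhere.
* **Noise**: independent proportional complex Gaussian perturbations,
  RMS magnitude `noise_cv·|Z|` per frequency (σ = noise_cv·|Z|/√2 on
  each quadrature). Default study noise is 1%.
* **Placement jitter**: mean-one lognormal factors applied to R∞ and ΔR
  (and to the capacitance for the localized scheme). Defaults encode
  the observed ordering as a generative assumption: localized probes
  (small fixed-geometry head re-placed on one region) get 10%
  resistance / 5% capacitance CVs; longitudinal (pole-to-pole,
  whole-organ) measurements get 2% / 0%. These magnitudes are invented
  knobs of plausible size, not measured values.
* **Trajectories**: per parameter, either a saturating-exponential rise
  from baseline to `baseline·(1 + peak_fraction)` exactly at the
  configured peak time followed by exponential decay to
  `stationary_fraction·baseline` (R0, Cm: +30% peak at 2 h, decay
  τ = 10 h, stationary 0.8×), or a plain exponential decay (R∞: 50 Ω →
  0.7×, τ = 30 h; α: 0.85 → 0.85×, τ = 30 h). The piecewise form pins
  the trajectory argmax to the configured peak time by construction.
  The default study samples 17 time points over 70 h, denser in the
  first hours. Absolute magnitudes are order-of-magnitude kidney-scale
  choices; curve shapes, the 2 h capacitance peak, the ≥15-point /
  70 h protocol and the 3-replicate short-term sessions follow the
  study design the bench emulates.

## What the bench does and does not show

Passing the synthetic pipeline demonstrates that the estimation and
statistics machinery is correct and self-consistent under the stated
generative assumptions: single-dispersion tissue, proportional Gaussian
noise, lognormal placement jitter, smooth two-phase trajectories. Real
kidney measurements add effects deliberately out of scope —
electrode polarization (removed by tetrapolar hardware), cable and
demodulation artefacts, temperature dependence of the dynamics,
multi-dispersion tissue behaviour — so synthetic results support the
software, not clinical claims. Reported tissue-study figures (e.g. the
percentage error reduction of Z2 over Z0, or specific reverse
repeatability percentages) depend on the animals measured and are
reproduced here only as directions of effect.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
the study's native scale: 22-frequency spectra, the default GA budget
(5000 × 12), 20-draw recovery and comparison studies, three synthetic
kidneys for the repeatability experiment, and 20 replicate 17-point
ischemia studies. The full suite completes in about a minute on one
core.
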