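"""Genetic-algorithm estimation of Cole-model parameters.

The fitter minimizes the mean squared error between a measured complex
spectrum and the forward model,

    MSE = (1/N) · Σᵢ |Z_meas(fᵢ) − Z_model(fᵢ)|²,

with a rank-based genetic algorithm: a population of 5000 parameter
vectors evolved for 12 generations. Each generation the population is
ranked by MSE; the best 20% survive unchanged (elitism), a middle band
is regenerated from elite-anchored difference-vector proposals with the
per-gene uniform-redraw mutation probability ramped linearly from 0.07%
to 21% across generations, and the remainder is re-randomized uniformly
within the search bounds. Capacitances are searched on a log10 scale;
R0 is encoded as R∞ + ΔR with ΔR > 0 so R0 > R∞ holds by construction.

`GAColeFitter` is a scikit-learn style estimator (``fit(f, z)``,
``predict(f)``, fitted attributes with trailing underscores) so it
composes with sklearn tooling; `fit_model` / `fit_all_models` are thin
functional wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping

import numpy as np
from sklearn.base import BaseEstimator

from .models import (
    ColeParams,
    ImpedanceSpectrum,
    ModelParams,
    Z1Params,
    Z2Params,
    impedance,
)

__all__ = [
    "GAConfig",
    "FitResult",
    "GAColeFitter",
    "ModelComparison",
    "objective_mse",
    "fit_model",
    "fit_all_models",
    "MODEL_KINDS",
    "default_bounds",
]

MODEL_KINDS = ("Z0", "Z1", "Z2")

#: Minimum number of frequencies accepted by the fitter.
MIN_FREQUENCIES = 5

# Heavy-tailed schedule for the difference-vector step scale F:
# log10(F) drawn uniformly in [lo, hi], annealed across generations.
_LOG10_F_START = (-0.7, 0.5)
_LOG10_F_END = (-1.0, 0.0)
#: Anchors for band proposals are drawn from this many top-ranked elites.
_ANCHOR_POOL = 10
#: Fraction of the population re-randomized, tapered across generations.
_RESTART_FRACTION_END = 0.1


def default_bounds() -> Dict[str, tuple]:
    """Kidney-scale default search bounds (all overridable).

    ``r0`` is parameterized as ``rinf + delta_r``. ``a`` may be negative;
    its lower bound is tied to the smallest admissible Cm,LF and the top
    of the band so the effective capacitance stays positive for every
    candidate (0.9 · 1e−10 F / 1e6 Hz = 9e−17 F/Hz).
    """
    return {
        "rinf": (1.0, 500.0),
        "delta_r": (1.0, 1000.0),
        "cm": (1e-10, 1e-6),
        "cm_lf": (1e-10, 1e-6),
        "alpha": (0.3, 1.0),
        "td": (0.0, 2e-6),
        "cp": (1e-13, 1e-8),
        "a": (-9e-17, 1e-13),
    }


# Gene layout per model kind; names refer to bounds keys.
_GENES = {
    "Z0": ("rinf", "delta_r", "cm", "alpha", "td"),
    "Z1": ("rinf", "delta_r", "cm", "alpha", "td", "cp"),
    "Z2": ("rinf", "delta_r", "cm_lf", "a", "alpha", "td"),
}
_LOG_GENES = frozenset({"cm", "cm_lf", "cp"})


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Defaults: population 5000, 12
    generations, 20% elitism, a 30% mutation band with the per-gene
    mutation probability ramped linearly from 0.0007 to 0.21, the rest
    re-randomized. `bounds` maps parameter names to (low, high) closed
    intervals; omitted parameters use `default_bounds()`.
    """

    population_size: int = 5000
    generations: int = 12
    elite_fraction: float = 0.20
    mutate_fraction: float = 0.30
    mutation_prob_start: float = 0.0007
    mutation_prob_end: float = 0.21
    bounds: Dict[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population_size must be at least 10")
        if self.generations < 2:
            raise ValueError("generations must be at least 2")
        if not (0.0 < self.elite_fraction < 1.0):
            raise ValueError("elite_fraction must lie in (0, 1)")
        if not (0.0 <= self.mutate_fraction <= 1.0):
            raise ValueError("mutate_fraction must lie in [0, 1]")
        if self.elite_fraction + self.mutate_fraction > 1.0:
            raise ValueError("elite_fraction + mutate_fraction must not exceed 1")
        for p in (self.mutation_prob_start, self.mutation_prob_end):
            if not (0.0 <= p <= 1.0):
                raise ValueError("mutation probabilities must lie in [0, 1]")
        merged = default_bounds()
        for name, pair in dict(self.bounds).items():
            if name not in merged:
                raise ValueError(f"unknown bound parameter {name!r}")
            lo, hi = float(pair[0]), float(pair[1])
            if not lo < hi:
                raise ValueError(f"bound for {name!r} must have lower < upper")
            merged[name] = (lo, hi)
        self.bounds = merged

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GAConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["bounds"] = {k: tuple(v) for k, v in raw.get("bounds", {}).items()}
        return cls(**raw)


@dataclass
class FitResult:
    """Outcome of one GA fit.

    `residuals` are the per-frequency complex differences
    ``Z_meas − Z_model`` (ohm); `residual_sd` is the population standard
    deviation of their magnitudes; `best_objective_trace` records the
    best MSE after each generation (non-increasing under elitism).
    """

    model_kind: str
    params: ModelParams
    mse: float
    residuals: np.ndarray
    residual_sd: float
    best_objective_trace: np.ndarray

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "params": self.params.as_dict(),
            "mse_ohm2": self.mse,
            "residual_sd_ohm": self.residual_sd,
            "best_objective_trace": list(map(float, self.best_objective_trace)),
        }


def _as_f_z(spectrum_or_f, z=None):
    if isinstance(spectrum_or_f, ImpedanceSpectrum):
        return spectrum_or_f.frequencies, spectrum_or_f.z
    f = np.asarray(spectrum_or_f, dtype=float).ravel()
    return f, np.asarray(z, dtype=complex).ravel()


def objective_mse(spectrum: ImpedanceSpectrum, params: ModelParams) -> float:
    """Mean squared complex-plane error between a spectrum and a model."""
    f, z = _as_f_z(spectrum)
    if f.size == 0:
        raise ValueError("cannot evaluate the objective on an empty spectrum")
    zm = impedance(params, f)
    return float(np.mean(np.abs(z - zm) ** 2))


def _encode_bounds(kind: str, bounds: Mapping[str, tuple]):
    names = _GENES[kind]
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, name in enumerate(names):
        b0, b1 = bounds[name]
        if name in _LOG_GENES:
            if b0 <= 0.0:
                raise ValueError(f"log-scale bound for {name!r} must be positive")
            lo[i], hi[i] = np.log10(b0), np.log10(b1)
        else:
            lo[i], hi[i] = b0, b1
    return names, lo, hi


def _decode(kind: str, names, pop: np.ndarray) -> dict:
    cols = {}
    for i, name in enumerate(names):
        v = pop[:, i]
        cols[name] = 10.0 ** v if name in _LOG_GENES else v
    return cols


def _eval_population(kind: str, cols: dict, f: np.ndarray, z: np.ndarray):
    """Vectorized forward model + MSE for a whole population."""
    rinf = cols["rinf"][:, None]
    r0 = rinf + cols["delta_r"][:, None]
    alpha = cols["alpha"][:, None]
    td = cols["td"][:, None]
    fr = f[None, :]
    if kind == "Z2":
        cm_eff = cols["cm_lf"][:, None] + cols["a"][:, None] * fr
        # the bound construction keeps cm_eff positive; clip guards against
        # user-supplied bounds that allow a transiently non-positive value
        cm_eff = np.maximum(cm_eff, 1e-300)
    else:
        cm_eff = cols["cm"][:, None]
    re_plus_ri = r0 * r0 / (r0 - rinf)
    wt = 2.0 * np.pi * fr * re_plus_ri * cm_eff
    zc = rinf + (r0 - rinf) / (1.0 + np.power(wt, alpha) * np.exp(1j * alpha * np.pi / 2))
    if kind == "Z1":
        zc = zc / (1.0 + 2j * np.pi * fr * cols["cp"][:, None] * zc)
    zm = zc * np.exp(-2j * np.pi * fr * td)
    return np.mean(np.abs(zm - z[None, :]) ** 2, axis=1)


def _params_from_row(kind: str, names, row: np.ndarray) -> ModelParams:
    vals = {
        name: float(10.0 ** row[i] if name in _LOG_GENES else row[i])
        for i, name in enumerate(names)
    }
    rinf = vals["rinf"]
    r0 = rinf + vals["delta_r"]
    if kind == "Z0":
        return ColeParams(r0=r0, rinf=rinf, cm=vals["cm"], alpha=vals["alpha"], td=vals["td"])
    if kind == "Z1":
        cole = ColeParams(r0=r0, rinf=rinf, cm=vals["cm"], alpha=vals["alpha"], td=vals["td"])
        return Z1Params(cole=cole, cp=vals["cp"])
    return Z2Params(
        r0=r0, rinf=rinf, cm_lf=vals["cm_lf"], a=vals["a"],
        alpha=vals["alpha"], td=vals["td"],
    )


def _run_ga(kind: str, f: np.ndarray, z: np.ndarray, config: GAConfig, seed: int):
    rng = np.random.default_rng(seed)
    names, lo, hi = _encode_bounds(kind, config.bounds)
    ng = len(names)
    n = config.population_size
    gens = config.generations
    n_elite = max(1, int(round(config.elite_fraction * n)))
    restart0 = max(0.0, 1.0 - config.elite_fraction - config.mutate_fraction)

    pop = rng.uniform(lo, hi, size=(n, ng))
    mse = _eval_population(kind, _decode(kind, names, pop), f, z)
    trace = np.empty(gens)

    for g in range(gens):
        order = np.argsort(mse, kind="stable")  # ties keep insertion order
        pop = pop[order]
        mse = mse[order]
        trace[g] = mse[0]
        if g == gens - 1:
            break
        t = g / (gens - 2) if gens > 2 else 1.0
        p_mut = config.mutation_prob_start + (
            config.mutation_prob_end - config.mutation_prob_start
        ) * t
        n_restart = int(round((restart0 + (_RESTART_FRACTION_END - restart0) * t) * n))
        n_restart = min(n_restart, n - n_elite)
        n_band = n - n_elite - n_restart

        elite = pop[:n_elite]
        children = []
        if n_band > 0:
            anchor_pool = min(_ANCHOR_POOL, n_elite)
            anchors = elite[rng.integers(0, anchor_pool, n_band)]
            diffs = (
                elite[rng.integers(0, n_elite, n_band)]
                - elite[rng.integers(0, n_elite, n_band)]
            )
            log_lo = _LOG10_F_START[0] + (_LOG10_F_END[0] - _LOG10_F_START[0]) * t
            log_hi = _LOG10_F_START[1] + (_LOG10_F_END[1] - _LOG10_F_START[1]) * t
            step = 10.0 ** rng.uniform(log_lo, log_hi, (n_band, 1))
            band = np.clip(anchors + step * diffs, lo, hi)
            mutate = rng.random((n_band, ng)) < p_mut
            redraw = rng.uniform(lo, hi, size=(n_band, ng))
            band[mutate] = redraw[mutate]
            children.append(band)
        if n_restart > 0:
            children.append(rng.uniform(lo, hi, size=(n_restart, ng)))
        new = np.concatenate([elite] + children)
        new_mse = _eval_population(kind, _decode(kind, names, new[n_elite:]), f, z)
        pop = new
        mse = np.concatenate([mse[:n_elite], new_mse])

    return pop[0], float(mse[0]), trace, names


class GAColeFitter(BaseEstimator):
    """Scikit-learn style genetic-algorithm Cole-model fitter.

    Parameters
    ----------
    model : {'Z0', 'Z1', 'Z2'}
        Which forward model to fit.
    population_size, generations, elite_fraction, mutate_fraction,
    mutation_prob_start, mutation_prob_end, bounds, seed
        See `GAConfig`.

    Attributes (after `fit`)
    ------------------------
    params_ : ModelParams
        Best-fit parameter object.
    mse_ : float
        Mean squared complex residual, ohm².
    residuals_ : ndarray of complex
        Per-frequency ``Z_meas − Z_model``.
    residual_sd_ : float
        Population SD of residual magnitudes, ohm.
    trace_ : ndarray
        Best objective per generation (non-increasing).
    result_ : FitResult
        All of the above bundled.

    Examples
    --------
    >>> from colefit import ColeParams, FrequencyGrid, spectrum
    >>> truth = ColeParams(r0=100, rinf=50, cm=1e-7, alpha=0.85)
    >>> sp = spectrum(truth)
    >>> fit = GAColeFitter(model="Z0", seed=1).fit(sp.frequencies, sp.z)
    >>> abs(fit.params_.r0 - 100) / 100 < 0.01
    True
    """

    def __init__(
        self,
        model: str = "Z0",
        population_size: int = 5000,
        generations: int = 12,
        elite_fraction: float = 0.20,
        mutate_fraction: float = 0.30,
        mutation_prob_start: float = 0.0007,
        mutation_prob_end: float = 0.21,
        bounds: Dict[str, tuple] | None = None,
        seed: int = 0,
    ) -> None:
        self.model = model
        self.population_size = population_size
        self.generations = generations
        self.elite_fraction = elite_fraction
        self.mutate_fraction = mutate_fraction
        self.mutation_prob_start = mutation_prob_start
        self.mutation_prob_end = mutation_prob_end
        self.bounds = bounds
        self.seed = seed

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            elite_fraction=self.elite_fraction,
            mutate_fraction=self.mutate_fraction,
            mutation_prob_start=self.mutation_prob_start,
            mutation_prob_end=self.mutation_prob_end,
            bounds=dict(self.bounds or {}),
            seed=self.seed,
        )

    def fit(self, X, y=None) -> "GAColeFitter":
        """Fit the model to a spectrum.

        X may be an `ImpedanceSpectrum`, or an array of frequencies in Hz
        with `y` the complex impedance in ohm.
        """
        if self.model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}, got {self.model!r}")
        f, z = _as_f_z(X, y)
        if f.size != z.size:
            raise ValueError("frequencies and impedance must have equal length")
        if f.size < MIN_FREQUENCIES:
            raise ValueError(
                f"fit requires at least {MIN_FREQUENCIES} frequencies, got {f.size}"
            )
        if np.any(f <= 0.0) or not np.all(np.isfinite(f)):
            raise ValueError("frequencies must be positive and finite")
        if not np.all(np.isfinite(z)):
            raise ValueError("impedance spectrum contains non-finite values")
        config = self._config()
        best, mse, trace, names = _run_ga(self.model, f, z, config, config.seed)
        params = _params_from_row(self.model, names, best)
        residuals = z - impedance(params, f)
        mags = np.abs(residuals)
        self.n_features_in_ = 1
        self.params_ = params
        self.mse_ = mse
        self.residuals_ = residuals
        self.residual_sd_ = float(np.std(mags))  # population (÷N) convention
        self.trace_ = trace
        self.result_ = FitResult(
            model_kind=self.model,
            params=params,
            mse=mse,
            residuals=residuals,
            residual_sd=self.residual_sd_,
            best_objective_trace=trace,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Model impedance at the given frequencies (Hz)."""
        if not hasattr(self, "params_"):
            raise AttributeError("fitter is not fitted yet; call fit first")
        f = np.asarray(X, dtype=float).ravel()
        return impedance(self.params_, f)

    def score(self, X, y=None) -> float:
        """Negative MSE of the fitted model on the given spectrum."""
        f, z = _as_f_z(X, y)
        return -float(np.mean(np.abs(z - self.predict(f)) ** 2))


@dataclass
class ModelComparison:
    """Per-model fit results for one spectrum, with the MSE-best kind."""

    results: Dict[str, FitResult]
    best_kind: str

    def __getitem__(self, kind: str) -> FitResult:
        return self.results[kind]

    def __len__(self) -> int:
        return len(self.results)

    @property
    def best(self) -> FitResult:
        return self.results[self.best_kind]


def fit_model(
    spectrum: ImpedanceSpectrum,
    model_kind: str = "Z0",
    config: GAConfig | None = None,
) -> FitResult:
    """Fit one model kind to a spectrum; wrapper over `GAColeFitter`."""
    config = config or GAConfig()
    fitter = GAColeFitter(
        model=model_kind,
        population_size=config.population_size,
        generations=config.generations,
        elite_fraction=config.elite_fraction,
        mutate_fraction=config.mutate_fraction,
        mutation_prob_start=config.mutation_prob_start,
        mutation_prob_end=config.mutation_prob_end,
        bounds=config.bounds,
        seed=config.seed,
    )
    return fitter.fit(spectrum).result_


def fit_all_models(
    spectrum: ImpedanceSpectrum, config: GAConfig | None = None
) -> ModelComparison:
    """Fit Z0, Z1 and Z2 to the same spectrum with a shared config."""
    results = {kind: fit_model(spectrum, kind, config) for kind in MODEL_KINDS}
    best_kind = min(results, key=lambda k: results[k].mse)
    return ModelComparison(results=results, best_kind=best_kind)
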