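"""Fitting the model age-incidence curve to age-binned observations.

Free parameters are a subset of {r1, gamma3, gamma45, K_A, K_R} evaluated on
an exhaustive grid (the loss surface is multimodal and cheap to tabulate, so
grid search with optional local refinement is the method of record). The loss
is the sum of squared differences between the model cumulative incidence
P(t_mid - DT) at the bin midpoints and the observed cumulative incidence;
binomial-variance weighting is available.

Model selection contrasts the *linear* model (no crypt competition,
K_A = K_R = infinity) with the *nonlinear* (finite carrying capacity) model.
With unlimited fission the predicted incidence rises too steeply with age,
and the best linear fits push the fission rates to the zero boundary; the
report records exactly that diagnostic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deterministic import IntegrationError, growth_delay_for, incidence_curve
from .model import ConversionMatrix, DomainError, ModelParams, conversion_matrix

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelSelectionReport",
    "fit_error",
    "grid_fit",
    "model_selection_linear_vs_nonlinear",
    "default_grids",
]

_FREE_PARAMS = ("r1", "gamma3", "gamma45", "K_A", "K_R")


def default_grids() -> dict:
    """Default search grids: fission rates in [0, 1]/yr (log-spaced plus an
    exact zero), carrying capacities spanning ~1e2..1e4, r1 over a broad
    physiological band of stem-cell division rates."""
    gamma = np.concatenate([[0.0], np.geomspace(0.0125, 0.8, 7)])
    K = np.geomspace(100.0, 10_000.0, 7)
    r1 = np.geomspace(5.0, 150.0, 6)
    return {"r1": r1, "gamma3": gamma, "gamma45": gamma.copy(), "K_A": K, "K_R": K.copy()}


@dataclass
class FitConfig:
    """Grid-search configuration.

    ``gamma5_equals_gamma4`` ties the two KRAS+ fission rates (the incidence
    data cannot separate them). ``loss`` is "sse"; ``weights`` may be
    "binomial" to weight squared residuals by inverse binomial variance.
    """

    free_parameters: tuple[str, ...] = ("gamma3", "gamma45", "K_A", "K_R")
    grids: dict = field(default_factory=default_grids)
    gamma5_equals_gamma4: bool = True
    loss: str = "sse"
    weights: str | None = None

    def __post_init__(self) -> None:
        self.free_parameters = tuple(self.free_parameters)
        unknown = set(self.free_parameters) - set(_FREE_PARAMS)
        if unknown:
            raise DomainError(f"unknown free parameters: {sorted(unknown)}")
        if self.loss != "sse":
            raise DomainError("only the 'sse' loss is implemented")
        for name in self.free_parameters:
            g = np.asarray(self.grids.get(name, ()), dtype=float)
            if g.size == 0:
                raise DomainError(f"empty grid for {name}")
            if np.any(g < 0):
                raise DomainError(f"grid for {name} must be non-negative")
            self.grids[name] = np.sort(g)


@dataclass
class FitResult:
    """Best parameters, loss, the full error surface, and boundary flags."""

    best_params: ModelParams
    error: float
    error_surface: pd.DataFrame
    flags: dict

    def to_csv(self, path, **meta) -> None:
        from .io import write_csv_with_metadata

        write_csv_with_metadata(self.error_surface, path, **meta)


def _apply_free(params: ModelParams, names, values) -> ModelParams:
    changes: dict = {}
    gamma = list(params.gamma)
    for name, val in zip(names, values):
        if name == "gamma3":
            gamma[0] = float(val)
        elif name == "gamma45":
            gamma[1] = float(val)
            gamma[2] = float(val)
        else:
            changes[name] = float(val)
    changes["gamma"] = tuple(gamma)
    return params.replace(**changes)


_CURVE_CACHE: dict = {}


def _predicted(params: ModelParams, ages: tuple, delta_t: float) -> np.ndarray:
    key = (params, ages, round(delta_t, 9))
    hit = _CURVE_CACHE.get(key)
    if hit is None:
        hit = incidence_curve(
            params, None, np.asarray(ages), delta_t=delta_t
        ).cumulative_incidence
        if len(_CURVE_CACHE) > 100_000:
            _CURVE_CACHE.clear()
        _CURVE_CACHE[key] = hit
    return hit


def clear_curve_cache() -> None:
    _CURVE_CACHE.clear()


def _midpoints(data) -> np.ndarray:
    return (data.frame["age_lo"].to_numpy() + data.frame["age_hi"].to_numpy() + 1) / 2.0


def fit_error(
    params: ModelParams,
    data,
    *,
    delta_t: float | None = None,
    weights: str | None = None,
) -> float:
    """Sum of squared differences between model and observed cumulative
    incidence at the observation-bin midpoints.

    ``data`` is an IncidenceTable. Bins are [age_lo, age_hi] inclusive
    5-year ranges; the model is evaluated at their midpoints.
    """
    if len(data.frame) == 0:
        raise DomainError("empty incidence table")
    mids = _midpoints(data)
    if delta_t is None:
        delta_t = growth_delay_for(params)
    pred = _predicted(params, tuple(mids), delta_t)
    obs = data.frame["cumulative_incidence"].to_numpy(dtype=float)
    resid2 = (pred - obs) ** 2
    if weights == "binomial":
        p = np.clip(obs, 1e-12, 1 - 1e-12)
        var = p * (1 - p) / data.frame["cohort_size"].to_numpy(dtype=float)
        resid2 = resid2 / var
    elif weights is not None:
        raise DomainError(f"unknown weighting {weights!r}")
    return float(resid2.sum())


def grid_fit(data, config: FitConfig, params_base: ModelParams) -> FitResult:
    """Exhaustive grid evaluation of the loss; deterministic.

    The growth delay DT depends only on (gamma6, delta6, detection_size),
    which are never free, so it is computed once from ``params_base``.
    """
    names = config.free_parameters
    grids = [np.asarray(config.grids[n], dtype=float) for n in names]
    delta_t = growth_delay_for(params_base)
    rows = []
    best_loss = math.inf
    best_vals: tuple = ()
    combos = itertools.product(*grids) if names else [()]
    n_failed = 0
    for values in combos:
        p = _apply_free(params_base, names, values)
        try:
            with warnings.catch_warnings():
                # solver chatter from explosive grid corners (handled below)
                warnings.filterwarnings("ignore", message=".*lsoda.*")
                loss = fit_error(p, data, delta_t=delta_t, weights=config.weights)
        except IntegrationError:
            # explosive corner of the grid (e.g. unlimited fission at high r1):
            # infinitely bad fit, recorded as such
            loss = math.inf
            n_failed += 1
        rows.append((*values, loss))
        if loss < best_loss:
            best_loss = loss
            best_vals = values
    if not math.isfinite(best_loss):
        raise IntegrationError("every grid point failed to integrate")
    surface = pd.DataFrame(rows, columns=[*names, "loss"])
    flags = {"n_failed_points": n_failed}
    for name, grid in zip(names, grids):
        val = best_vals[names.index(name)]
        flags[f"{name}_at_lower"] = bool(val == grid[0])
        flags[f"{name}_at_upper"] = bool(val == grid[-1])
        if name.startswith("gamma"):
            flags[f"{name}_at_zero"] = bool(val == 0.0)
    best_params = _apply_free(params_base, names, best_vals)
    return FitResult(
        best_params=best_params, error=best_loss, error_surface=surface, flags=flags
    )


@dataclass
class ModelSelectionReport:
    """Linear (K = infinity) vs nonlinear (finite K) model comparison."""

    linear: FitResult
    nonlinear: FitResult
    linear_fission_at_zero: bool
    linear_best_gammas: dict
    nonlinear_best_gammas: dict

    @property
    def nonlinear_preferred(self) -> bool:
        return self.nonlinear.error <= self.linear.error


def model_selection_linear_vs_nonlinear(
    data, config: FitConfig, params_base: ModelParams
) -> ModelSelectionReport:
    """Fit the no-competition (K_A = K_R = inf) and finite-K models.

    Reports best losses, the best-fitting fission rates under each, and
    whether the linear model's optimum sits at the zero-fission boundary —
    the diagnostic under which unlimited fission is rejected.
    """
    lin_free = tuple(n for n in config.free_parameters if n not in ("K_A", "K_R"))
    lin_config = FitConfig(
        free_parameters=lin_free,
        grids={n: config.grids[n] for n in lin_free},
        gamma5_equals_gamma4=config.gamma5_equals_gamma4,
        loss=config.loss,
        weights=config.weights,
    )
    lin_base = params_base.replace(K_A=math.inf, K_R=math.inf)
    linear = grid_fit(data, lin_config, lin_base)
    nonlinear = grid_fit(data, config, params_base)

    def _gammas(res: FitResult) -> dict:
        return {
            "gamma3": res.best_params.gamma3,
            "gamma4": res.best_params.gamma4,
            "gamma5": res.best_params.gamma5,
        }

    gamma_names = [n for n in lin_free if n.startswith("gamma")]
    at_zero = all(linear.flags.get(f"{n}_at_zero", False) for n in gamma_names) and bool(
        gamma_names
    )
    return ModelSelectionReport(
        linear=linear,
        nonlinear=nonlinear,
        linear_fission_at_zero=at_zero,
        linear_best_gammas=_gammas(linear),
        nonlinear_best_gammas=_gammas(nonlinear),
    )
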