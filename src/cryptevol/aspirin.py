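"""Aspirin intervention: dose-derived kinetic fold-changes and relative risk.

Xenograft experiments measured a dose-dependent fold-reduction in tumour-cell
division rate (F_r < 1) and fold-increase in death rate (F_d > 1). For stem
cells, removal is a mix of differentiation (90%) and apoptosis (10%), and only
the apoptotic component responds to the drug, so the aspirin-induced change in
stem-cell fitness is the *fitness factor*

    phi = F_r / ((1 - a) + a * F_d),        a = apoptosis fraction (0.1)

which multiplies the invading type's relative fitness in the crypt-conversion
fixation probability. At the inter-crypt level aspirin scales crypt fission
rates by F_r and crypt death rates by F_d. A regimen applies these changes
during a treatment window [t_start, t_end) either to type 6 only or to all
mutated types 2-6, and either to intra-crypt dynamics only or to both levels.

Relative risk is the ratio of cumulative detected-adenoma incidence by an
assessment age in treated vs untreated simulated cohorts, with common random
numbers by default so that dose comparisons are paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    EDGES,
    APC_EDGES,
    APC_FIRST_HIT_EDGES,
    ConversionMatrix,
    DomainError,
    ModelParams,
    conversion_matrix,
    fixation_probability,
)
from .stochastic import ParameterSwitch, run_detection_ensemble

__all__ = [
    "AspirinRegimen",
    "DOSE_TABLE",
    "TreatedModel",
    "RelativeRiskResult",
    "UndefinedRRError",
    "fitness_factor",
    "human_equivalent_dose",
    "apply_regimen",
    "relative_risk",
    "regimen_for_dose",
]


class UndefinedRRError(ZeroDivisionError):
    """Untreated incidence is zero at the assessment age."""


def fitness_factor(f_r: float, f_d: float, apoptosis_fraction: float = 0.1) -> float:
    """Aspirin-induced multiplicative change in stem-cell fitness.

    phi = f_r / ((1 - a) + a * f_d) with a the fraction of stem-cell removal
    that is apoptosis (the rest being loss through differentiation, which the
    drug does not touch).
    """
    if f_r <= 0 or f_d <= 0:
        raise DomainError("fold changes must be positive")
    if not 0.0 <= apoptosis_fraction <= 1.0:
        raise DomainError("apoptosis_fraction must be in [0, 1]")
    return f_r / ((1.0 - apoptosis_fraction) + apoptosis_fraction * f_d)


def human_equivalent_dose(
    mouse_mg_per_kg: float,
    human_mass_kg: float = 70.0,
    bsa_factor: float = 12.3,
    pill_mg: float = 325.0,
) -> float:
    """Human-equivalent aspirin intake, in 325 mg pills per week.

    Standard body-surface-area scaling: the mouse mg/kg dose is divided by
    12.3 to obtain the human mg/kg equivalent, scaled to a 70 kg adult dosed
    daily, and expressed in standard pills per week.
    """
    if mouse_mg_per_kg < 0 or human_mass_kg <= 0 or bsa_factor <= 0 or pill_mg <= 0:
        raise DomainError("doses, masses and scaling constants must be positive")
    return mouse_mg_per_kg / bsa_factor * human_mass_kg * 7.0 / pill_mg


#: Xenograft doses with their human equivalents and measured kinetic fold-changes.
DOSE_TABLE = pd.DataFrame(
    [
        ("light", 15.0, 1.8, 0.9, 1.5),
        ("medium", 50.0, 6.1, 0.75, 1.75),
        ("strong", 100.0, 12.2, 0.5, 2.0),
    ],
    columns=["label", "mouse_dose_mg_per_kg", "pills_per_week", "f_r", "f_d"],
)


@dataclass(frozen=True)
class AspirinRegimen:
    """A treatment window with its kinetic fold-changes and scope.

    ``affected_types``: "type6_only" (only the fully transformed type) or
    "types2to6" (all mutated types). ``affected_levels``: "intra_only"
    (conversion rates only) or "intra_and_inter" (also fission/death rates).
    ``conversion_mode``: how the fitness factor enters conversion rates —
    "fixation" multiplies the invader's fitness inside the Moran fixation
    probability (default); "direct" multiplies the affected R_ij directly.
    """

    f_r: float
    f_d: float
    t_start: float
    t_end: float
    affected_types: str = "types2to6"
    affected_levels: str = "intra_and_inter"
    apoptosis_fraction: float = 0.1
    conversion_mode: str = "fixation"

    def __post_init__(self) -> None:
        if self.f_r <= 0 or self.f_d <= 0:
            raise DomainError("fold changes must be positive")
        if not self.t_start < self.t_end:
            raise DomainError("need t_start < t_end")
        if not 0.0 <= self.apoptosis_fraction <= 1.0:
            raise DomainError("apoptosis_fraction must be in [0, 1]")
        if self.affected_types not in ("type6_only", "types2to6"):
            raise DomainError(f"unknown affected_types {self.affected_types!r}")
        if self.affected_levels not in ("intra_only", "intra_and_inter"):
            raise DomainError(f"unknown affected_levels {self.affected_levels!r}")
        if self.conversion_mode not in ("fixation", "direct"):
            raise DomainError(f"unknown conversion_mode {self.conversion_mode!r}")

    @property
    def fitness_factor(self) -> float:
        return fitness_factor(self.f_r, self.f_d, self.apoptosis_fraction)

    @property
    def target_types(self) -> frozenset:
        return frozenset({6}) if self.affected_types == "type6_only" else frozenset(
            {2, 3, 4, 5, 6}
        )


def regimen_for_dose(label: str, t_start: float, t_end: float, **kwargs) -> AspirinRegimen:
    """Regimen built from a named row of the dose table."""
    row = DOSE_TABLE[DOSE_TABLE["label"] == label]
    if row.empty:
        raise DomainError(f"unknown dose label {label!r}")
    return AspirinRegimen(
        f_r=float(row["f_r"].iloc[0]),
        f_d=float(row["f_d"].iloc[0]),
        t_start=t_start,
        t_end=t_end,
        **kwargs,
    )


@dataclass(frozen=True)
class TreatedModel:
    """Piecewise-constant model: baseline outside the window, treated inside."""

    params_base: ModelParams
    rates_base: ConversionMatrix
    params_treated: ModelParams
    rates_treated: ConversionMatrix
    regimen: AspirinRegimen

    @property
    def switch(self) -> ParameterSwitch:
        return ParameterSwitch(
            params=self.params_treated,
            rates=self.rates_treated,
            t_start=self.regimen.t_start,
            t_end=self.regimen.t_end,
        )

    def params_at(self, t: float) -> ModelParams:
        in_window = self.regimen.t_start <= t < self.regimen.t_end
        return self.params_treated if in_window else self.params_base

    def rates_at(self, t: float) -> ConversionMatrix:
        in_window = self.regimen.t_start <= t < self.regimen.t_end
        return self.rates_treated if in_window else self.rates_base


def _treated_rates(
    params: ModelParams, rates: ConversionMatrix, regimen: AspirinRegimen
) -> ConversionMatrix:
    phi = regimen.fitness_factor
    targets = regimen.target_types
    F = params.fitness
    new = dict(rates.as_dict())
    for edge in EDGES:
        i, j = edge
        if j not in targets:
            continue
        if regimen.conversion_mode == "direct":
            new[edge] = new[edge] * phi
        else:
            u_ij = params.u if edge in APC_EDGES else params.mu
            if edge in APC_FIRST_HIT_EDGES:
                u_ij *= params.apc_first_hit_multiplicity
            rho = fixation_probability(F[j - 1] * phi / F[i - 1], params.n_sc)
            new[edge] = params.n_sc * params.r1 * F[i - 1] * u_ij * rho
    return ConversionMatrix.from_mapping(new)


def apply_regimen(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    regimen: AspirinRegimen | None = None,
) -> TreatedModel:
    """Build the time-dependent (piecewise-constant) model under a regimen.

    During the window, conversion rates into affected types carry the fitness
    factor; with ``affected_levels="intra_and_inter"`` the fission rates of
    affected crypt types are additionally scaled by f_r and their death rates
    by f_d. Outside the window all parameters revert exactly.
    """
    if regimen is None:
        raise DomainError("a regimen is required")
    if rates is None:
        rates = conversion_matrix(params)
    rates_trt = _treated_rates(params, rates, regimen)
    params_trt = params
    if regimen.affected_levels == "intra_and_inter":
        targets = regimen.target_types
        gamma = list(params.gamma)  # entries for types 3, 4, 5, 6
        for idx, ctype in enumerate((3, 4, 5, 6)):
            if ctype in targets:
                gamma[idx] = gamma[idx] * regimen.f_r
        delta = params.delta * regimen.f_d if targets >= {3, 4, 5} else params.delta
        delta6 = params.delta6 * regimen.f_d if 6 in targets else params.delta6
        params_trt = params.replace(gamma=tuple(gamma), delta=delta, delta6=delta6)
    return TreatedModel(
        params_base=params,
        rates_base=rates,
        params_treated=params_trt,
        rates_treated=rates_trt,
        regimen=regimen,
    )


@dataclass
class RelativeRiskResult:
    """RR of detected advanced adenoma by the assessment age, with 95% CI."""

    rr: float
    ci_low: float
    ci_high: float
    p_treated: float
    p_untreated: float
    assessment_age: float
    n_runs: int
    seed: int


def relative_risk(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    regimen: AspirinRegimen | None = None,
    assessment_age: float = 80.0,
    n_runs: int = 2000,
    seed: int = 0,
    *,
    t_max: float | None = None,
    common_random_numbers: bool = True,
    hybrid: bool = True,
) -> RelativeRiskResult:
    """Relative risk = treated / untreated cumulative detection fraction.

    Both arms use seeded ensembles; with common random numbers (default) the
    two arms share per-run seeds and segment boundaries, so runs are identical
    until treatment starts and dose ladders are paired.
    """
    if regimen is None:
        raise DomainError("a regimen is required")
    if assessment_age <= 0:
        raise DomainError("assessment_age must be positive")
    if rates is None:
        rates = conversion_matrix(params)
    model = apply_regimen(params, rates, regimen)
    if t_max is None:
        t_max = assessment_age
    if t_max < assessment_age:
        raise DomainError("t_max must cover the assessment age")
    if regimen.t_start >= t_max:
        # window never opens within the simulated horizon; arms coincide
        pass
    null_switch = ParameterSwitch(
        params=params, rates=rates, t_start=regimen.t_start, t_end=regimen.t_end
    )
    seed_u = seed if common_random_numbers else seed + 1
    ens_t = run_detection_ensemble(
        params, rates, n_runs, t_max, seed, switch=model.switch, hybrid=hybrid
    )
    ens_u = run_detection_ensemble(
        params, rates, n_runs, t_max, seed_u, switch=null_switch, hybrid=hybrid
    )
    x = (np.nan_to_num(ens_t.detection_ages, nan=np.inf) <= assessment_age)
    y = (np.nan_to_num(ens_u.detection_ages, nan=np.inf) <= assessment_age)
    p_t = x.mean()
    p_u = y.mean()
    if p_u == 0:
        raise UndefinedRRError("no untreated detections by the assessment age")
    if p_t == 0:
        return RelativeRiskResult(0.0, 0.0, float("nan"), 0.0, float(p_u),
                                  float(assessment_age), int(n_runs), int(seed))
    rr = p_t / p_u
    # delta method on log RR for paired binary outcomes
    cov = np.mean(x & y) - p_t * p_u
    var_log = (
        (1 - p_t) / p_t + (1 - p_u) / p_u - 2 * cov / (p_t * p_u)
    ) / n_runs
    var_log = max(var_log, 0.0)
    half = 1.959963984540054 * math.sqrt(var_log)
    return RelativeRiskResult(
        rr=float(rr),
        ci_low=float(rr * math.exp(-half)),
        ci_high=float(rr * math.exp(half)),
        p_treated=float(p_t),
        p_untreated=float(p_u),
        assessment_age=float(assessment_age),
        n_runs=int(n_runs),
        seed=int(seed),
    )
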