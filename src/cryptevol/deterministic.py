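"""Mean-field dynamics: crypt ODE system, adenoma probability, incidence curve.

The expected numbers of crypts of types 1-5 obey

    dn1/dt = -(R12 + R14) n1
    dn2/dt =  R12 n1 - (R23 + R25) n2
    dn3/dt =  R23 n2 - R36 n3 + g3 n3 (1 - S/K_A) - d n3
    dn4/dt =  R14 n1 - R45 n4 + g4 n4 (1 - S/K_R) - d n4
    dn5/dt =  R25 n2 + R45 n4 - R56 n5 + g5 n5 (1 - S/K_R) - d n5

with S = n3 + n4 + n5, starting from n1(0) = N_crypt and all other types at
zero. The probability that at least one type-6 (advanced adenoma) crypt has
been generated by age t satisfies

    dP/dt = (R56 n5 + R36 n3) (1 - P),    P(0) = 0,

and splits into the APC path (final KRAS hit in an APC-/- crypt, edge 3->6)
and the KRAS path (final APC hit in a KRAS+ APC+/- crypt, edge 5->6):

    dP_APC/dt  = R36 n3 (1 - P),   dP_KRAS/dt = R56 n5 (1 - P),

so P_APC + P_KRAS = P identically. The age-incidence curve of *detected*
advanced adenoma is P(t - DT), where DT is the expected time for a single
type-6 crypt to grow by fission (rate gamma_6) and death (rate delta_6) to
the detection size N, conditioned on non-extinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import ConversionMatrix, DomainError, ModelParams, conversion_matrix

__all__ = [
    "Trajectory",
    "IncidenceCurve",
    "IntegrationError",
    "integrate_crypt_odes",
    "expected_growth_delay",
    "incidence_curve",
    "pathway_proportion",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an inadmissible solution."""


class UndefinedProportionError(ZeroDivisionError):
    """Both pathway probabilities are zero; the proportion is undefined."""


@dataclass
class Trajectory:
    """Deterministic solution: expected crypt counts and adenoma probabilities."""

    times: np.ndarray          # ages, years
    n: np.ndarray              # shape (len(times), 5), expected counts n1..n5
    p: np.ndarray              # P(t)
    p_apc: np.ndarray          # P_APC(t)
    p_kras: np.ndarray         # P_KRAS(t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age": self.times,
                **{f"n{i + 1}": self.n[:, i] for i in range(5)},
                "P": self.p,
                "P_APC": self.p_apc,
                "P_KRAS": self.p_kras,
            }
        )

    def to_csv(self, path, **meta) -> None:
        from .io import write_csv_with_metadata

        write_csv_with_metadata(self.to_frame(), path, **meta)


@dataclass
class IncidenceCurve:
    """Cumulative incidence of detected advanced adenoma by age."""

    ages: np.ndarray
    cumulative_incidence: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_runs: int | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.cumulative_incidence = np.asarray(self.cumulative_incidence, dtype=float)
        inc = self.cumulative_incidence
        if inc.size and (inc.min() < -1e-12 or inc.max() > 1 + 1e-12):
            raise DomainError("cumulative incidence must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        d = {"age": self.ages, "incidence": self.cumulative_incidence}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return pd.DataFrame(d)

    def to_csv(self, path, **meta) -> None:
        from .io import write_csv_with_metadata

        write_csv_with_metadata(self.to_frame(), path, **meta)


def _rhs(t, y, R, params: ModelParams, printed_variant: bool):
    n1, n2, n3, n4, n5, P, Papc, Pkras = y
    R12, R23, R14, R25, R45, R36, R56 = R
    g3, g4, g5, _ = params.gamma
    d = params.delta
    S = n3 + n4 + n5
    cA = 0.0 if math.isinf(params.K_A) else S / params.K_A
    cR = 0.0 if math.isinf(params.K_R) else S / params.K_R
    if printed_variant:
        # As printed (no influx R12*n1 into n2; -R45*n4 in n5): violates
        # conservation, retained only for archaeology.
        dn2 = R23 * n1 - (R23 + R25) * n2
        dn5 = R25 * n2 - R45 * n4 - R56 * n5 + g5 * n5 * (1 - cR) - d * n5
    else:
        dn2 = R12 * n1 - (R23 + R25) * n2
        dn5 = R25 * n2 + R45 * n4 - R56 * n5 + g5 * n5 * (1 - cR) - d * n5
    dn1 = -(R12 + R14) * n1
    dn3 = R23 * n2 - R36 * n3 + g3 * n3 * (1 - cA) - d * n3
    dn4 = R14 * n1 - R45 * n4 + g4 * n4 * (1 - cR) - d * n4
    hazard = R56 * n5 + R36 * n3
    dP = hazard * (1 - P)
    return (dn1, dn2, dn3, dn4, dn5, dP, R36 * n3 * (1 - P), R56 * n5 * (1 - P))


def _solve(params, rates, t_end, rtol, atol, printed_variant=False,
           initial_counts=None):
    R = rates.rates
    y0 = np.zeros(8)
    if initial_counts is not None:
        y0[:5] = np.asarray(initial_counts, dtype=float)
    else:
        y0[0] = params.n_crypt
    sol = solve_ivp(
        _rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        args=(R, params, printed_variant),
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return sol


def integrate_crypt_odes(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    t_grid=None,
    *,
    printed_variant: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    initial_counts=None,
) -> Trajectory:
    """Integrate the crypt ODE system on a grid of ages.

    ``t_grid`` must be strictly increasing and start at 0. With
    ``printed_variant=True`` the non-conservative flux form is integrated
    instead (kept for comparison only; excluded from all invariants).
    ``initial_counts`` overrides the default all-wild-type initial condition
    (n1(0) = N_crypt) with explicit counts for types 1-5.
    """
    if rates is None:
        rates = conversion_matrix(params)
    t_grid = np.asarray(t_grid if t_grid is not None else np.linspace(0, 80, 161), float)
    if t_grid.ndim != 1 or t_grid.size < 1 or t_grid[0] != 0.0:
        raise DomainError("t_grid must be a 1-d grid starting at 0")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise DomainError("t_grid must be strictly increasing")
    sol = _solve(params, rates, float(t_grid[-1]), rtol, atol, printed_variant,
                 initial_counts=initial_counts)
    y = sol.sol(t_grid).T
    n = y[:, :5]
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite solution")
    neg_tol = max(atol * 1e3, 1e-9) + rtol * np.abs(n).max()
    if not printed_variant and n.min() < -neg_tol:
        raise IntegrationError(f"negative populations beyond tolerance: {n.min()}")
    n = np.clip(n, 0.0, None)
    p = np.clip(y[:, 5], 0.0, 1.0)
    return Trajectory(times=t_grid, n=n, p=p, p_apc=y[:, 6], p_kras=y[:, 7])


# ---------------------------------------------------------------------------
# Growth delay of the type-6 colony


def expected_growth_delay(
    gamma6: float,
    delta6: float,
    detection_size: int,
    method: str = "simulation",
    n_reps: int = 10_000,
    seed: int = 0,
    return_se: bool = False,
):
    """Expected time DT for a type-6 colony to grow from 1 to the detection size.

    The colony follows a linear birth-death process (birth rate gamma6*k,
    death rate delta6*k). ``method="simulation"`` returns the mean first
    passage time from 1 to ``detection_size`` conditioned on reaching it,
    from ``n_reps`` seeded replicates. ``method="analytic"`` returns the fast
    approximation sum_{k=1}^{N-1} 1 / (k * (gamma6 - delta6)) (exact for
    delta6 = 0 in expectation of the Yule first-passage time; otherwise an
    approximation that ignores sub-detection excursions and conditioning).
    """
    if not gamma6 > delta6 or delta6 < 0:
        raise DomainError(
            f"need gamma6 > delta6 >= 0 (supercritical growth), got {gamma6}, {delta6}"
        )
    N = int(detection_size)
    if N < 2:
        raise DomainError("detection_size must be >= 2")
    if method == "analytic":
        dt = sum(1.0 / (k * (gamma6 - delta6)) for k in range(1, N))
        return (dt, 0.0) if return_se else dt
    if method != "simulation":
        raise DomainError(f"unknown method {method!r}")
    from .stochastic import sample_type6_growth_times

    sample = sample_type6_growth_times(gamma6, delta6, N, n_runs=n_reps, seed=seed)
    times = sample.times
    if times.size == 0:
        raise IntegrationError("no replicate reached the detection size")
    mean = float(times.mean())
    se = float(times.std(ddof=1) / math.sqrt(times.size)) if times.size > 1 else 0.0
    return (mean, se) if return_se else mean


_DELAY_CACHE: dict = {}


def growth_delay_for(params: ModelParams, method="simulation",
                     n_reps=10_000, seed=0) -> float:
    """Memoized DT for a parameter set (depends only on gamma6, delta6, N)."""
    key = (params.gamma6, params.delta6, params.detection_size, method, n_reps, seed)
    if key not in _DELAY_CACHE:
        _DELAY_CACHE[key] = expected_growth_delay(
            params.gamma6, params.delta6, params.detection_size,
            method=method, n_reps=n_reps, seed=seed,
        )
    return _DELAY_CACHE[key]


def incidence_curve(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    ages=None,
    *,
    delta_t: float | None = None,
    delay_method: str = "simulation",
    delay_reps: int = 10_000,
    seed: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> IncidenceCurve:
    """Model age-incidence curve of detected advanced adenoma, P(t - DT).

    ``delta_t`` overrides the growth delay; otherwise it is computed from
    (gamma6, delta6, detection_size) and memoized. Ages earlier than DT have
    zero incidence.
    """
    if rates is None:
        rates = conversion_matrix(params)
    ages = np.asarray(ages if ages is not None else np.linspace(0, 80, 81), float)
    if np.any(ages < 0):
        raise DomainError("ages must be non-negative")
    if delta_t is None:
        delta_t = growth_delay_for(params, delay_method, delay_reps, seed)
    shifted = ages - delta_t
    t_end = float(max(shifted.max(), 0.0)) or 1.0
    sol = _solve(params, rates, t_end, rtol, atol)
    inc = np.zeros_like(ages)
    pos = shifted > 0
    if pos.any():
        inc[pos] = np.clip(sol.sol(shifted[pos])[5], 0.0, 1.0)
    return IncidenceCurve(ages=ages, cumulative_incidence=inc)


def pathway_proportion(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    horizon: float = 80.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> float:
    """Proportion of adenoma probability arising through the APC path.

    Returns P_APC(horizon) / (P_APC(horizon) + P_KRAS(horizon)).
    """
    if horizon <= 0:
        raise DomainError("horizon must be positive")
    if rates is None:
        rates = conversion_matrix(params)
    sol = _solve(params, rates, float(horizon), rtol, atol)
    _, _, _, _, _, _, papc, pkras = sol.sol(horizon)
    total = papc + pkras
    if total <= 0:
        raise UndefinedProportionError(
            "both pathway probabilities are zero at the horizon"
        )
    return float(papc / total)
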