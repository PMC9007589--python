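"""Exact stochastic (Gillespie) simulation of the crypt model.

Events are crypt conversions on the seven edges of the mutation graph,
fission of types 3-6 (types 3-5 with logistic thinning against their shared
competitor pool n3+n4+n5, capped at K_A resp. K_R; propensities clamped at
zero above capacity), and crypt death of types 3-6. A run ends when the
type-6 colony reaches the detection size (advanced adenoma detection) or at
the censoring age ``t_max``.

Two modes are provided:

* hybrid (default): types 1-2, whose dynamics are linear and autonomous and
  whose counts are of order 10^7, evolve deterministically (closed-form
  two-compartment solution, piecewise over treatment segments) and feed a
  time-inhomogeneous Poisson influx of type-3/4/5 crypts, sampled by
  thinning with a short-lookahead bound; types 3-6 are simulated exactly.
* full: every type, including the wild-type pool, is simulated exactly
  (useful for validating the hybrid on small crypt numbers).

Randomness: each run gets its own seed derived from the master seed via
``numpy.random.SeedSequence``, so ensembles are reproducible run-by-run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import ConversionMatrix, DomainError, ModelParams, conversion_matrix

__all__ = [
    "ParameterSwitch",
    "GillespieResult",
    "DetectionEnsemble",
    "FirstType6Counts",
    "GrowthTimeSample",
    "SimulationError",
    "gillespie_run",
    "run_detection_ensemble",
    "simulate_incidence",
    "counts_at_first_type6",
    "sample_type6_growth_times",
]


class SimulationError(RuntimeError):
    """The stochastic simulation reached an inadmissible state."""


@dataclass(frozen=True)
class ParameterSwitch:
    """Piecewise-constant parameter change during [t_start, t_end)."""

    params: ModelParams
    rates: ConversionMatrix
    t_start: float
    t_end: float


_LOOKAHEAD = 2.0  # years; bound-refresh horizon for influx thinning

# Status codes returned by the core.
_OK = 0.0
_FAIL = 1.0


@njit(cache=False)
def _ssa_one(
    seed,
    hybrid,
    R0, R1,            # float64[7] conversion rates, base / treated
    gam0, gam1,        # float64[4] fission rates types 3..6
    dlt0, dlt1,        # float64[4] death rates types 3..6
    K_A, K_R,
    ts, te,            # treatment window
    t_max, det_size,
    init1, init2, init3, init4, init5, init6,
):
    # out: [det_time, first6_time, n3_at6, n5_at6, status, n1..n6]
    np.random.seed(seed)
    out = np.empty(11, dtype=np.float64)
    out[0] = -1.0
    out[1] = -1.0
    out[2] = -1.0
    out[3] = -1.0
    out[4] = _OK

    n1c = float(init1)  # deterministic layer (hybrid mode)
    n2c = float(init2)
    n1 = init1          # integer state (full mode)
    n2 = init2
    n3 = init3
    n4 = init4
    n5 = init5
    n6 = init6

    t = 0.0
    if n6 >= det_size:
        out[0] = 0.0
    props = np.zeros(15, dtype=np.float64)

    while out[0] < 0.0 and t < t_max:
        treated = ts <= t < te
        if treated:
            R, gam, dlt = R1, gam1, dlt1
        else:
            R, gam, dlt = R0, gam0, dlt0
        # next parameter/censoring boundary
        seg_end = t_max
        if t < ts <= t_max:
            seg_end = ts
        elif t < te <= seg_end:
            seg_end = te
        horizon = t + _LOOKAHEAD
        if seg_end < horizon:
            horizon = seg_end

        R12, R23, R14, R25, R45, R36, R56 = R[0], R[1], R[2], R[3], R[4], R[5], R[6]
        S = float(n3 + n4 + n5)
        cA = S / K_A
        cR = S / K_R
        if hybrid:
            props[0] = 0.0
            props[1] = 0.0
            props[2] = 0.0
            props[3] = 0.0
        else:
            props[0] = R12 * n1
            props[1] = R23 * n2
            props[2] = R14 * n1
            props[3] = R25 * n2
        props[4] = R45 * n4
        props[5] = R36 * n3
        props[6] = R56 * n5
        f3 = gam[0] * n3 * (1.0 - cA)
        f4 = gam[1] * n4 * (1.0 - cR)
        f5 = gam[2] * n5 * (1.0 - cR)
        props[7] = f3 if f3 > 0.0 else 0.0
        props[8] = f4 if f4 > 0.0 else 0.0
        props[9] = f5 if f5 > 0.0 else 0.0
        props[10] = gam[3] * n6
        props[11] = dlt[0] * n3
        props[12] = dlt[1] * n4
        props[13] = dlt[2] * n5
        props[14] = dlt[3] * n6
        A = 0.0
        for k in range(15):
            A += props[k]
        # influx bound over [t, horizon] (hybrid only): n1 decreasing, and
        # dn2/dt <= R12*n1(t), so n2 <= n2c + R12*n1c*(horizon - t).
        B = 0.0
        if hybrid:
            n2_bound = n2c + R12 * n1c * (horizon - t)
            B = R14 * n1c + (R23 + R25) * n2_bound
        lam = A + B
        if not math.isfinite(lam):
            out[4] = _FAIL
            break

        if lam <= 0.0:
            dt = horizon - t
            if hybrid:
                n1c, n2c = _advance_wild(n1c, n2c, R12, R14, R23, R25, dt)
            t = horizon
            continue
        tau = -math.log(1.0 - np.random.random()) / lam
        if t + tau >= horizon:
            dt = horizon - t
            if hybrid:
                n1c, n2c = _advance_wild(n1c, n2c, R12, R14, R23, R25, dt)
            t = horizon
            continue
        if hybrid:
            n1c, n2c = _advance_wild(n1c, n2c, R12, R14, R23, R25, tau)
        t = t + tau
        u = np.random.random() * lam
        if u < A:
            acc = 0.0
            ch = -1
            for k in range(15):
                acc += props[k]
                if u < acc:
                    ch = k
                    break
            if ch == 0:      # 1 -> 2
                n1 -= 1; n2 += 1
            elif ch == 1:    # 2 -> 3
                n2 -= 1; n3 += 1
            elif ch == 2:    # 1 -> 4
                n1 -= 1; n4 += 1
            elif ch == 3:    # 2 -> 5
                n2 -= 1; n5 += 1
            elif ch == 4:    # 4 -> 5
                n4 -= 1; n5 += 1
            elif ch == 5 or ch == 6:   # 3 -> 6 or 5 -> 6
                if out[1] < 0.0:
                    out[1] = t
                    out[2] = float(n3)
                    out[3] = float(n5)
                if ch == 5:
                    n3 -= 1
                else:
                    n5 -= 1
                n6 += 1
            elif ch == 7:
                n3 += 1
            elif ch == 8:
                n4 += 1
            elif ch == 9:
                n5 += 1
            elif ch == 10:
                n6 += 1
            elif ch == 11:
                n3 -= 1
            elif ch == 12:
                n4 -= 1
            elif ch == 13:
                n5 -= 1
            elif ch == 14:
                n6 -= 1
            if n6 >= det_size:
                out[0] = t
        else:
            # candidate influx event; thin against the exact intensities
            I3 = R23 * n2c
            I4 = R14 * n1c
            I5 = R25 * n2c
            v = u - A
            if v < I3:
                n3 += 1
            elif v < I3 + I4:
                n4 += 1
            elif v < I3 + I4 + I5:
                n5 += 1
            # else: thinned, no event

    out[5] = n1c if hybrid else float(n1)
    out[6] = n2c if hybrid else float(n2)
    out[7] = float(n3)
    out[8] = float(n4)
    out[9] = float(n5)
    out[10] = float(n6)
    return out


@njit(cache=False)
def _advance_wild(n1c, n2c, R12, R14, R23, R25, dt):
    """Exact update of the deterministic type-1/2 pool over dt (constant rates)."""
    a = R12 + R14
    b = R23 + R25
    e_a = math.exp(-a * dt)
    if abs(b - a) > 1e-12 * (a + b + 1e-300):
        e_b = math.exp(-b * dt)
        n2n = n2c * e_b + R12 * n1c * (e_a - e_b) / (b - a)
    else:
        n2n = n2c * e_a + R12 * n1c * dt * e_a
    return n1c * e_a, n2n


@njit(cache=False)
def _ssa_batch(
    seeds, hybrid,
    R0, R1, gam0, gam1, dlt0, dlt1,
    K_A, K_R, ts, te, t_max, det_size,
    init1, init2, init3, init4, init5, init6,
):
    n = seeds.shape[0]
    out = np.empty((n, 11), dtype=np.float64)
    for i in range(n):
        out[i] = _ssa_one(
            seeds[i], hybrid, R0, R1, gam0, gam1, dlt0, dlt1,
            K_A, K_R, ts, te, t_max, det_size,
            init1, init2, init3, init4, init5, init6,
        )
    return out


def _pack(params: ModelParams, rates: ConversionMatrix):
    R = np.asarray(rates.rates, dtype=np.float64)
    gam = np.asarray(params.gamma, dtype=np.float64)
    dlt = np.asarray(
        [params.delta, params.delta, params.delta, params.delta6], dtype=np.float64
    )
    return R, gam, dlt


def _per_run_seeds(seed: int, n_runs: int) -> np.ndarray:
    state = np.random.SeedSequence(seed).generate_state(n_runs, np.uint32)
    return (state.astype(np.int64) % np.int64(2**31)).astype(np.int64)


def _run_batch(
    params: ModelParams,
    rates: ConversionMatrix,
    n_runs: int,
    t_max: float,
    seed: int,
    switch: ParameterSwitch | None = None,
    hybrid: bool = True,
    init_state=None,
) -> np.ndarray:
    R0, gam0, dlt0 = _pack(params, rates)
    if switch is None:
        R1, gam1, dlt1 = R0, gam0, dlt0
        ts, te = t_max + 1.0, t_max + 2.0
    else:
        R1, gam1, dlt1 = _pack(switch.params, switch.rates)
        ts, te = float(switch.t_start), float(switch.t_end)
        if ts >= te:
            raise DomainError("switch window must satisfy t_start < t_end")
    if t_max <= 0:
        raise DomainError("t_max must be positive")
    if init_state is None:
        init_state = (int(params.n_crypt), 0, 0, 0, 0, 0)
    init_state = tuple(int(v) for v in init_state)
    K_A = params.K_A if math.isfinite(params.K_A) else 1e300
    K_R = params.K_R if math.isfinite(params.K_R) else 1e300
    seeds = _per_run_seeds(seed, n_runs)
    out = _ssa_batch(
        seeds, hybrid, R0, R1, gam0, gam1, dlt0, dlt1,
        float(K_A), float(K_R), ts, te, float(t_max),
        int(params.detection_size), *init_state,
    )
    if np.any(out[:, 4] != _OK):
        bad = int(np.argmax(out[:, 4] != _OK))
        raise SimulationError(
            f"non-finite propensity in run {bad}; final state {out[bad, 5:].tolist()}"
        )
    return out


@dataclass
class GillespieResult:
    """Outcome of a single stochastic run."""

    detection_age: float | None
    censor_age: float
    first_type6_age: float | None
    n3_at_first_type6: int | None
    n5_at_first_type6: int | None
    final_state: tuple[int, ...]
    seed: int

    @property
    def censored(self) -> bool:
        return self.detection_age is None


@dataclass
class DetectionEnsemble:
    """Detection ages from a seeded ensemble of runs (NaN where censored)."""

    detection_ages: np.ndarray
    censor_age: float
    n_runs: int
    seed: int

    @property
    def detected(self) -> np.ndarray:
        return self.detection_ages[np.isfinite(self.detection_ages)]

    def fraction_detected_by(self, age) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(age, dtype=float))
        det = self.detected
        frac = np.array([(det <= a).sum() for a in ages], dtype=float) / self.n_runs
        return frac if np.ndim(age) else float(frac[0])

    def to_frame(self):
        import pandas as pd

        censored = ~np.isfinite(self.detection_ages)
        return pd.DataFrame(
            {
                "run_id": np.arange(self.n_runs),
                "detection_age": self.detection_ages,
                "censored": censored.astype(int),
            }
        )

    def to_csv(self, path, **meta) -> None:
        from .io import write_csv_with_metadata

        write_csv_with_metadata(self.to_frame(), path, seed=self.seed, **meta)


@dataclass
class FirstType6Counts:
    """Crypt counts at the instant the first type-6 crypt is generated.

    Counts are recorded immediately before the conversion event, so the
    converting crypt is still included and n3 + n5 >= 1.
    """

    n3: np.ndarray
    n5: np.ndarray
    n_nongenerating: int
    n_runs: int
    seed: int


@dataclass
class GrowthTimeSample:
    """Conditional first-passage times of the type-6 colony to detection size."""

    times: np.ndarray
    n_runs: int
    n_reached: int

    @property
    def survival_fraction(self) -> float:
        return self.n_reached / self.n_runs


def gillespie_run(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    t_max: float = 80.0,
    seed: int = 0,
    *,
    switch: ParameterSwitch | None = None,
    hybrid: bool = True,
    init_state=None,
) -> GillespieResult:
    """One exact stochastic run; terminates at detection or at ``t_max``."""
    if rates is None:
        rates = conversion_matrix(params)
    out = _run_batch(
        params, rates, 1, t_max, seed, switch=switch, hybrid=hybrid,
        init_state=init_state,
    )[0]
    det = float(out[0]) if out[0] >= 0 else None
    first6 = float(out[1]) if out[1] >= 0 else None
    return GillespieResult(
        detection_age=det,
        censor_age=t_max,
        first_type6_age=first6,
        n3_at_first_type6=int(out[2]) if first6 is not None else None,
        n5_at_first_type6=int(out[3]) if first6 is not None else None,
        final_state=tuple(int(v) for v in out[5:11]),
        seed=seed,
    )


def run_detection_ensemble(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    n_runs: int = 1000,
    t_max: float = 80.0,
    seed: int = 0,
    *,
    switch: ParameterSwitch | None = None,
    hybrid: bool = True,
    init_state=None,
) -> DetectionEnsemble:
    """Seeded ensemble of detection ages (NaN = censored at ``t_max``)."""
    if n_runs < 1:
        raise DomainError("n_runs must be >= 1")
    if rates is None:
        rates = conversion_matrix(params)
    out = _run_batch(
        params, rates, n_runs, t_max, seed, switch=switch, hybrid=hybrid,
        init_state=init_state,
    )
    det = np.where(out[:, 0] >= 0, out[:, 0], np.nan)
    return DetectionEnsemble(det, float(t_max), int(n_runs), int(seed))


def simulate_incidence(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    n_runs: int = 1000,
    t_max: float = 80.0,
    age_grid=None,
    seed: int = 0,
    *,
    switch: ParameterSwitch | None = None,
    hybrid: bool = True,
):
    """Simulated age-incidence curve with a Wilson binomial confidence band."""
    from statsmodels.stats.proportion import proportion_confint

    from .deterministic import IncidenceCurve

    ages = np.asarray(age_grid if age_grid is not None else np.arange(0, t_max + 1), float)
    ens = run_detection_ensemble(
        params, rates, n_runs, t_max, seed, switch=switch, hybrid=hybrid
    )
    counts = np.array([(ens.detected <= a).sum() for a in ages])
    frac = counts / n_runs
    lo, hi = proportion_confint(counts, n_runs, alpha=0.05, method="wilson")
    return IncidenceCurve(
        ages=ages,
        cumulative_incidence=frac,
        ci_low=np.asarray(lo, float),
        ci_high=np.asarray(hi, float),
        n_runs=n_runs,
    )


def counts_at_first_type6(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    n_runs: int = 1000,
    seed: int = 0,
    t_max: float = 80.0,
    *,
    hybrid: bool = True,
) -> FirstType6Counts:
    """Paired (n3, n5) at the first 3->6 or 5->6 conversion, per run.

    Runs in which no type-6 crypt is generated by ``t_max`` are excluded and
    counted in ``n_nongenerating``.
    """
    if n_runs < 1:
        raise DomainError("n_runs must be >= 1")
    if rates is None:
        rates = conversion_matrix(params)
    out = _run_batch(params, rates, n_runs, t_max, seed, hybrid=hybrid)
    got = out[:, 1] >= 0
    if not got.any():
        warnings.warn("no run generated a type-6 crypt; sample is empty")
    return FirstType6Counts(
        n3=out[got, 2].astype(int),
        n5=out[got, 3].astype(int),
        n_nongenerating=int((~got).sum()),
        n_runs=int(n_runs),
        seed=int(seed),
    )


def sample_type6_growth_times(
    gamma6: float,
    delta6: float,
    detection_size: int,
    n_runs: int = 10_000,
    seed: int = 0,
) -> GrowthTimeSample:
    """First-passage times of a linear birth-death colony from 1 to N.

    The colony has per-crypt birth rate ``gamma6`` and death rate ``delta6``.
    Only runs that reach ``detection_size`` (probability 1 - delta6/gamma6
    from a single founder) contribute times; extinct runs are dropped.

    Uses the embedded jump chain: with linear rates the jump probabilities
    are size-independent (p_up = gamma6/(gamma6+delta6)), so paths are simple
    random walks, and holding times are Exp((gamma6+delta6) * k).
    """
    if not gamma6 > delta6 or delta6 < 0:
        raise DomainError("need gamma6 > delta6 >= 0 (supercritical growth)")
    N = int(detection_size)
    if N < 2:
        raise DomainError("detection_size must be >= 2")
    if n_runs < 1:
        raise DomainError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    total = gamma6 + delta6
    p_up = gamma6 / total
    k = np.ones(n_runs, dtype=np.int64)
    t = np.zeros(n_runs)
    active = np.arange(n_runs)
    while active.size:
        ka = k[active]
        t[active] += rng.exponential(1.0, size=active.size) / (total * ka)
        step = np.where(rng.random(active.size) < p_up, 1, -1)
        k[active] = ka + step
        alive = (k[active] > 0) & (k[active] < N)
        active = active[alive]
    reached = k >= N
    return GrowthTimeSample(
        times=t[reached], n_runs=int(n_runs), n_reached=int(reached.sum())
    )
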