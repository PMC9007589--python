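"""Synthetic inputs with the statistical structure the analysis assumes.

The real input is a screening-study prevalence table: for each 5-year age bin
between 55 and 79, the fraction of an examined cohort found to carry an
advanced adenoma or CRC (cumulative, prevalence-style). The generator draws
``cases ~ Binomial(cohort_size, P(t_mid - DT))`` per bin from a known model
parameterisation, which makes fitting, model selection and relative-risk
estimation testable end to end without external downloads. A subject-level
trial generator wraps the detection ensembles into placebo/treated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deterministic import growth_delay_for, incidence_curve
from .model import ConversionMatrix, DomainError, ModelParams, conversion_matrix
from .stochastic import ParameterSwitch, run_detection_ensemble

__all__ = [
    "IncidenceTable",
    "TrialCohort",
    "DEFAULT_AGE_BINS",
    "generate_incidence_data",
    "exact_incidence_table",
    "generate_trial_cohorts",
]

#: The study's five 5-year age bins.
DEFAULT_AGE_BINS = ((55, 59), (60, 64), (65, 69), (70, 74), (75, 79))

_COLUMNS = ["age_lo", "age_hi", "cohort_size", "cases", "cumulative_incidence"]


@dataclass
class IncidenceTable:
    """Age-binned cumulative incidence observations.

    Columns: age_lo, age_hi, cohort_size, cases, cumulative_incidence, with
    cumulative_incidence = cases / cohort_size, non-overlapping ordered bins.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in _COLUMNS if c not in f.columns]
        if missing:
            raise DomainError(f"incidence table missing columns: {missing}")
        f = f[_COLUMNS].reset_index(drop=True)
        bad = f.index[f["cases"] > f["cohort_size"]].tolist()
        if bad:
            raise DomainError(f"cases exceed cohort_size in rows {bad}")
        if (f["cases"] < 0).any() or (f["cohort_size"] <= 0).any():
            raise DomainError("cases must be >= 0 and cohort sizes positive")
        if not (f["age_hi"] >= f["age_lo"]).all():
            raise DomainError("bins must satisfy age_lo <= age_hi")
        lo = f["age_lo"].to_numpy()
        hi = f["age_hi"].to_numpy()
        if len(f) > 1 and not np.all(lo[1:] > hi[:-1]):
            raise DomainError("age bins must be ordered and non-overlapping")
        ratio = f["cases"] / f["cohort_size"]
        if not np.allclose(ratio, f["cumulative_incidence"], atol=1e-9):
            rows = f.index[~np.isclose(ratio, f["cumulative_incidence"], atol=1e-9)]
            raise DomainError(
                f"cumulative_incidence != cases/cohort_size in rows {rows.tolist()}"
            )
        self.frame = f

    @property
    def midpoints(self) -> np.ndarray:
        return (self.frame["age_lo"].to_numpy() + self.frame["age_hi"].to_numpy() + 1) / 2.0

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path, **meta) -> None:
        from .io import write_csv_with_metadata

        write_csv_with_metadata(self.frame, path, **meta)


def generate_incidence_data(
    true_params: ModelParams,
    rates: ConversionMatrix | None = None,
    age_bins=DEFAULT_AGE_BINS,
    cohort_sizes=10_000,
    seed: int = 0,
) -> IncidenceTable:
    """Binomial-sampled incidence table from a known model parameterisation.

    Per bin, cases ~ Binomial(cohort_size, P(t_mid - DT)) with t_mid the bin
    midpoint. ``cohort_sizes`` may be a scalar or one count per bin.
    """
    if rates is None:
        rates = conversion_matrix(true_params)
    bins = [(int(lo), int(hi)) for lo, hi in age_bins]
    cohorts = np.broadcast_to(np.asarray(cohort_sizes, dtype=np.int64), (len(bins),))
    mids = np.array([(lo + hi + 1) / 2.0 for lo, hi in bins])
    delta_t = growth_delay_for(true_params)
    p = incidence_curve(true_params, rates, mids, delta_t=delta_t).cumulative_incidence
    rng = np.random.default_rng(seed)
    cases = rng.binomial(cohorts, p)
    frame = pd.DataFrame(
        {
            "age_lo": [lo for lo, _ in bins],
            "age_hi": [hi for _, hi in bins],
            "cohort_size": cohorts,
            "cases": cases,
            "cumulative_incidence": cases / cohorts,
        }
    )
    return IncidenceTable(frame)


def exact_incidence_table(
    true_params: ModelParams,
    rates: ConversionMatrix | None = None,
    age_bins=DEFAULT_AGE_BINS,
) -> IncidenceTable:
    """Noise-free table: observations equal the model curve (up to 1e-9,
    via a nominal cohort of 1e9 so the table invariants still hold)."""
    if rates is None:
        rates = conversion_matrix(true_params)
    bins = [(int(lo), int(hi)) for lo, hi in age_bins]
    mids = np.array([(lo + hi + 1) / 2.0 for lo, hi in bins])
    delta_t = growth_delay_for(true_params)
    p = incidence_curve(true_params, rates, mids, delta_t=delta_t).cumulative_incidence
    cohort = 10**9
    cases = np.rint(p * cohort).astype(np.int64)
    frame = pd.DataFrame(
        {
            "age_lo": [lo for lo, _ in bins],
            "age_hi": [hi for _, hi in bins],
            "cohort_size": cohort,
            "cases": cases,
            "cumulative_incidence": cases / cohort,
        }
    )
    return IncidenceTable(frame)


@dataclass
class TrialCohort:
    """Subject-level two-arm trial: placebo vs treated detection ages."""

    frame: pd.DataFrame  # subject_id, arm, detection_age (NaN censored), censored
    seed: int
    censor_age: float

    def relative_risk(self, assessment_age: float) -> float:
        f = self.frame
        det = f["detection_age"].fillna(np.inf) <= assessment_age
        p = det.groupby(f["arm"]).mean()
        if p.get("placebo", 0.0) == 0:
            raise ZeroDivisionError("no placebo detections by the assessment age")
        return float(p.get("treated", 0.0) / p["placebo"])

    def to_csv(self, path, **meta) -> None:
        from .io import write_csv_with_metadata

        write_csv_with_metadata(self.frame, path, seed=self.seed, **meta)


def generate_trial_cohorts(
    params: ModelParams,
    rates: ConversionMatrix | None = None,
    regimen=None,
    n_per_arm: int = 1000,
    seed: int = 0,
    t_max: float = 80.0,
    paired: bool = True,
) -> TrialCohort:
    """Placebo and treated arms under identical parameters except the regimen.

    With ``paired=True`` the arms share per-run seeds (common random numbers).
    """
    from .aspirin import apply_regimen

    if n_per_arm < 1:
        raise DomainError("n_per_arm must be >= 1")
    if regimen is None:
        raise DomainError("a regimen is required")
    if rates is None:
        rates = conversion_matrix(params)
    model = apply_regimen(params, rates, regimen)
    null_switch = ParameterSwitch(
        params=params, rates=rates, t_start=regimen.t_start, t_end=regimen.t_end
    )
    seed_placebo = seed if paired else seed + 1
    placebo = run_detection_ensemble(
        params, rates, n_per_arm, t_max, seed_placebo, switch=null_switch
    )
    treated = run_detection_ensemble(
        params, rates, n_per_arm, t_max, seed, switch=model.switch
    )
    frames = []
    for arm, ens in (("placebo", placebo), ("treated", treated)):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{arm[0]}{i:06d}" for i in range(n_per_arm)],
                    "arm": arm,
                    "detection_age": ens.detection_ages,
                    "censored": (~np.isfinite(ens.detection_ages)).astype(int),
                }
            )
        )
    return TrialCohort(
        frame=pd.concat(frames, ignore_index=True), seed=int(seed), censor_age=float(t_max)
    )
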