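"""Exact stochastic simulation: exactness, reproducibility, mean-field limit."""

import numpy as np
import pytest
from scipy import stats

import cryptevol as ce
from cryptevol.stochastic import _run_batch


class TestGillespieRun:
    def test_no_mutations_always_censored(self):
        p = ce.ModelParams(u=0.0, mu=0.0, n_crypt=1e6)
        res = ce.gillespie_run(p, t_max=80.0, seed=5)
        assert res.censored and res.detection_age is None
        assert res.final_state == (int(1e6), 0, 0, 0, 0, 0)

    def test_seeded_type6_detected_immediately(self):
        p = ce.ModelParams(detection_size=1)
        res = ce.gillespie_run(p, t_max=80.0, seed=5,
                               init_state=(int(p.n_crypt), 0, 0, 0, 0, 1))
        assert res.detection_age == 0.0

    def test_full_reproducibility(self, rr_params):
        rates = ce.conversion_matrix(rr_params)
        a = ce.run_detection_ensemble(rr_params, rates, 200, 80.0, seed=9)
        b = ce.run_detection_ensemble(rr_params, rates, 200, 80.0, seed=9)
        c = ce.run_detection_ensemble(rr_params, rates, 200, 80.0, seed=10)
        assert np.array_equal(a.detection_ages, b.detection_ages, equal_nan=True)
        assert not np.array_equal(a.detection_ages, c.detection_ages, equal_nan=True)

    def test_two_type_toy_is_exponential(self):
        """One conversion edge, no fission/death: the first conversion (and so
        detection at size 1) is exponential with rate R36 * n3."""
        n3, R36 = 200, 0.01
        p = ce.ModelParams(u=0.0, mu=0.0, n_crypt=0.0, detection_size=1,
                           gamma=(0, 0, 0, 0), delta=0.0, delta6=0.0)
        rates = ce.ConversionMatrix((0.0,) * 7).with_rates(R36=R36)
        ens = ce.run_detection_ensemble(
            p, rates, n_runs=10_000, t_max=1e4, seed=21,
            init_state=(0, 0, n3, 0, 0, 0),
        )
        ages = ens.detected
        assert ages.size == 10_000
        ks = stats.kstest(ages, "expon", args=(0.0, 1.0 / (R36 * n3)))
        assert ks.pvalue > 0.01

    def test_logistic_clamp_bounds_pool(self, rr_params):
        rates = ce.conversion_matrix(rr_params)
        out = _run_batch(rr_params, rates, 100, 80.0, seed=31)
        S = out[:, 7:10].sum(axis=1)  # final n3 + n4 + n5
        assert np.all(S <= max(rr_params.K_A, rr_params.K_R) + 10)

    def test_mean_field_agreement_in_low_noise_regime(self):
        """In the linear regime (no fission/death, plentiful conversions) the
        ensemble mean of every crypt count matches the ODE within 3 MC
        standard errors, in both hybrid and full modes."""
        p = ce.ModelParams(u=1e-4, mu=1e-6, n_crypt=1e4, gamma=(0, 0, 0, 0),
                           delta=0.0, delta6=0.0, detection_size=10**9)
        rates = ce.conversion_matrix(p)
        traj = ce.integrate_crypt_odes(p, rates, np.linspace(0, 60, 7))
        ode = traj.n[-1]
        for hybrid in (True, False):
            out = _run_batch(p, rates, 1000, 60.0, seed=13, hybrid=hybrid)
            for idx in (2, 3, 4):  # types 3, 4, 5
                vals = out[:, 5 + idx]
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                assert abs(vals.mean() - ode[idx]) <= 3 * se, (hybrid, idx)


class TestSimulateIncidence:
    def test_single_run_step_function(self):
        """One detected run: the empirical CDF is a 0 -> 1 step at its age."""
        p = ce.ModelParams(u=0.0, mu=0.0, n_crypt=0.0, detection_size=1,
                           gamma=(0, 0, 0, 0), delta=0.0, delta6=0.0)
        rates = ce.ConversionMatrix((0.0,) * 7).with_rates(R36=0.5)
        ens = ce.run_detection_ensemble(
            p, rates, n_runs=1, t_max=100.0, seed=2, init_state=(0, 0, 5, 0, 0, 0)
        )
        a = ens.detection_ages[0]
        assert np.isfinite(a) and a > 0
        assert ens.fraction_detected_by(a * 0.99) == 0.0
        assert ens.fraction_detected_by(a) == 1.0

    def test_no_mutations_flat_zero(self):
        p = ce.ModelParams(u=0.0, mu=0.0, n_crypt=1e5)
        curve = ce.simulate_incidence(p, n_runs=20, t_max=80.0, seed=2)
        assert np.all(curve.cumulative_incidence == 0.0)
        assert np.all(curve.ci_high >= curve.cumulative_incidence)

    def test_band_shrinks_with_run_count(self, rr_params):
        rates = ce.conversion_matrix(rr_params)
        widths = []
        for n_runs in (500, 2000):
            curve = ce.simulate_incidence(
                rr_params, rates, n_runs=n_runs, t_max=60.0,
                age_grid=np.array([40.0, 50.0, 60.0]), seed=4,
            )
            widths.append(np.mean(curve.ci_high - curve.ci_low))
        # quadrupling the runs should halve the Wilson band (binomial scaling)
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.25)


class TestCountsAtFirstType6:
    def test_no_paths_gives_empty_sample_with_warning(self):
        p = ce.ModelParams(u=1e-5, mu=1e-6, n_crypt=1e3)
        rates = ce.conversion_matrix(p).with_rates(R36=0.0, R56=0.0)
        with pytest.warns(UserWarning):
            counts = ce.counts_at_first_type6(p, rates, n_runs=20, seed=1, t_max=20.0)
        assert counts.n3.size == 0 and counts.n_nongenerating == 20

    def test_progenitor_counted_and_type3_dominates(self, rr_params):
        """With K_A >> K_R and dominant type-3 fission, the type-3 pool at the
        first type-6 event exceeds the type-5 pool (deterministic trajectory
        ordering under the same parameters), and the converting crypt itself
        is still in the recorded counts."""
        rates = ce.conversion_matrix(rr_params)
        counts = ce.counts_at_first_type6(rr_params, rates, n_runs=300, seed=17)
        assert counts.n3.size > 50
        assert np.all(counts.n3 + counts.n5 >= 1)
        assert np.median(counts.n3) > np.median(counts.n5)
        traj = ce.integrate_crypt_odes(rr_params, rates, np.linspace(0, 80, 9))
        assert traj.n[-1, 2] > traj.n[-1, 4]  # same ordering in the mean field


class TestGrowthTimeSampling:
    def test_single_step_mean(self):
        s = ce.sample_type6_growth_times(1.0, 0.0, 2, n_runs=20_000, seed=3)
        se = s.times.std(ddof=1) / np.sqrt(s.times.size)
        assert s.times.mean() == pytest.approx(1.0, abs=3 * se)
        assert s.survival_fraction == 1.0

    def test_survival_fraction_matches_branching_theory(self):
        gamma6, delta6 = 1.01, 0.05
        s = ce.sample_type6_growth_times(gamma6, delta6, 100, n_runs=20_000, seed=5)
        expected = 1.0 - delta6 / gamma6
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert s.survival_fraction == pytest.approx(expected, abs=3 * se)

    def test_agrees_with_expected_growth_delay(self):
        s = ce.sample_type6_growth_times(1.01, 0.05, 100, n_runs=20_000, seed=7)
        mean, se = ce.expected_growth_delay(
            1.01, 0.05, 100, method="simulation", n_reps=20_000, seed=8,
            return_se=True,
        )
        se_s = s.times.std(ddof=1) / np.sqrt(s.times.size)
        assert s.times.mean() == pytest.approx(mean, abs=3 * (se + se_s))

    def test_subcritical_rejected(self):
        with pytest.raises(ce.DomainError):
            ce.sample_type6_growth_times(0.5, 0.6, 10)


def test_detection_ensemble_csv_round_trip(tmp_path, rr_params):
    import pandas as pd

    rates = ce.conversion_matrix(rr_params)
    ens = ce.run_detection_ensemble(rr_params, rates, 50, 80.0, seed=23)
    path = tmp_path / "ens.csv"
    ens.to_csv(path)
    back = pd.read_csv(path, comment="#")
    assert list(back.columns) == ["run_id", "detection_age", "censored"]
    assert len(back) == 50
    assert back["censored"].sum() == np.isnan(ens.detection_ages).sum()
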