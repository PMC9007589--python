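"""Mean-field ODE system, growth delay, incidence curve, pathway split."""

import math

import numpy as np
import pytest

import cryptevol as ce
from cryptevol.deterministic import UndefinedProportionError


def zero_rates():
    return ce.ConversionMatrix((0.0,) * 7)


class TestOdeSystem:
    def test_all_rates_zero_is_frozen(self):
        p = ce.ModelParams(u=0.0, mu=0.0, gamma=(0, 0, 0, 0), delta=0.0, delta6=0.0)
        traj = ce.integrate_crypt_odes(p, zero_rates(), np.linspace(0, 80, 9))
        assert np.allclose(traj.n[:, 0], p.n_crypt)
        assert np.allclose(traj.n[:, 1:], 0.0)
        assert np.allclose(traj.p, 0.0)

    def test_closed_system_conserves_total(self, default_params):
        """With fission/death off and no outflow to type 6, the corrected flux
        form conserves the total crypt count."""
        p = default_params.replace(gamma=(0, 0, 0, 0), delta=0.0, delta6=0.0)
        rates = ce.conversion_matrix(p).with_rates(R36=0.0, R56=0.0)
        traj = ce.integrate_crypt_odes(p, rates, np.linspace(0, 80, 17))
        total = traj.n.sum(axis=1)
        assert np.all(np.abs(total / p.n_crypt - 1.0) < 1e-8)

    def test_printed_variant_violates_conservation(self, default_params):
        """The as-printed flux form loses crypts; kept only for comparison."""
        p = default_params.replace(gamma=(0, 0, 0, 0), delta=0.0, delta6=0.0)
        rates = ce.conversion_matrix(p).with_rates(R36=0.0, R56=0.0)
        traj = ce.integrate_crypt_odes(
            p, rates, np.linspace(0, 80, 17), printed_variant=True
        )
        total = traj.n.sum(axis=1)
        assert abs(total[-1] / p.n_crypt - 1.0) > 1e-6

    def test_linear_chain_closed_form(self):
        """n2(t) for the neutral no-fission model equals the two-compartment
        closed form n2 = R12 N (e^{-at} - e^{-bt}) / (b - a)."""
        p = ce.ModelParams(
            u=1e-7, mu=1e-9, fitness=(1.0,) * 6, n_sc=5, r1=10.0,
            n_crypt=1e7, gamma=(0, 0, 0, 0), delta=0.0, delta6=0.0,
        )
        rates = ce.conversion_matrix(p)
        R12, R23, R14, R25 = (rates[e] for e in [(1, 2), (2, 3), (1, 4), (2, 5)])
        a, b = R12 + R14, R23 + R25
        t = 50.0
        if abs(b - a) < 1e-18:
            # neutral rates make the chain degenerate: n2 = R12 N t e^{-at}
            expected = p.n_crypt * R12 * t * math.exp(-a * t)
        else:
            expected = p.n_crypt * R12 * (math.exp(-a * t) - math.exp(-b * t)) / (b - a)
        traj = ce.integrate_crypt_odes(p, rates, np.array([0.0, t]))
        assert traj.n[-1, 1] == pytest.approx(expected, rel=1e-7)

    def test_pathway_additivity_and_monotonicity(self, default_params, default_rates):
        traj = ce.integrate_crypt_odes(default_params, default_rates,
                                       np.linspace(0, 80, 161))
        assert np.max(np.abs(traj.p_apc + traj.p_kras - traj.p)) < 1e-8
        assert np.all(np.diff(traj.p) >= -1e-12)
        assert traj.p.min() >= 0.0 and traj.p.max() <= 1.0
        assert traj.n.min() >= 0.0

    def test_logistic_ceiling(self):
        """With conversions switched off after seeding and no crypt death, the
        mutated-crypt pool equilibrates at (or below) the larger capacity."""
        p = ce.ModelParams(
            u=0.0, mu=0.0, gamma=(0.4, 0.3, 0.3, 0.0), delta=0.0, delta6=0.0,
            K_A=500.0, K_R=300.0,
        )
        traj = ce.integrate_crypt_odes(
            p, zero_rates(), np.linspace(0, 200, 11),
            initial_counts=(0, 0, 10, 10, 10),
        )
        S = traj.n[:, 2:5].sum(axis=1)
        assert S[-1] <= max(p.K_A, p.K_R) + 1e-6
        assert S[-1] == pytest.approx(p.K_A, rel=1e-3)  # type 3 wins the pool

    def test_bad_grid_rejected(self, default_params, default_rates):
        with pytest.raises(ce.DomainError):
            ce.integrate_crypt_odes(default_params, default_rates, np.array([1.0, 2.0]))
        with pytest.raises(ce.DomainError):
            ce.integrate_crypt_odes(default_params, default_rates, np.array([0.0, 0.0]))


class TestGrowthDelay:
    def test_single_step_exact(self):
        """N = 2 with no death: a single exponential wait of mean 1/gamma6."""
        assert ce.expected_growth_delay(1.0, 0.0, 2, method="analytic") == 1.0
        mean, se = ce.expected_growth_delay(
            1.0, 0.0, 2, method="simulation", n_reps=20_000, seed=1, return_se=True
        )
        assert mean == pytest.approx(1.0, abs=3 * se)

    def test_yule_first_passage(self):
        """Pure birth to N = 100: mean is the harmonic number H_99."""
        H99 = sum(1.0 / k for k in range(1, 100))
        assert ce.expected_growth_delay(1.0, 0.0, 100, method="analytic") == (
            pytest.approx(H99, rel=1e-12)
        )
        mean, se = ce.expected_growth_delay(
            1.0, 0.0, 100, method="simulation", n_reps=20_000, seed=2, return_se=True
        )
        assert mean == pytest.approx(H99, abs=3 * se)
        assert H99 == pytest.approx(5.177, abs=1e-3)

    def test_simulation_reports_standard_error(self):
        mean, se = ce.expected_growth_delay(
            1.01, 0.05, 100, method="simulation", n_reps=5000, seed=3, return_se=True
        )
        assert se > 0.0 and mean > 0.0

    def test_subcritical_rejected(self):
        with pytest.raises(ce.DomainError):
            ce.expected_growth_delay(0.05, 1.01, 100)
        with pytest.raises(ce.DomainError):
            ce.expected_growth_delay(1.0, 1.0, 100)


class TestIncidenceCurve:
    def test_zero_before_delay_and_shift_bound(self, reduced_params):
        rates = ce.conversion_matrix(reduced_params)
        dt = 5.0
        ages = np.array([0.0, 2.0, 4.9, 20.0, 50.0, 80.0])
        curve = ce.incidence_curve(reduced_params, rates, ages, delta_t=dt)
        assert np.all(curve.cumulative_incidence[ages < dt] == 0.0)
        assert np.all(np.diff(curve.cumulative_incidence) >= -1e-12)
        # the shifted curve never exceeds the no-delay curve
        nodelay = ce.incidence_curve(reduced_params, rates, ages, delta_t=0.0)
        assert np.all(
            curve.cumulative_incidence <= nodelay.cumulative_incidence + 1e-12
        )

    def test_no_mutations_no_incidence(self):
        p = ce.ModelParams(u=0.0, mu=0.0)
        curve = ce.incidence_curve(p, zero_rates(), np.linspace(0, 80, 5), delta_t=5.0)
        assert np.all(curve.cumulative_incidence == 0.0)


class TestPathwayProportion:
    def test_pure_kras_path(self, default_params, default_rates):
        rates = default_rates.with_rates(R36=0.0)
        assert ce.pathway_proportion(default_params, rates, 80.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_pure_apc_path(self, default_params, default_rates):
        rates = default_rates.with_rates(R56=0.0)
        assert ce.pathway_proportion(default_params, rates, 80.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_symmetric_branches(self):
        """Equal rates on both branches, R45 = 0 and K_A = K_R, make n3 and n5
        exchangeable, so the APC path carries exactly half the probability."""
        p = ce.ModelParams(
            u=1e-5, mu=1e-5, fitness=(1.0,) * 6, n_sc=5, r1=10.0, n_crypt=1e5,
            gamma=(0.2, 0.0, 0.2, 1.01), K_A=500.0, K_R=500.0,
        )
        rates = ce.conversion_matrix(p).with_rates(R45=0.0, R14=0.0)
        assert ce.pathway_proportion(p, rates, 80.0) == pytest.approx(0.5, abs=1e-6)

    def test_undefined_when_both_paths_zero(self, default_params, default_rates):
        rates = default_rates.with_rates(R36=0.0, R56=0.0)
        with pytest.raises(UndefinedProportionError):
            ce.pathway_proportion(default_params, rates, 80.0)


def test_trajectory_csv_round_trip(tmp_path, reduced_params):
    import pandas as pd

    rates = ce.conversion_matrix(reduced_params)
    traj = ce.integrate_crypt_odes(reduced_params, rates, np.linspace(0, 80, 9))
    path = tmp_path / "traj.csv"
    traj.to_csv(path, params=reduced_params)
    back = pd.read_csv(path, comment="#")
    assert list(back.columns) == ["age", "n1", "n2", "n3", "n4", "n5",
                                  "P", "P_APC", "P_KRAS"]
    assert np.allclose(back["P"], traj.p)
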