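"""Estimators: exponential-CDF fit, velocity filters, displacement and
load statistics, effective rates, stiffness scaling."""

import math

import numpy as np
import pytest
from scipy import integrate

import kinesim as ks
from kinesim.analysis import effective_stepping_rate, sample_loads
from kinesim.engine import TrajectoryRecord


def _record(times, cargo, motor=None, run_length=None):
    times = np.asarray(times, float)
    cargo = np.asarray(cargo, float)
    motor = cargo.copy() if motor is None else np.asarray(motor, float)
    return TrajectoryRecord(
        seed=0, dt=1e-5, run_length=run_length or float(motor[-1] - motor[0]),
        duration=float(times[-1]), n_motor_steps=0, termination="detached",
        times=times, motor=motor, cargo=cargo)


class TestRunLengthFit:
    def test_recovers_exponential_parameters(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(1500.0, size=1000)
        est = ks.fit_run_length(x, n_boot=200, seed=1)
        assert est.l == pytest.approx(1500.0, rel=0.05)
        assert est.A == pytest.approx(1.0, rel=0.10)
        assert est.n == 1000

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(1.0, size=500)
        l1 = ks.fit_run_length(x, n_boot=10, seed=1).l
        l2 = ks.fit_run_length(1000.0 * x, n_boot=10, seed=1).l
        assert l2 == pytest.approx(1000.0 * l1, rel=1e-6)

    def test_bootstrap_sem_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1500.0, size=1600)
        sem_small = ks.fit_run_length(x[:100], n_boot=400, seed=1).sem
        sem_large = ks.fit_run_length(x, n_boot=400, seed=1).sem
        # 16x the data should shrink the SEM roughly 4-fold
        assert sem_large < sem_small / 2.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ks.InsufficientDataError):
            ks.fit_run_length([100.0] * 5)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ks.FitFailureError):
            ks.fit_run_length([800.0] * 50)

    def test_normalization_by_unloaded_run_length(self):
        est = ks.RunLengthEstimate(l=1500.0, A=1.0, sem=50.0, n=100)
        frac, sem = ks.normalized_run_length(est, 1500.0)
        assert (frac, sem) == (pytest.approx(1.0), pytest.approx(50 / 1500))
        assert ks.normalized_run_length(
            ks.RunLengthEstimate(1140.0, 1.0, 0.0, 10), 1500.0
        )[0] == pytest.approx(0.76)


class TestTrajectoryVelocity:
    def test_noiseless_trajectory_recovers_exact_slope(self):
        t = np.arange(0.0, 1.0, 1e-3)
        res = ks.trajectory_velocity(_record(t, 800.0 * t))
        assert res.accepted
        assert res.velocity == pytest.approx(800.0, rel=1e-9)

    def test_short_duration_rejected(self):
        t = np.arange(0.0, 0.1, 1e-3)
        res = ks.trajectory_velocity(_record(t, 800.0 * t))
        assert not res.accepted
        assert "duration" in res.reason

    def test_short_travel_rejected(self):
        t = np.arange(0.0, 1.0, 1e-3)
        res = ks.trajectory_velocity(_record(t, 50.0 * t))
        assert not res.accepted
        assert "displacement" in res.reason

    def test_ensemble_mean_velocity_with_bootstrap_sem(self):
        t = np.arange(0.0, 1.0, 1e-3)
        recs = [_record(t, v * t) for v in (700.0, 800.0, 900.0)]
        mean, sem, n = ks.ensemble_velocity(recs, n_boot=200, seed=1)
        assert n == 3
        assert mean == pytest.approx(800.0)
        assert sem > 0


class TestDisplacementStats:
    def test_probabilities_partition_the_samples(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0, 30, size=5000)
        st = ks.displacement_stats(d, 40.0)
        assert st.p_free + st.p_assisting + st.p_hindering == pytest.approx(1.0)
        assert st.n == 5000

    def test_all_samples_in_free_range_have_no_tails(self):
        st = ks.displacement_stats(np.linspace(-39, 39, 100), 40.0)
        assert st.p_assisting == 0.0 and st.p_hindering == 0.0
        assert st.mean_excursion_assisting == 0.0

    def test_known_mixture(self):
        d = np.array([0.0, 45.0, 50.0, -43.0])
        st = ks.displacement_stats(d, 40.0)
        assert st.p_assisting == pytest.approx(0.5)
        assert st.p_hindering == pytest.approx(0.25)
        assert st.mean_excursion_assisting == pytest.approx(7.5)
        assert st.mean_excursion_hindering == pytest.approx(3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ks.InsufficientDataError):
            ks.displacement_stats(np.array([]), 40.0)


class TestEffectiveRates:
    def test_free_range_samples_give_exactly_eps0(self, profile):
        d = np.linspace(-39, 39, 500)
        assert ks.effective_detachment_rate(d, profile, 0.32, 40.0) == \
            pytest.approx(profile.eps0, rel=1e-12)

    def test_never_below_unloaded_rate(self, profile):
        rng = np.random.default_rng(9)
        for _ in range(20):
            d = rng.normal(0, 50, size=200)
            assert ks.effective_detachment_rate(d, profile, 0.32, 40.0) >= \
                profile.eps0 * (1 - 1e-12)

    def test_boltzmann_weighted_rate_matches_quadrature(self, profile):
        """Against an independent quadrature of eps(F(x)) over the
        stationary density (flat inside the rest length, Gaussian beyond):
        the ratio to eps0 is ~1.18 at default stiffness."""
        kappa, L0, kBT = 0.32, 40.0, 4.11
        sigma = math.sqrt(kBT / kappa)

        def dens(x):
            if abs(x) <= L0:
                return 1.0
            return math.exp(-((abs(x) - L0) ** 2) / (2 * sigma ** 2))

        def integrand(x):
            return dens(x) * profile.rate(ks.tether_load_on_motor(x, kappa, L0))

        num, _ = integrate.quad(integrand, -L0 - 10 * sigma, L0 + 10 * sigma, limit=200)
        den, _ = integrate.quad(dens, -L0 - 10 * sigma, L0 + 10 * sigma, limit=200)
        expected = num / den
        assert expected / profile.eps0 == pytest.approx(1.18, abs=0.01)
        samples = ks.boltzmann_displacement_sample(400_000, seed=2)
        mc = ks.effective_detachment_rate(samples, profile, kappa, L0)
        assert mc == pytest.approx(expected, rel=0.01)

    def test_predicted_run_length_is_velocity_over_rate(self):
        assert ks.predicted_run_length(800.0, 800.0 / 1500.0) == pytest.approx(1500.0)
        assert ks.predicted_run_length(400.0, 800.0 / 1500.0) == pytest.approx(750.0)
        with pytest.raises(ks.InvalidParameterError):
            ks.predicted_run_length(800.0, 0.0)

    def test_stepping_rate_weighting_uses_only_hindering_tail(self, motor):
        # assisting side cannot exceed the unloaded stepping rate
        d = np.array([0.0, 50.0, 60.0])
        assert effective_stepping_rate(d, motor) == pytest.approx(motor.k0)
        d = np.array([-60.0])
        assert effective_stepping_rate(d, motor) < motor.k0


class TestLoadHistogram:
    def test_diffusion_free_loads_are_purely_hindering(self, motor, profile):
        fluid = ks.FluidCargo.from_water_multiple(50.0)
        cfg = ks.SimulationConfig(n_replicates=30, seed=13, diffusion=False,
                                  record_stride=100)
        recs = ks.simulate_ensemble(cfg, motor, fluid, profile)
        edges, freq = ks.load_histogram(recs, 0.05, motor)
        assert freq.sum() == pytest.approx(1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert freq[centers > 0.025].sum() == 0.0

    def test_empty_records_rejected(self, motor):
        with pytest.raises(ks.InsufficientDataError):
            ks.load_histogram([], 0.1, motor)

    def test_sample_loads_mirror_tether_law(self):
        d = np.array([45.0, 0.0, -50.0])
        np.testing.assert_allclose(sample_loads(d, 0.32, 40.0), [1.6, 0.0, -3.2])


class TestStiffnessScaling:
    def test_exact_square_root_law_gives_slope_half(self):
        k = np.logspace(-1.5, 0.5, 6)
        slope, _ = ks.stiffness_scaling_slope(k, 2.0 * np.sqrt(k))
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_boltzmann_conditional_mean_load_gives_slope_half(self):
        # closed form: mean load among load-bearing samples is
        # kappa * sigma * sqrt(2/pi) = sqrt(2 * kappa * kBT / pi)
        k = np.array([0.032, 0.1, 0.32, 1.0, 3.2])
        mean_loads = np.sqrt(2.0 * k * 4.11 / np.pi)
        slope, _ = ks.stiffness_scaling_slope(k, mean_loads)
        assert slope == pytest.approx(0.5, abs=1e-9)

    def test_requires_three_points_spanning_tenfold(self):
        with pytest.raises(ks.InsufficientDataError):
            ks.stiffness_scaling_slope([0.1, 0.2], [1.0, 1.4])
        with pytest.raises(ks.InsufficientDataError):
            ks.stiffness_scaling_slope([0.1, 0.2, 0.4], [1.0, 1.4, 2.0])
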