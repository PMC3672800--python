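"""System identification: RMS error, pole recovery, response metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rigidnet import simulate, tracking
from rigidnet.simulate import TrackingSimSpec
from rigidnet.tracking import (
    DegeneratePolesError,
    InvalidTrialError,
    TrackingTrial,
    UnidentifiableInputError,
    aggregate_subject_metrics,
    compare_rms_groups,
    discrete_to_continuous_poles,
    fit_lds,
    poles_to_metrics,
    rms_error,
    trial_metrics,
)


def make_trial(u, y, dt=0.02):
    u = np.asarray(u, dtype=float)
    return TrackingTrial(time=np.arange(len(u)) * dt, u=u, y=np.asarray(y, float), dt=dt)


class TestRMSError:
    def test_perfect_tracking_is_zero(self):
        u = np.sin(np.linspace(0, 10, 100))
        assert rms_error(make_trial(u, u)) == 0.0

    def test_constant_offset(self):
        assert rms_error(make_trial(np.zeros(50), np.ones(50))) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # padded with identical-error triples so N >= 20 leaves the mean unchanged
        u = np.tile([0.0, 1.0, 2.0], 7)
        y = np.ones(21)
        assert rms_error(make_trial(u, y)) == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidTrialError):
            TrackingTrial(time=np.arange(30) * 0.02, u=np.zeros(30), y=np.zeros(29), dt=0.02)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(0)
        u = rng.normal(size=40)
        y = rng.normal(size=40)
        base = rms_error(make_trial(u, y))
        assert rms_error(make_trial(u + shift, y + shift)) == pytest.approx(base, rel=1e-9)
        assert rms_error(make_trial(u * scale, y * scale)) == pytest.approx(
            scale * base, rel=1e-9
        )


class TestFitLDS:
    @pytest.mark.parametrize("zeta", [0.3, 0.7, 1.0, 1.5])
    @pytest.mark.parametrize("omega_n", [1.0, 3.0, 6.0])
    def test_noise_free_parameter_recovery(self, zeta, omega_n):
        """Noise-free simulated trials return the generating (zeta, omega_n)."""
        trial = simulate.simulate_tracking_trial(
            TrackingSimSpec(zeta=zeta, omega_n=omega_n)
        )
        m = trial_metrics(trial)
        assert m.zeta == pytest.approx(zeta, abs=1e-4)
        assert m.omega_n == pytest.approx(omega_n, abs=1e-4)

    def test_noise_free_poles_match_discretized_generator(self):
        zeta, omega_n = 0.7, 3.0
        trial = simulate.simulate_tracking_trial(TrackingSimSpec(zeta=zeta, omega_n=omega_n))
        model = fit_lds(trial, method="arx")
        wd = omega_n * math.sqrt(1 - zeta**2)
        s_true = np.array([complex(-zeta * omega_n, wd), complex(-zeta * omega_n, -wd)])
        lam_true = np.exp(s_true * trial.dt)
        fitted = np.sort_complex(model.eigenvalues)
        assert np.allclose(fitted, np.sort_complex(lam_true), atol=1e-6)

    def test_zero_response_gives_zero_gain(self):
        u = simulate.generate_target_trajectory(TrackingSimSpec(zeta=0.7, omega_n=3.0))
        model = fit_lds(make_trial(u, np.zeros_like(u)))
        assert abs(model.dc_gain()) < 1e-8

    def test_constant_input_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(UnidentifiableInputError):
            fit_lds(make_trial(np.full(200, 10.0), rng.normal(size=200)))

    def test_noisy_recovery_is_accurate(self):
        """Median |zeta_hat - zeta| stays small under 5%-of-range output noise."""
        errs = []
        for seed in range(30):
            trial = simulate.simulate_tracking_trial(
                TrackingSimSpec(zeta=0.7, omega_n=3.0, noise_sd=0.5, seed=seed)
            )
            errs.append(abs(trial_metrics(trial).zeta - 0.7))
        assert np.median(errs) < 0.05


class TestPoleMapping:
    def test_real_scalar_log(self):
        s = discrete_to_continuous_poles([math.exp(-0.5 * 0.02)], dt=0.02)
        assert s[0] == pytest.approx(-0.5)

    def test_conjugate_pair(self):
        lam = np.exp(np.array([-1 + 2j, -1 - 2j]) * 0.02)
        s = discrete_to_continuous_poles(lam, dt=0.02)
        assert np.allclose(np.sort_complex(s), np.sort_complex([-1 + 2j, -1 - 2j]))

    def test_round_trip_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            zeta = rng.uniform(0.05, 2.0)
            omega = rng.uniform(0.3, 20.0)
            if zeta < 1:
                s = complex(-zeta * omega, omega * math.sqrt(1 - zeta**2))
                poles = np.array([s, s.conjugate()])
            else:
                r = omega * math.sqrt(zeta**2 - 1)
                poles = np.array([-zeta * omega + r, -zeta * omega - r], dtype=complex)
            lam = np.exp(poles * 0.02)
            back = discrete_to_continuous_poles(lam, dt=0.02)
            assert np.allclose(np.exp(back * 0.02), lam, atol=1e-12)
            assert np.allclose(np.sort_complex(back), np.sort_complex(poles), atol=1e-9)

    def test_negative_real_eigenvalue_flagged(self):
        with pytest.raises(DegeneratePolesError):
            discrete_to_continuous_poles([-0.5, 0.9], dt=0.02)


class TestResponseMetrics:
    def test_critical_damping(self):
        m = poles_to_metrics(np.array([-3.0, -3.0], dtype=complex))
        assert m.zeta == pytest.approx(1.0)
        assert m.classification == "critically_damped"
        assert m.peak_time is None

    def test_zero_damping(self):
        m = poles_to_metrics(np.array([3j, -3j]))
        assert m.zeta == pytest.approx(0.0, abs=1e-12)
        assert m.omega_n == pytest.approx(3.0)
        assert math.isinf(m.settling_time)

    def test_peak_time_closed_form_vs_simulation(self):
        """zeta=0.5, omega_n=2: peak at pi/(2 sqrt(0.75)), and the simulated
        step response peaks there too."""
        zeta, omega_n = 0.5, 2.0
        wd = omega_n * math.sqrt(1 - zeta**2)
        m = poles_to_metrics(np.array([complex(-zeta * omega_n, wd), complex(-zeta * omega_n, -wd)]))
        expected = math.pi / (2.0 * math.sqrt(0.75))
        assert m.peak_time == pytest.approx(expected, rel=1e-12)
        # brute-force step response of the same system
        dt = 0.001
        model = simulate.second_order_discrete(zeta, omega_n, dt)
        y = model.simulate(np.ones(8000))
        assert int(np.argmax(y)) * dt == pytest.approx(expected, abs=2 * dt)

    def test_settling_time_approximation(self):
        m = poles_to_metrics(np.array([-1.4 + 1.43j, -1.4 - 1.43j]))
        assert m.settling_time == pytest.approx(4.0 / 1.4, rel=1e-6)
        # simulated 2% crossing is within ~40% of the band approximation
        assert m.settling_time_simulated == pytest.approx(m.settling_time, rel=0.4)

    def test_unstable_poles_still_reported(self):
        m = poles_to_metrics(np.array([0.5 + 2j, 0.5 - 2j]))
        assert not m.stable
        assert m.zeta < 0

    def test_full_round_trip_precision(self):
        """discretize -> log -> metrics reproduces (zeta, omega_n) to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            zeta = rng.uniform(0.05, 2.5)
            omega = rng.uniform(0.2, 30.0)
            if abs(zeta - 1) < 1e-3:
                continue
            if zeta < 1:
                s = complex(-zeta * omega, omega * math.sqrt(1 - zeta**2))
                poles = np.array([s, s.conjugate()])
            else:
                r = omega * math.sqrt(zeta**2 - 1)
                poles = np.array([-zeta * omega + r, -zeta * omega - r], dtype=complex)
            back = discrete_to_continuous_poles(np.exp(poles * 0.02), dt=0.02)
            m = poles_to_metrics(back)
            assert m.zeta == pytest.approx(zeta, abs=1e-10)
            assert m.omega_n == pytest.approx(omega, abs=1e-10 * max(1, omega))


class TestAggregation:
    def run_metric(self, zeta, omega_n=3.0):
        wd = omega_n * math.sqrt(abs(1 - zeta**2))
        if zeta < 1:
            s = np.array([complex(-zeta * omega_n, wd), complex(-zeta * omega_n, -wd)])
        else:
            s = np.array([-zeta * omega_n + wd, -zeta * omega_n - wd], dtype=complex)
        return poles_to_metrics(s)

    def test_single_run_identity(self):
        m = self.run_metric(0.6)
        agg = aggregate_subject_metrics([m])
        assert agg.zeta == pytest.approx(0.6)

    def test_mean_of_two_runs(self):
        agg = aggregate_subject_metrics([self.run_metric(0.4), self.run_metric(0.6)])
        assert agg.zeta == pytest.approx(0.5)

    def test_median_resists_outlier_run(self):
        runs = [self.run_metric(z) for z in (0.4, 0.5, 5.0)]
        agg = aggregate_subject_metrics(runs, aggregator="median")
        assert agg.zeta == pytest.approx(0.5)

    def test_all_degenerate_rejected(self):
        from rigidnet.tracking import ResponseMetrics

        deg = ResponseMetrics(
            zeta=math.nan,
            omega_n=math.nan,
            rise_time=math.nan,
            peak_time=None,
            settling_time=math.nan,
            classification="degenerate",
        )
        with pytest.raises(ValueError):
            aggregate_subject_metrics([deg])


class TestRMSGroupComparison:
    def test_identical_groups_not_significant(self):
        vals = np.tile(np.arange(10.0), 2)
        labels = ["a"] * 10 + ["b"] * 10
        f, p = compare_rms_groups(vals, labels)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        _, p = compare_rms_groups(vals, labels)
        assert p < 1e-3

    def test_type_one_error_calibration(self):
        """Three null groups: ~5% of replicates reject at alpha = 0.05."""
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 600
        labels = np.repeat(["a", "b", "c"], 15)
        for _ in range(reps):
            vals = rng.normal(size=45)
            _, p = compare_rms_groups(vals, labels)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            compare_rms_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
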