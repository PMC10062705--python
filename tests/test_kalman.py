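"""Constant-velocity Kalman filter: oracles and invariants.

The reference oracle used here is an independent textbook implementation
built from explicit transition/observation matrices and `np.linalg.inv`,
sharing no code with the package's filter.
"""

import numpy as np
import pytest

from budcount.kalman import KalmanState, NoiseModel, init_state, predict, update


class ReferenceKF:
    """Plain textbook linear Kalman filter (independent oracle)."""

    def __init__(self, noise: NoiseModel):
        self.noise = noise
        self.F = np.eye(8)
        for i in range(4):
            self.F[i, i + 4] = 1.0
        self.H = np.hstack([np.eye(4), np.zeros((4, 4))])

    def predict(self, mean, cov):
        Q = np.diag(self.noise.process_std(mean[3]) ** 2)
        return self.F @ mean, self.F @ cov @ self.F.T + Q

    def update(self, mean, cov, z):
        R = np.diag(self.noise.measurement_std(mean[3]) ** 2)
        S = self.H @ cov @ self.H.T + R
        K = cov @ self.H.T @ np.linalg.inv(S)
        mean2 = mean + K @ (z - self.H @ mean)
        cov2 = (np.eye(8) - K @ self.H) @ cov
        return mean2, cov2


class TestInit:
    def test_mean_is_measurement_with_zero_velocity(self):
        s = init_state(np.array([5.0, 10.0, 0.5, 20.0]))
        assert s.mean == pytest.approx([5, 10, 0.5, 20, 0, 0, 0, 0])

    def test_covariance_diagonal_with_inflated_velocities(self):
        s = init_state(np.array([5.0, 10.0, 0.5, 20.0]))
        off_diag = s.covariance - np.diag(np.diag(s.covariance))
        assert np.all(off_diag == 0)
        # velocity uncertainty exceeds position uncertainty at birth
        assert s.covariance[4, 4] > 0 and s.covariance[5, 5] > 0

    def test_deterministic(self):
        m = np.array([1.0, 2.0, 0.8, 30.0])
        a, b = init_state(m), init_state(m)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.covariance, b.covariance)

    def test_non_finite_measurement_rejected(self):
        with pytest.raises(ValueError):
            init_state(np.array([1.0, np.nan, 0.5, 20.0]))


class TestPredict:
    def test_zero_velocity_keeps_position(self):
        s = init_state(np.array([50.0, 60.0, 0.7, 30.0]))
        p = predict(s)
        assert p.mean[:4] == pytest.approx(s.mean[:4])

    def test_matches_explicit_matrix_product(self):
        mean = np.array([100.0, 100.0, 0.5, 40.0, 2.0, -1.0, 0.0, 0.5])
        cov = np.diag(np.arange(1.0, 9.0))
        s = KalmanState(mean, cov)
        p = predict(s)
        assert p.mean[0] == pytest.approx(102.0)
        assert p.mean[1] == pytest.approx(99.0)
        F = np.eye(8)
        F[:4, 4:] = np.eye(4)
        ref_cov = F @ cov @ F.T + np.diag(NoiseModel().process_std(40.0) ** 2)
        assert p.mean == pytest.approx(F @ mean)
        assert p.covariance == pytest.approx(ref_cov)

    def test_uncertainty_grows(self):
        s = init_state(np.array([50.0, 60.0, 0.7, 30.0]))
        assert np.trace(predict(s).covariance) > np.trace(s.covariance)


class TestUpdate:
    def test_zero_innovation_keeps_position(self):
        s = predict(init_state(np.array([50.0, 60.0, 0.7, 30.0])))
        u = update(s, s.measurement)
        assert u.mean[:4] == pytest.approx(s.mean[:4])

    def test_scalar_kalman_oracle(self):
        """Equal prior and measurement variance -> posterior mean halfway.

        With h = 20 and position_scale = 1/20 the measurement variance of cx
        is exactly 1; a prior (mean 0, var 1) observed at 1 must yield the
        1-D closed-form posterior mean 0.5 and variance 0.5.
        """
        noise = NoiseModel(position_scale=1.0 / 20.0)
        mean = np.array([0.0, 7.0, 1.0, 20.0, 0, 0, 0, 0])
        cov = np.diag([1.0, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12])
        u = update(KalmanState(mean, cov), np.array([1.0, 7.0, 1.0, 20.0]), noise)
        assert u.mean[0] == pytest.approx(0.5, abs=1e-9)
        assert u.covariance[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_posterior_variance_never_exceeds_prior(self):
        s = predict(init_state(np.array([50.0, 60.0, 0.7, 30.0])))
        u = update(s, np.array([55.0, 58.0, 0.8, 32.0]))
        prior_var = np.diag(s.covariance)
        post_var = np.diag(u.covariance)
        assert np.all(post_var <= prior_var + 1e-12)


class TestFilterBehaviour:
    def test_locks_onto_constant_velocity_track(self):
        """After 5 predict/update cycles the one-step-ahead prediction is
        within 1 px of the true center on a noiseless linear track."""
        v = np.array([3.0, 2.0])
        center = np.array([100.0, 120.0])
        s = init_state(np.array([*center, 0.6, 50.0]))
        for _ in range(5):
            center = center + v
            s = predict(s)
            s = update(s, np.array([*center, 0.6, 50.0]))
        pred = predict(s)
        assert np.abs(pred.mean[:2] - (center + v)).max() < 1.0

    def test_fuzz_stays_finite(self, rng):
        for _ in range(30):
            s = init_state(np.array([*rng.uniform(10, 900, 2), rng.uniform(0.3, 2), rng.uniform(10, 100)]))
            for _ in range(20):
                s = predict(s)
                if rng.random() < 0.7:
                    z = s.measurement + rng.normal(0, 3, 4)
                    z[2] = abs(z[2]) + 0.05
                    z[3] = abs(z[3]) + 1.0
                    s = update(s, z)
                assert np.all(np.isfinite(s.mean))
                assert np.all(np.isfinite(s.covariance))
                cov = s.covariance
                assert np.allclose(cov, cov.T, atol=1e-9)
                assert np.linalg.eigvalsh(cov).min() > -1e-9

    def test_matches_reference_implementation(self, rng):
        """Filter agrees with the independent textbook oracle on 50 random
        predict/update sequences to 1e-6."""
        noise = NoiseModel()
        ref = ReferenceKF(noise)
        for _ in range(50):
            z0 = np.array([*rng.uniform(50, 900, 2), rng.uniform(0.3, 2), rng.uniform(20, 80)])
            s = init_state(z0, noise)
            mean, cov = s.mean.copy(), s.covariance.copy()
            for _ in range(rng.integers(3, 12)):
                s = predict(s, noise)
                mean, cov = ref.predict(mean, cov)
                z = s.measurement + rng.normal(0, 2, 4)
                z[2], z[3] = abs(z[2]) + 0.05, abs(z[3]) + 1.0
                s = update(s, z, noise)
                mean, cov = ref.update(mean, cov, z)
            assert np.allclose(s.mean, mean, atol=1e-6)
            assert np.allclose(s.covariance, cov, atol=1e-6)
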