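"""Constant-velocity linear Kalman filter for bounding-box state estimation.

The state is the 8-vector ``(cx, cy, a, h, v_cx, v_cy, v_a, v_h)``: box
center, aspect ratio, height, and their per-frame velocities.  Motion is
assumed linear — between consecutive frames each position component advances
by its velocity times one frame — which is a good approximation for a camera
advancing at uniform walking speed over a high-frame-rate video.  The
observation is the measured box ``(cx, cy, a, h)``.

Process and measurement noise standard deviations scale with the box height,
so that near (large) and far (small) objects are filtered with comparable
relative uncertainty.  The aspect-ratio components carry a small fixed noise
floor instead, since aspect ratio is dimensionless and roughly
scale-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KalmanState", "NoiseModel", "init_state", "predict", "update"]

_DIM = 8
_NDIM_MEAS = 4

# Constant-velocity transition: position components advance by velocity * 1 frame.
_F = np.eye(_DIM)
_F[:_NDIM_MEAS, _NDIM_MEAS:] = np.eye(_NDIM_MEAS)

# Observation selects (cx, cy, a, h).
_H = np.eye(_NDIM_MEAS, _DIM)

# Numerical floors keeping the box geometry valid: a long-coasting track
# whose size velocity went negative would otherwise predict its aspect or
# height through zero.
_MIN_ASPECT = 1e-3
_MIN_HEIGHT = 1.0


def _clamp_shape(mean: np.ndarray) -> np.ndarray:
    if mean[2] < _MIN_ASPECT:
        mean[2], mean[6] = _MIN_ASPECT, 0.0
    if mean[3] < _MIN_HEIGHT:
        mean[3], mean[7] = _MIN_HEIGHT, 0.0
    return mean


@dataclass(frozen=True)
class NoiseModel:
    """Height-scaled noise magnitudes for the filter.

    ``position_scale`` multiplies the box height to give the standard
    deviation of position-like components (center, height); ``velocity_scale``
    does the same for their velocities.  ``aspect_sigma`` / ``aspect_vel_sigma``
    are fixed floors for the dimensionless aspect-ratio components, keeping
    their covariance from collapsing to exact zero.
    """

    position_scale: float = 1.0 / 20.0
    # Faster velocity adaptation than the pedestrian-tracking convention:
    # the scene flow of a steadily advancing camera is fast (~10 px/frame)
    # and genuinely constant, so the filter should lock onto it quickly.
    velocity_scale: float = 1.0 / 80.0
    aspect_sigma: float = 1e-2
    aspect_vel_sigma: float = 1e-5

    def __post_init__(self) -> None:
        if self.position_scale <= 0 or self.velocity_scale <= 0:
            raise ValueError("noise scales must be positive")

    def process_std(self, h: float) -> np.ndarray:
        return np.array(
            [
                self.position_scale * h,
                self.position_scale * h,
                self.aspect_sigma,
                self.position_scale * h,
                self.velocity_scale * h,
                self.velocity_scale * h,
                self.aspect_vel_sigma,
                self.velocity_scale * h,
            ]
        )

    def measurement_std(self, h: float) -> np.ndarray:
        return np.array(
            [
                self.position_scale * h,
                self.position_scale * h,
                self.aspect_sigma,
                self.position_scale * h,
            ]
        )


@dataclass(frozen=True)
class KalmanState:
    """Gaussian belief over the 8-D box state: mean vector and covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != (_DIM,) or self.covariance.shape != (_DIM, _DIM):
            raise ValueError("state must be an 8-vector with an 8x8 covariance")

    @property
    def measurement(self) -> np.ndarray:
        """The (cx, cy, a, h) the state projects to."""
        return self.mean[:_NDIM_MEAS].copy()


def init_state(m: np.ndarray, noise: NoiseModel | None = None) -> KalmanState:
    """Create a track-birth state from a first measurement.

    The positional part of the mean is the measurement itself; velocities
    start at zero.  The covariance is diagonal with velocity variances
    inflated relative to position variances, reflecting that the first
    observation says nothing about motion.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (_NDIM_MEAS,) or not np.all(np.isfinite(m)):
        raise ValueError(f"measurement must be a finite 4-vector, got {m!r}")
    noise = noise or NoiseModel()
    h = m[3]
    std = np.array(
        [
            2 * noise.position_scale * h,
            2 * noise.position_scale * h,
            noise.aspect_sigma,
            2 * noise.position_scale * h,
            10 * noise.velocity_scale * h,
            10 * noise.velocity_scale * h,
            noise.aspect_vel_sigma,
            10 * noise.velocity_scale * h,
        ]
    )
    mean = np.concatenate([m, np.zeros(_NDIM_MEAS)])
    return KalmanState(mean=mean, covariance=np.diag(std**2))


def predict(s: KalmanState, noise: NoiseModel | None = None) -> KalmanState:
    """Advance the belief one frame under the constant-velocity model."""
    noise = noise or NoiseModel()
    q_std = noise.process_std(s.mean[3])
    mean = _clamp_shape(_F @ s.mean)
    cov = _F @ s.covariance @ _F.T + np.diag(q_std**2)
    return KalmanState(mean=mean, covariance=cov)


def update(s: KalmanState, m: np.ndarray, noise: NoiseModel | None = None) -> KalmanState:
    """Condition the belief on an observed box measurement.

    Standard linear Kalman update; the posterior covariance never exceeds the
    prior in the positive-semidefinite order.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (_NDIM_MEAS,) or not np.all(np.isfinite(m)):
        raise ValueError(f"measurement must be a finite 4-vector, got {m!r}")
    noise = noise or NoiseModel()
    r = np.diag(noise.measurement_std(s.mean[3]) ** 2)

    proj_mean = _H @ s.mean
    proj_cov = _H @ s.covariance @ _H.T + r
    try:
        # Kalman gain K = P Hᵀ S⁻¹ via a solve against the innovation covariance.
        gain = np.linalg.solve(proj_cov.T, (s.covariance @ _H.T).T).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - positive R prevents this
        raise ArithmeticError("singular innovation covariance") from exc

    innovation = m - proj_mean
    mean = _clamp_shape(s.mean + gain @ innovation)
    cov = s.covariance - gain @ proj_cov @ gain.T
    # Symmetrise to remove floating-point drift.
    cov = 0.5 * (cov + cov.T)
    return KalmanState(mean=mean, covariance=cov)
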