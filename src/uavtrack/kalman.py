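"""Constant-velocity Kalman filter over bounding-box states.

The state of one tracked animal is the 8-vector

    (x, y, gamma, h, vx, vy, vgamma, vh)

where ``(x, y)`` is the box centre in pixels, ``gamma`` the aspect ratio
(width / height), ``h`` the box height in pixels, and the last four
components the per-frame velocities of the first four.  The motion model
is uniform (constant velocity, dt = one frame); the observation model is
linear and observes the first four components.

Process and measurement noise follow the Deep SORT convention: standard
deviations of the position/size components are proportional to the current
box height ``h`` (weight ``std_weight_position``), velocity components use
``std_weight_velocity``; the dimensionless aspect-ratio component gets
small fixed standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "TrackState",
    "Measurement",
    "NoiseConfig",
    "ObservationModel",
    "InvalidMeasurementError",
    "FilterNumericalError",
    "initiate",
    "predict",
    "project",
    "update",
]

STATE_DIM = 8
MEAS_DIM = 4


class InvalidMeasurementError(ValueError):
    """A measurement violates its invariants (non-positive h or gamma)."""


class FilterNumericalError(RuntimeError):
    """A linear solve inside the filter failed (singular innovation)."""


@dataclass
class TrackState:
    """Gaussian belief over one target's 8-D state."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(STATE_DIM)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(
            STATE_DIM, STATE_DIM
        )


@dataclass
class Measurement:
    """A detection in measurement space: (x, y, gamma, h)."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).reshape(MEAS_DIM)
        x, y, gamma, h = self.vector
        if not (h > 0):
            raise InvalidMeasurementError(f"box height must be positive, got {h}")
        if not (gamma > 0):
            raise InvalidMeasurementError(f"aspect ratio must be positive, got {gamma}")


@dataclass
class NoiseConfig:
    """Scale weights for the height-proportional noise model."""

    std_weight_position: float = 1.0 / 20.0
    std_weight_velocity: float = 1.0 / 160.0

    def __post_init__(self) -> None:
        if self.std_weight_position <= 0 or self.std_weight_velocity <= 0:
            raise ValueError("noise weights must be strictly positive")


def _default_obs_matrix() -> np.ndarray:
    return np.eye(MEAS_DIM, STATE_DIM)


@dataclass
class ObservationModel:
    """Linear selector H mapping state space to measurement space."""

    matrix: np.ndarray = field(default_factory=_default_obs_matrix)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(MEAS_DIM, STATE_DIM)


def _transition_matrix() -> np.ndarray:
    F = np.eye(STATE_DIM)
    F[:MEAS_DIM, MEAS_DIM:] = np.eye(MEAS_DIM)
    return F


def process_noise(h: float, noise: NoiseConfig) -> np.ndarray:
    """Diagonal process-noise covariance Q for a state with box height h."""
    wp, wv = noise.std_weight_position, noise.std_weight_velocity
    std = [wp * h, wp * h, 1e-2, wp * h, wv * h, wv * h, 1e-5, wv * h]
    return np.diag(np.square(std))


def measurement_noise(h: float, noise: NoiseConfig) -> np.ndarray:
    """Diagonal measurement-noise covariance R for box height h."""
    wp = noise.std_weight_position
    std = [wp * h, wp * h, 1e-1, wp * h]
    return np.diag(np.square(std))


def symmetrize(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def initiate(measurement: Measurement, noise: NoiseConfig) -> TrackState:
    """Start a new track from an unassociated measurement.

    Velocities start at zero; the initial covariance is diagonal with
    generous (doubled position / 10x velocity) height-scaled stds,
    reflecting that velocity is entirely unobserved at birth.
    """
    z = measurement.vector
    mean = np.zeros(STATE_DIM)
    mean[:MEAS_DIM] = z
    h = z[3]
    wp, wv = noise.std_weight_position, noise.std_weight_velocity
    std = [
        2 * wp * h,
        2 * wp * h,
        1e-2,
        2 * wp * h,
        10 * wv * h,
        10 * wv * h,
        1e-5,
        10 * wv * h,
    ]
    return TrackState(mean=mean, covariance=np.diag(np.square(std)))


def predict(state: TrackState, noise: NoiseConfig) -> TrackState:
    """One constant-velocity prediction step (dt = 1 frame)."""
    F = _transition_matrix()
    Q = process_noise(state.mean[3], noise)
    mean = F @ state.mean
    cov = symmetrize(F @ state.covariance @ F.T + Q)
    return TrackState(mean=mean, covariance=cov)


def project(
    state: TrackState,
    noise: NoiseConfig,
    obs: ObservationModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the state distribution into measurement space.

    Returns ``(H mean, H P H^T + R)`` — the predicted measurement and its
    innovation covariance, consumed by the Mahalanobis association cost.
    """
    H = (obs or ObservationModel()).matrix
    R = measurement_noise(state.mean[3], noise)
    mean = H @ state.mean
    cov = symmetrize(H @ state.covariance @ H.T + R)
    return mean, cov


def update(
    state: TrackState,
    measurement: Measurement,
    noise: NoiseConfig,
    obs: ObservationModel | None = None,
) -> TrackState:
    """Kalman measurement update.

    Computes the gain K = P H^T (H P H^T + R)^-1, corrects the mean by the
    gained residual, and contracts the covariance as (I - K H) P.

    Raises
    ------
    FilterNumericalError
        If the innovation covariance is singular (Cholesky fails).
    """
    H = (obs or ObservationModel()).matrix
    proj_mean, proj_cov = project(state, noise, obs)
    try:
        chol = scipy.linalg.cho_factor(proj_cov, lower=True, check_finite=False)
        # K^T solved from S K^T = H P, i.e. K = P H^T S^-1
        gain = scipy.linalg.cho_solve(
            chol, (state.covariance @ H.T).T, check_finite=False
        ).T
    except scipy.linalg.LinAlgError as exc:
        raise FilterNumericalError(
            f"singular innovation covariance during update: {exc}"
        ) from exc
    residual = measurement.vector - proj_mean
    mean = state.mean + gain @ residual
    cov = (np.eye(STATE_DIM) - gain @ H) @ state.covariance
    return TrackState(mean=mean, covariance=symmetrize(cov))
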