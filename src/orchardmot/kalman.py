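"""Adaptive fading-memory Kalman filter for bounding-box tracking.

The filter estimates an 8-dimensional constant-velocity state
``X = (x, y, w, h, vx, vy, vw, vh)`` (center position, box size, and their
per-frame velocities, all in pixels).  On top of the textbook
predict/update recursion it carries a *variable forgetting factor*
``lambda_t`` that discounts the historical covariance when the measurement
residual is large:

    lambda_t = lambda_min + (lambda_max - lambda_min) * exp(-gamma * ||delta||^2)

    C_t+1 = (I - K H) C-_t+1 / lambda_t + (1 - 1/lambda_t) C_t

With small residuals ``lambda_t -> lambda_max`` (= 1 by default) and the
update degenerates to the standard Kalman form; with large residuals the
covariance is inflated so recent evidence dominates, letting the filter
re-converge quickly after abrupt or irregular target motion.

Noise scales with the box: the initial standard deviations are
``sigma_px = 2 w_p w``, ``sigma_py = 2 w_p h`` for position and
``sigma_vx = 10 w_v w``, ``sigma_vy = 10 w_v h`` for velocity, summed into
isotropic blocks ``sigma_p^2 = sigma_px^2 + sigma_py^2`` (likewise for
velocity) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import KalmanConfig
from .io import Detection

__all__ = [
    "NoiseModel", "MotionModel", "TrackState",
    "init_track", "predict", "gain", "forget_factor", "update",
]

#: relative eigenvalue floor applied to the covariance after each update
PSD_FLOOR_REL = 1e-6
#: smallest admissible box side in the state, px
MIN_BOX_SIDE = 1.0

# multipliers for the position / velocity standard deviations: velocity is
# differentiated and therefore noisier
POS_MULT = 2.0
VEL_MULT = 10.0


@dataclass(frozen=True)
class NoiseModel:
    """Noise weights and forgetting-factor parameters."""

    w_p: float = 1.0 / 20.0
    w_v: float = 1.0 / 160.0
    lambda_min: float = 0.6
    lambda_max: float = 1.0
    gamma: float = 0.01  # px^-2
    residual_normalized: bool = False
    per_component_init: bool = False

    def __post_init__(self):
        if not (0.0 < self.lambda_min <= self.lambda_max <= 1.0):
            raise ValueError(
                "forgetting-factor bounds must satisfy 0 < lambda_min <= lambda_max <= 1"
            )
        if self.gamma < 0 or self.w_p <= 0 or self.w_v <= 0:
            raise ValueError("gamma must be >= 0 and noise weights > 0")

    @classmethod
    def from_config(cls, cfg: KalmanConfig) -> "NoiseModel":
        return cls(
            w_p=cfg.w_p, w_v=cfg.w_v,
            lambda_min=cfg.lambda_min, lambda_max=cfg.lambda_max, gamma=cfg.gamma,
            residual_normalized=cfg.residual_normalized,
            per_component_init=cfg.per_component_init,
        )

    def sigmas(self, w: float, h: float) -> tuple[float, float, float, float]:
        """(sigma_px, sigma_py, sigma_vx, sigma_vy) for a box of size (w, h)."""
        return (
            POS_MULT * self.w_p * w,
            POS_MULT * self.w_p * h,
            VEL_MULT * self.w_v * w,
            VEL_MULT * self.w_v * h,
        )


class MotionModel:
    """Constant-velocity transition and linear observation model.

    ``F`` is the 8x8 block transition matrix with ``dt`` coupling position
    to velocity; ``H = [I4 0]`` observes the box directly.  The process
    noise ``Q`` and observation noise ``S`` are rebuilt from the current
    box size at every step so uncertainty tracks apparent target scale.
    """

    def __init__(self, nm: NoiseModel, dt: float = 1.0):
        self.nm = nm
        self.dt = dt
        F = np.eye(8)
        F[:4, 4:] = dt * np.eye(4)
        self.F = F
        self.H = np.hstack([np.eye(4), np.zeros((4, 4))])

    def process_noise(self, w: float, h: float) -> np.ndarray:
        """Per-step Q: squared per-component weights rebuilt from the box."""
        sp_w, sp_h = self.nm.w_p * w, self.nm.w_p * h
        sv_w, sv_h = self.nm.w_v * w, self.nm.w_v * h
        return np.diag(
            np.array([sp_w, sp_h, sp_w, sp_h, sv_w, sv_h, sv_w, sv_h]) ** 2
        )

    def obs_noise(self, w: float, h: float) -> np.ndarray:
        """Observation covariance S = sigma_p^2 * I4 from the current box."""
        s_px, s_py, _, _ = self.nm.sigmas(w, h)
        return (s_px**2 + s_py**2) * np.eye(4)


@dataclass
class TrackState:
    """Filter state: mean, covariance, and the last forgetting diagnostics."""

    X: np.ndarray            # (8,)
    C: np.ndarray            # (8, 8)
    last_residual_sq: float = 0.0
    lambda_t: float = 1.0
    predicted: bool = False  # True between predict and update

    @property
    def box(self) -> tuple[float, float, float, float]:
        return tuple(self.X[:4])


def init_track(det: Detection | tuple, nm: NoiseModel) -> TrackState:
    """Initialize a filter state from a first detection.

    Velocities start at zero (no prior motion information); the covariance
    is diagonal with isotropic position/velocity blocks
    ``diag(sigma_p^2 I4, sigma_v^2 I4)`` built from the box size.
    """
    box = det.box if isinstance(det, Detection) else tuple(det)
    x, y, w, h = box
    if w <= 0 or h <= 0:
        raise ValueError(f"cannot initialize a track from box {box}: nonpositive size")
    s_px, s_py, s_vx, s_vy = nm.sigmas(w, h)
    if nm.per_component_init:
        diag = np.array([s_px, s_py, s_px, s_py, s_vx, s_vy, s_vx, s_vy]) ** 2
    else:
        sigma_p2 = s_px**2 + s_py**2
        sigma_v2 = s_vx**2 + s_vy**2
        diag = np.array([sigma_p2] * 4 + [sigma_v2] * 4)
    X = np.array([x, y, w, h, 0.0, 0.0, 0.0, 0.0])
    return TrackState(X=X, C=np.diag(diag), lambda_t=nm.lambda_max, predicted=False)


def predict(s: TrackState, mm: MotionModel) -> TrackState:
    """Propagate the state one step: X- = F X, C- = F C F^T + Q."""
    X_minus = mm.F @ s.X
    Q = mm.process_noise(s.X[2], s.X[3])
    C_minus = mm.F @ s.C @ mm.F.T + Q
    return TrackState(
        X=X_minus, C=C_minus,
        last_residual_sq=s.last_residual_sq, lambda_t=s.lambda_t, predicted=True,
    )


def gain(C_minus: np.ndarray, mm: MotionModel, S: np.ndarray) -> np.ndarray:
    """Kalman gain K = C- H^T (H C- H^T + S)^-1 (8x4).

    A singular innovation covariance is regularized with a small ridge
    before the solve; if it is still singular a LinAlgError propagates so
    the caller can drop the track.
    """
    innov = mm.H @ C_minus @ mm.H.T + S
    try:
        K = np.linalg.solve(innov.T, (C_minus @ mm.H.T).T).T
    except np.linalg.LinAlgError:
        ridge = 1e-9 * max(np.trace(innov) / 4.0, 1.0)
        K = np.linalg.solve((innov + ridge * np.eye(4)).T, (C_minus @ mm.H.T).T).T
    return K


def forget_factor(residual_sq: float, nm: NoiseModel) -> float:
    """Variable forgetting factor: lambda_min + (lambda_max - lambda_min) e^{-gamma r2}.

    Continuous, monotone nonincreasing in the squared residual, and bounded
    in [lambda_min, lambda_max].
    """
    if residual_sq < 0:
        raise ValueError("squared residual must be nonnegative")
    lam = nm.lambda_min + (nm.lambda_max - nm.lambda_min) * np.exp(-nm.gamma * residual_sq)
    return float(min(max(lam, nm.lambda_min), nm.lambda_max))


def _psd_floor(C: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrize and clip eigenvalues from below at ``floor``."""
    C = 0.5 * (C + C.T)
    vals, vecs = np.linalg.eigh(C)
    if vals[0] >= floor:
        return C
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def update(
    s_minus: TrackState,
    z: np.ndarray,
    s_prev: TrackState,
    mm: MotionModel,
    nm: NoiseModel,
) -> TrackState:
    """Measurement update with the fading-memory covariance recursion.

    ``s_minus`` is the predicted state, ``z`` the observed box
    ``(x, y, w, h)``, and ``s_prev`` the last *updated* state whose
    covariance enters the fading term.  The updated covariance is
    symmetrized and eigenvalue-floored (the fading recursion with
    ``lambda_t < 1`` can otherwise lose positive semi-definiteness), and
    box sides in the state are kept positive.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (4,) or not np.all(np.isfinite(z)):
        raise ValueError(f"observation must be a finite 4-vector, got {z!r}")
    C_minus = s_minus.C
    S = mm.obs_noise(s_minus.X[2], s_minus.X[3])
    K = gain(C_minus, mm, S)

    delta = z - mm.H @ s_minus.X
    residual_sq = float(delta @ delta)
    if nm.residual_normalized:
        residual_sq /= float(np.trace(mm.H @ C_minus @ mm.H.T + S))
    lam = forget_factor(residual_sq, nm)

    X_plus = s_minus.X + K @ delta
    X_plus[2] = max(X_plus[2], MIN_BOX_SIDE)
    X_plus[3] = max(X_plus[3], MIN_BOX_SIDE)

    IKH = np.eye(8) - K @ mm.H
    C_plus = IKH @ C_minus / lam + (1.0 - 1.0 / lam) * s_prev.C
    C_plus = _psd_floor(C_plus, PSD_FLOOR_REL * np.trace(C_minus) / 8.0)

    return TrackState(
        X=X_plus, C=C_plus,
        last_residual_sq=residual_sq, lambda_t=lam, predicted=False,
    )


def coast(s_minus: TrackState) -> TrackState:
    """Accept a predicted state as the new filter state (no observation)."""
    return replace(s_minus, predicted=False)
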