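"""Virtual mirror-game player driven by two coupled phase oscillators.

The virtual character moves both hands on circles in a frontal (YZ) plane.
Each hand is a second-order Kuramoto-style oscillator: its angular velocity
is accelerated by a sine coupling toward the partner's opposite hand
(mirror pairing, gain ``k_inter``) and toward the character's own other
hand (gain ``k_intra``).  The circle radius is jittered by one-dimensional
gradient (Perlin) noise so the movement never looks perfectly mechanical.

Coordinate frame: a right-handed frame with ``x`` the facing axis (normal
to the movement plane), ``y`` vertical and ``z`` lateral.  The movement
plane sits at ``x = plane_offset`` in front of the character, which itself
stands ``partner_distance`` from the participant.

All phases are in radians wrapped to (-pi, pi], angular velocities in
rad/s, distances in metres, and time advances on a uniform grid with
``dt = 1 / sample_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .errors import EstimationError

__all__ = [
    "ModelConfig",
    "HandParams",
    "OscillatorState",
    "HandTrajectory",
    "wrap_phase",
    "perlin_noise",
    "radius_at",
    "position_of",
    "angular_accel",
    "step",
    "simulate_virtual",
    "estimate_params",
    "K_INTER_DEFAULT",
    "K_INTRA_DEFAULT",
    "R_MIN",
]

#: Inter-subject coupling gain used in the "coupling" condition [rad/s^2].
K_INTER_DEFAULT = 0.0075
#: Intra-subject coupling gain between the character's own hands [rad/s^2].
K_INTRA_DEFAULT = 0.005
#: Minimum mean radial distance below which a trajectory is considered
#: degenerate (no usable circular motion) [m].
R_MIN = 0.03

_TWO_PI = 2.0 * math.pi


def wrap_phase(theta):
    """Wrap an angle (scalar or array) to the interval (-pi, pi]."""
    w = np.mod(theta, _TWO_PI)
    return np.where(w > np.pi, w - _TWO_PI, w) if np.ndim(w) else (
        w - _TWO_PI if w > np.pi else w
    )


# --------------------------------------------------------------------------
# Configuration and state containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Global constants of the virtual player.

    Parameters
    ----------
    k_inter
        Coupling gain toward the human partner's hands [rad/s^2].  0 in the
        *no coupling* condition, 0.0075 in the *coupling* condition.
    k_intra
        Coupling gain between the virtual player's own hands [rad/s^2].
    noise_amplitude
        Half-range of the Perlin radius jitter [m].
    sample_rate
        Simulation and recording rate [Hz].
    plane_offset
        Distance of the movement plane from the character along the facing
        axis [m].
    partner_distance
        Distance between character and participant [m].
    duration
        Trial length [s].
    """

    k_inter: float = K_INTER_DEFAULT
    k_intra: float = K_INTRA_DEFAULT
    noise_amplitude: float = 0.085
    sample_rate: float = 50.0
    plane_offset: float = 0.343
    partner_distance: float = 1.246
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be nonnegative")
        if self.k_inter < 0 or self.k_intra < 0:
            raise ValueError("coupling gains must be nonnegative")

    @property
    def dt(self) -> float:
        """Simulation step [s]; the inverse of the sample rate."""
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        """Number of samples in one trial, including t = 0."""
        return int(round(self.duration * self.sample_rate)) + 1


@dataclass(frozen=True)
class HandParams:
    """Per-hand kinematic parameters (circle centre, radius, frequency)."""

    center: np.ndarray
    radius0: float
    omega0: float
    side: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        if not self.radius0 > 0:
            raise ValueError("radius0 must be positive")
        if not math.isfinite(self.omega0):
            raise ValueError("omega0 must be finite")


@dataclass(frozen=True)
class OscillatorState:
    """Evolving phases and angular velocities of the virtual player."""

    theta_right: float
    theta_left: float
    omega_right: float
    omega_left: float
    t: float
    noise_seed: int


@dataclass(frozen=True)
class HandTrajectory:
    """Timestamped 3-D positions of one hand on a uniform grid."""

    side: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "positions", np.asarray(self.positions, dtype=float)
        )
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        if self.times.ndim != 1 or self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must be (n, 3) matching times")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(steps) > 1e-9:
                raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# --------------------------------------------------------------------------
# Perlin noise
# --------------------------------------------------------------------------

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x):
    """Stateless 64-bit mix (SplitMix64 finaliser); deterministic everywhere."""
    with np.errstate(over="ignore"):
        z = np.asarray(x, dtype=np.uint64) + _SPLITMIX_GAMMA
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _gradients(nodes, seed: int):
    """Pseudo-random lattice gradients in [-1, 1), keyed by (seed, node)."""
    key = _splitmix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    h = _splitmix64(np.asarray(nodes, dtype=np.int64).view(np.uint64) ^ key)
    return (h >> np.uint64(11)).astype(np.float64) / float(1 << 53) * 2.0 - 1.0


def perlin_noise(t, seed: int, amplitude: float):
    """Classic one-dimensional gradient (Perlin) noise.

    Single octave on an integer lattice (one node per second), quintic
    fade interpolation.  The raw gradient-noise extremes are +/-0.5, so the
    output is rescaled by ``2 * amplitude`` to span ``[-amplitude,
    +amplitude]``.  The value is zero at every lattice node, continuous
    (C1) in ``t``, and deterministic given ``(t, seed)`` alone — no hidden
    state, so any sub-grid of times yields consistent values.

    Parameters
    ----------
    t
        Time in seconds; scalar or array.
    seed
        Stream key; different seeds give independent noise streams.
    amplitude
        Half-range of the output [m]; must be nonnegative.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    t_arr = np.asarray(t, dtype=float)
    i = np.floor(t_arr).astype(np.int64)
    u = t_arr - i
    g0 = _gradients(i, seed)
    g1 = _gradients(i + 1, seed)
    s = u * u * u * (u * (u * 6.0 - 15.0) + 10.0)  # quintic fade
    raw = (1.0 - s) * (g0 * u) + s * (g1 * (u - 1.0))
    out = 2.0 * amplitude * raw
    return out if t_arr.ndim else float(out)


def _side_noise_seed(seed: int, side: str) -> int:
    """Derive an independent noise stream per hand from the trial seed."""
    idx = 0 if side == "right" else 1
    return int(_splitmix64(np.uint64((seed & 0x7FFFFFFFFFFFFFFF) * 2 + idx)))


def radius_at(
    hand: HandParams, t: float, config: ModelConfig, seed: int
):
    """Instantaneous circle radius: ``radius0`` plus Perlin jitter.

    The right and left hands draw from independent noise streams derived
    from ``(seed, side)``.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be nonnegative")
    return hand.radius0 + perlin_noise(
        t, _side_noise_seed(seed, hand.side), config.noise_amplitude
    )


# --------------------------------------------------------------------------
# Kinematics and dynamics
# --------------------------------------------------------------------------

def position_of(hand: HandParams, theta: float, radius: float) -> np.ndarray:
    """Map a phase and radius to a 3-D hand position on the circle.

    The right hand traces ``c + r cos(theta) z_hat + r sin(theta) y_hat``;
    the left hand flips the sign of the lateral (z) term so the two hands
    counter-rotate and the movement stays mirror-symmetric.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    sign = 1.0 if hand.side == "right" else -1.0
    pos = hand.center.copy()
    pos[1] += radius * math.sin(theta)
    pos[2] += sign * radius * math.cos(theta)
    return pos


def angular_accel(
    state: OscillatorState,
    human_theta_right: float,
    human_theta_left: float,
    config: ModelConfig,
) -> Tuple[float, float]:
    """Sine-coupling angular accelerations of the two virtual hands.

    The pairing is crossed, as in a mirror: the virtual right hand couples
    to the human *left* hand and vice versa.  With ``k_inter = 0`` the
    human phases are ignored entirely (they may be NaN sentinels).
    """
    intra_r = config.k_intra * math.sin(
        wrap_phase(state.theta_left - state.theta_right)
    )
    intra_l = config.k_intra * math.sin(
        wrap_phase(state.theta_right - state.theta_left)
    )
    if config.k_inter == 0.0:
        return intra_r, intra_l
    inter_r = config.k_inter * math.sin(
        wrap_phase(human_theta_left - state.theta_right)
    )
    inter_l = config.k_inter * math.sin(
        wrap_phase(human_theta_right - state.theta_left)
    )
    return inter_r + intra_r, inter_l + intra_l


def step(
    state: OscillatorState,
    human_theta_right: float,
    human_theta_left: float,
    hands: Tuple[HandParams, HandParams],
    config: ModelConfig,
) -> Tuple[OscillatorState, np.ndarray, np.ndarray]:
    """Advance the oscillator one sample step (explicit Euler).

    Velocity first, then phase with the updated velocity:
    ``omega_k = omega_{k-1} + domega * dt`` and
    ``theta_k = wrap(theta_{k-1} + omega_k * dt)``.
    Returns the new state and both hand positions at the new time.
    """
    if config.k_inter > 0 and not (
        math.isfinite(human_theta_right) and math.isfinite(human_theta_left)
    ):
        raise ValueError("human phases must be finite when k_inter > 0")
    hand_r, hand_l = hands
    acc_r, acc_l = angular_accel(
        state, human_theta_right, human_theta_left, config
    )
    dt = config.dt
    omega_r = state.omega_right + acc_r * dt
    omega_l = state.omega_left + acc_l * dt
    theta_r = wrap_phase(state.theta_right + omega_r * dt)
    theta_l = wrap_phase(state.theta_left + omega_l * dt)
    t_new = state.t + dt
    new_state = OscillatorState(
        theta_right=theta_r,
        theta_left=theta_l,
        omega_right=omega_r,
        omega_left=omega_l,
        t=t_new,
        noise_seed=state.noise_seed,
    )
    pos_r = position_of(
        hand_r, theta_r, radius_at(hand_r, t_new, config, state.noise_seed)
    )
    pos_l = position_of(
        hand_l, theta_l, radius_at(hand_l, t_new, config, state.noise_seed)
    )
    return new_state, pos_r, pos_l


PhaseSource = Callable[[float], Tuple[float, float]]


def initial_state(
    hands: Tuple[HandParams, HandParams], seed: int
) -> OscillatorState:
    """State at t = 0: both hands at phase zero, at their base frequency."""
    hand_r, hand_l = hands
    return OscillatorState(
        theta_right=0.0,
        theta_left=0.0,
        omega_right=hand_r.omega0,
        omega_left=hand_l.omega0,
        t=0.0,
        noise_seed=int(seed),
    )


def simulate_virtual(
    hands: Tuple[HandParams, HandParams],
    config: ModelConfig,
    human_phase_source: Optional[PhaseSource] = None,
    seed: int = 0,
) -> Tuple[HandTrajectory, HandTrajectory]:
    """Run the virtual player for one trial.

    ``human_phase_source`` maps a time to the human's (right, left) hand
    phases; it is sampled at the *previous* tick when the oscillator steps
    (one-sample delay, as in a networked real-time loop).  It is required
    when ``k_inter > 0`` and ignored otherwise.  Output has
    ``duration * sample_rate + 1`` samples per hand and is fully
    deterministic given the seed.
    """
    if config.k_inter > 0 and human_phase_source is None:
        raise ValueError("a human phase source is required when k_inter > 0")
    hand_r, hand_l = hands
    n = config.n_samples
    state = initial_state(hands, seed)
    times = np.empty(n)
    pos_r = np.empty((n, 3))
    pos_l = np.empty((n, 3))
    times[0] = 0.0
    pos_r[0] = position_of(
        hand_r, state.theta_right, radius_at(hand_r, 0.0, config, seed)
    )
    pos_l[0] = position_of(
        hand_l, state.theta_left, radius_at(hand_l, 0.0, config, seed)
    )
    nan2 = (math.nan, math.nan)
    for k in range(1, n):
        if config.k_inter > 0:
            h_r, h_l = human_phase_source(state.t)
        else:
            h_r, h_l = nan2
        state, pr, pl = step(state, h_r, h_l, hands, config)
        times[k] = state.t
        pos_r[k] = pr
        pos_l[k] = pl
    return (
        HandTrajectory("right", times, pos_r),
        HandTrajectory("left", times, pos_l),
    )


# --------------------------------------------------------------------------
# Parameter estimation from a training trajectory
# --------------------------------------------------------------------------

def _estimate_one(traj: HandTrajectory) -> HandParams:
    if traj.duration < 2.0:
        raise EstimationError("need at least 2 s of training data")
    center = traj.positions.mean(axis=0)
    radial = np.linalg.norm(traj.positions - center, axis=1)
    if radial.mean() < R_MIN:
        raise EstimationError(
            f"near-stationary trajectory: mean radial distance "
            f"{radial.mean():.4f} m is below {R_MIN} m"
        )
    y = traj.positions[:, 1] - center[1]
    z = traj.positions[:, 2] - center[2]
    if traj.side == "left":
        z = -z
    theta = np.unwrap(np.arctan2(y, z))
    omega = float(abs(np.mean(np.diff(theta) / traj.dt)))
    return HandParams(
        center=center,
        radius0=float(radial.mean()),
        omega0=omega,
        side=traj.side,
    )


def estimate_params(
    training_right: HandTrajectory, training_left: HandTrajectory
) -> Tuple[HandParams, HandParams]:
    """Estimate each hand's circle centre, radius and angular frequency.

    The centre is the time-average position, the radius the time-average
    distance to that centre, and the frequency the mean derivative of the
    unwrapped phase (reported as a positive magnitude; the rotation
    direction is carried by each side's kinematic convention).

    Raises
    ------
    EstimationError
        If a trajectory is shorter than 2 s or nearly stationary (mean
        radial distance below ``R_MIN``).
    """
    return _estimate_one(training_right), _estimate_one(training_left)
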