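"""Synthetic human partners and closed-loop dyad trials.

The study's participants cannot be redistributed, so this module provides
a configurable stand-in: a synthetic "human" that traces quasi-circular
hand motion with realistic centre / radius / frequency magnitudes,
optional slow frequency drift (an Ornstein-Uhlenbeck process on the
angular velocity) and optional reciprocal coupling toward the virtual
player.  ``run_trial`` wires a synthetic human and the virtual player
into one 60-s trial under each of the three experimental conditions:

``human``
    The "virtual" character is a verbatim pass-through of a second
    simulated human; the oscillator model is not used.
``no_coupling``
    The virtual player runs open loop with ``k_inter = 0``.
``coupling``
    Human and virtual player are co-simulated tick by tick, each side
    seeing the other's phase from the previous tick (one-sample delay,
    mimicking a networked two-machine loop).

Every trial is bit-reproducible from ``(condition, profile, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core_model import (
    HandParams,
    HandTrajectory,
    ModelConfig,
    OscillatorState,
    initial_state,
    position_of,
    step,
    wrap_phase,
)
from .errors import MirrorGameError

__all__ = [
    "CONDITIONS",
    "HumanProfile",
    "TrialRecord",
    "default_profile",
    "simulate_human",
    "run_trial",
    "generate_button_stream",
    "generate_questionnaire",
    "generate_sync_times",
]

CONDITIONS = ("human", "no_coupling", "coupling")

#: Default button model: pressed when |relative phase| stays below pi/4
#: for at least 0.5 s.  Arbitrary but configurable; the real button data
#: are subjective reports.
BUTTON_THRESHOLD = math.pi / 4
BUTTON_DWELL = 0.5

#: Number of participants in the analysed study sample.
N_PARTICIPANTS = 34


@dataclass(frozen=True)
class HumanProfile:
    """Parameters of a synthetic human partner.

    ``kind`` selects the generative model: ``constant`` (fixed angular
    velocity), ``drifting`` (Ornstein-Uhlenbeck frequency wander) or
    ``coupled`` (the human also adapts toward the virtual player with
    gain ``k_human``).  Defaults reflect the magnitudes observed in
    training trials: hand circles of roughly 0.16 m radius traversed at
    roughly 2.7 rad/s, centred shoulder-width apart at chest height.
    """

    kind: str = "drifting"
    base_omega: float = 2.7
    base_radius: float = 0.16
    center_right: np.ndarray = field(
        default_factory=lambda: np.array([0.343, 1.3, 0.25])
    )
    center_left: np.ndarray = field(
        default_factory=lambda: np.array([0.343, 1.3, -0.25])
    )
    drift_sd: float = 0.3
    drift_tau: float = 5.0
    position_noise_sd: float = 0.005
    k_human: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center_right", np.asarray(self.center_right, dtype=float)
        )
        object.__setattr__(
            self, "center_left", np.asarray(self.center_left, dtype=float)
        )
        if self.kind not in ("constant", "drifting", "coupled"):
            raise ValueError(f"unknown profile kind: {self.kind!r}")
        if not self.base_omega > 0:
            raise ValueError("base_omega must be positive")
        if not self.base_radius > 0:
            raise ValueError("base_radius must be positive")
        if min(self.drift_sd, self.drift_tau, self.position_noise_sd) < 0:
            raise ValueError("noise parameters must be nonnegative")

    def hand_params(self) -> Tuple[HandParams, HandParams]:
        return (
            HandParams(self.center_right, self.base_radius, self.base_omega,
                       "right"),
            HandParams(self.center_left, self.base_radius, self.base_omega,
                       "left"),
        )


def default_profile(seed: int = 0, kind: str = "drifting") -> HumanProfile:
    """A partner profile with study-scale movement magnitudes."""
    return HumanProfile(kind=kind, seed=seed)


@dataclass(frozen=True)
class TrialRecord:
    """One 60-s trial: condition, both players' hands, button stream."""

    condition: str
    human_right: HandTrajectory
    human_left: HandTrajectory
    virtual_right: HandTrajectory
    virtual_left: HandTrajectory
    button: np.ndarray
    seed: int
    config: ModelConfig

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        grids = [
            t.times
            for t in (self.human_right, self.human_left,
                      self.virtual_right, self.virtual_left)
        ]
        for g in grids[1:]:
            if len(g) != len(grids[0]) or np.max(np.abs(g - grids[0])) > 1e-9:
                raise ValueError("all trajectories must share one time grid")
        if len(self.button) != len(grids[0]):
            raise ValueError("button series must match the time grid")


# --------------------------------------------------------------------------
# Synthetic human simulation
# --------------------------------------------------------------------------

def _human_phase_step(
    kind: str,
    theta: np.ndarray,
    omega: np.ndarray,
    base_omega: float,
    drift_sd: float,
    drift_tau: float,
    k_human: float,
    virtual_phases: Optional[Tuple[float, float]],
    dt: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Advance (theta_right, theta_left) and their velocities one tick."""
    omega = omega.copy()
    if kind == "drifting" and drift_sd > 0:
        # Euler-Maruyama OU step with stationary sd drift_sd around base_omega
        noise = rng.standard_normal(2)
        omega += (base_omega - omega) * (dt / drift_tau) + drift_sd * math.sqrt(
            2.0 * dt / drift_tau
        ) * noise
    elif kind == "coupled":
        v_r, v_l = virtual_phases
        # mirror pairing, same form as the virtual player's dynamics
        omega[0] += k_human * math.sin(wrap_phase(v_l - theta[0])) * dt
        omega[1] += k_human * math.sin(wrap_phase(v_r - theta[1])) * dt
    theta = wrap_phase(theta + omega * dt)
    return theta, omega


def simulate_human(
    profile: HumanProfile,
    config: ModelConfig,
    virtual_phase_source: Optional[Callable[[float], Tuple[float, float]]] = None,
) -> Tuple[HandTrajectory, HandTrajectory]:
    """Simulate one synthetic human partner for a full trial.

    Deterministic given ``profile.seed``.  ``coupled`` profiles require a
    ``virtual_phase_source`` mapping time to the virtual player's
    (right, left) phases; other kinds ignore it.
    """
    if profile.kind == "coupled" and virtual_phase_source is None:
        raise ValueError("coupled profiles need a virtual phase source")
    rng = np.random.default_rng(profile.seed)
    n = config.n_samples
    dt = config.dt
    hand_r, hand_l = profile.hand_params()
    theta = np.zeros(2)
    omega = np.full(2, profile.base_omega)
    times = np.arange(n) * dt
    thetas = np.empty((n, 2))
    thetas[0] = theta
    for k in range(1, n):
        vp = None
        if profile.kind == "coupled":
            vp = virtual_phase_source(times[k - 1])
        theta, omega = _human_phase_step(
            profile.kind, theta, omega, profile.base_omega,
            profile.drift_sd, profile.drift_tau, profile.k_human,
            vp, dt, rng,
        )
        thetas[k] = theta
    pos_r = _circle_positions(hand_r, thetas[:, 0])
    pos_l = _circle_positions(hand_l, thetas[:, 1])
    if profile.position_noise_sd > 0:
        pos_r = pos_r + rng.normal(0, profile.position_noise_sd, pos_r.shape)
        pos_l = pos_l + rng.normal(0, profile.position_noise_sd, pos_l.shape)
    return (
        HandTrajectory("right", times, pos_r),
        HandTrajectory("left", times, pos_l),
    )


def _circle_positions(hand: HandParams, thetas: np.ndarray) -> np.ndarray:
    sign = 1.0 if hand.side == "right" else -1.0
    pos = np.tile(hand.center, (len(thetas), 1))
    pos[:, 1] += hand.radius0 * np.sin(thetas)
    pos[:, 2] += sign * hand.radius0 * np.cos(thetas)
    return pos


# --------------------------------------------------------------------------
# Closed-loop trials
# --------------------------------------------------------------------------

def _derive_seed(seed: int, salt: int) -> int:
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, salt])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _phase_source_from(traj_r: HandTrajectory, traj_l: HandTrajectory):
    """Sample-and-hold phase source backed by two recorded trajectories."""
    ph_r = _trajectory_phases(traj_r)
    ph_l = _trajectory_phases(traj_l)
    dt = traj_r.dt
    n = len(ph_r)

    def source(t: float) -> Tuple[float, float]:
        k = min(n - 1, max(0, int(round(t / dt))))
        return float(ph_r[k]), float(ph_l[k])

    return source


def _trajectory_phases(traj: HandTrajectory) -> np.ndarray:
    """Phase of a synthetic circular trajectory around its mean centre."""
    center = traj.positions.mean(axis=0)
    y = traj.positions[:, 1] - center[1]
    z = traj.positions[:, 2] - center[2]
    if traj.side == "left":
        z = -z
    return np.arctan2(y, z)


def _closed_loop(
    profile: HumanProfile,
    hands: Tuple[HandParams, HandParams],
    config: ModelConfig,
    seed: int,
) -> Tuple[HandTrajectory, HandTrajectory, HandTrajectory, HandTrajectory]:
    """Co-simulate human and virtual player with a one-tick phase delay."""
    rng = np.random.default_rng(profile.seed)
    n = config.n_samples
    dt = config.dt
    h_r, h_l = profile.hand_params()
    v_state = initial_state(hands, seed)
    theta_h = np.zeros(2)
    omega_h = np.full(2, profile.base_omega)

    times = np.arange(n) * dt
    h_thetas = np.empty((n, 2))
    h_thetas[0] = theta_h
    v_pos_r = np.empty((n, 3))
    v_pos_l = np.empty((n, 3))
    from .core_model import radius_at  # local import avoids cycle at top

    v_pos_r[0] = position_of(
        hands[0], v_state.theta_right, radius_at(hands[0], 0.0, config, seed)
    )
    v_pos_l[0] = position_of(
        hands[1], v_state.theta_left, radius_at(hands[1], 0.0, config, seed)
    )
    for k in range(1, n):
        prev_h = (theta_h[0], theta_h[1])
        prev_v = (v_state.theta_right, v_state.theta_left)
        v_state, pr, pl = step(v_state, prev_h[0], prev_h[1], hands, config)
        theta_h, omega_h = _human_phase_step(
            profile.kind, theta_h, omega_h, profile.base_omega,
            profile.drift_sd, profile.drift_tau, profile.k_human,
            prev_v, dt, rng,
        )
        h_thetas[k] = theta_h
        v_pos_r[k] = pr
        v_pos_l[k] = pl
    h_pos_r = _circle_positions(h_r, h_thetas[:, 0])
    h_pos_l = _circle_positions(h_l, h_thetas[:, 1])
    if profile.position_noise_sd > 0:
        h_pos_r = h_pos_r + rng.normal(0, profile.position_noise_sd,
                                       h_pos_r.shape)
        h_pos_l = h_pos_l + rng.normal(0, profile.position_noise_sd,
                                       h_pos_l.shape)
    return (
        HandTrajectory("right", times, h_pos_r),
        HandTrajectory("left", times, h_pos_l),
        HandTrajectory("right", times, v_pos_r),
        HandTrajectory("left", times, v_pos_l),
    )


def run_trial(
    condition: str,
    profile: HumanProfile,
    hands: Optional[Tuple[HandParams, HandParams]] = None,
    config: Optional[ModelConfig] = None,
    seed: int = 0,
) -> TrialRecord:
    """Run one trial in the given condition and package the results.

    ``hands`` are the virtual player's parameters (defaults to the
    profile's own magnitudes, as if estimated from a training trial).
    The button stream is generated from the relative phase between the
    human's right hand and the virtual left hand (the pair facing it).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition!r}")
    config = config or ModelConfig()
    if hands is None:
        hands = profile.hand_params()

    if condition == "human":
        # pass-through: the "virtual" hands replay a second simulated
        # human verbatim; the oscillator model is not used at all
        cfg = replace(config, k_inter=0.0)
        partner = replace(
            profile,
            seed=_derive_seed(seed, 1),
            kind="drifting" if profile.kind == "coupled" else profile.kind,
        )
        virt_r, virt_l = simulate_human(partner, cfg)
        source = _phase_source_from(virt_r, virt_l)
        human_r, human_l = simulate_human(
            profile, cfg,
            virtual_phase_source=source if profile.kind == "coupled" else None,
        )
    else:
        # both oscillator conditions co-simulate human and virtual player
        # tick by tick; with k_inter = 0 the virtual side runs open loop
        k = 0.0 if condition == "no_coupling" else (config.k_inter or 0.0075)
        cfg = replace(config, k_inter=k)
        human_r, human_l, virt_r, virt_l = _closed_loop(
            profile, hands, cfg, seed
        )

    rel = wrap_phase(
        _trajectory_phases(human_r) - _trajectory_phases(virt_l)
    )
    button = generate_button_stream(
        rel, BUTTON_THRESHOLD, BUTTON_DWELL, sample_rate=cfg.sample_rate
    )
    return TrialRecord(
        condition=condition,
        human_right=human_r,
        human_left=human_l,
        virtual_right=virt_r,
        virtual_left=virt_l,
        button=button,
        seed=seed,
        config=cfg,
    )


def simulate_virtual_open_loop(hands, config, seed):
    """Open-loop virtual player (no human input); thin wrapper."""
    from .core_model import simulate_virtual

    return simulate_virtual(hands, config, human_phase_source=None, seed=seed)


# --------------------------------------------------------------------------
# Button stream and questionnaire synthesis
# --------------------------------------------------------------------------

def generate_button_stream(
    relative_phase: np.ndarray,
    threshold: float = BUTTON_THRESHOLD,
    dwell: float = BUTTON_DWELL,
    sample_rate: float = 50.0,
) -> np.ndarray:
    """Synthetic synchrony-report button: pressed after sustained alignment.

    The button is pressed at time t iff the wrapped relative phase has
    stayed strictly within ``threshold`` for the whole preceding ``dwell``
    seconds (inclusive of t).
    """
    if not 0 < threshold <= math.pi:
        raise ValueError("threshold must be in (0, pi]")
    if dwell < 0:
        raise ValueError("dwell must be nonnegative")
    ok = np.abs(wrap_phase(np.asarray(relative_phase))) < threshold
    w = int(round(dwell * sample_rate))
    if w == 0:
        return ok.copy()
    pressed = np.zeros_like(ok)
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        pressed[i] = run >= w + 1  # w+1 samples span dwell seconds
    return pressed


def generate_questionnaire(
    n_participants: int = N_PARTICIPANTS,
    effects: Optional[Mapping[int, Mapping[str, float]]] = None,
    sd: float = 1.0,
    seed: int = 0,
    n_questions: int = 10,
    intercept_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Synthesize a post-trial questionnaire table.

    Each response is ``round(clip(base + condition effect + participant
    intercept + noise, -3, 3))`` on the 7-point scale from -3 to +3.
    ``effects`` maps question index (1-based) to per-condition mean
    shifts, e.g. ``{9: {"coupling": 2.0}}``.  Participant intercepts have
    standard deviation ``intercept_sd`` (default: half of ``sd``).

    Returns a tidy DataFrame with columns
    ``participant, condition, question, response``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    effects = effects or {}
    if intercept_sd is None:
        intercept_sd = 0.5 * sd
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, intercept_sd, n_participants)
    rows = []
    for p in range(n_participants):
        for cond in CONDITIONS:
            for q in range(1, n_questions + 1):
                shift = effects.get(q, {}).get(cond, 0.0)
                value = shift + intercepts[p] + rng.normal(0.0, sd)
                rows.append(
                    (p, cond, q, int(round(float(np.clip(value, -3, 3)))))
                )
    return pd.DataFrame(
        rows, columns=["participant", "condition", "question", "response"]
    )


def generate_sync_times(
    n_participants: int = N_PARTICIPANTS,
    shift_coupling: float = 2.2,
    shift_no_coupling: float = -3.1,
    baseline_sd: float = 6.0,
    condition_sd: float = 12.0,
    ceiling_fraction: float = 0.25,
    duration: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthesize a per-participant time-in-sync table.

    Emulates the qualitative structure of real synchrony reports: each
    participant has an idiosyncratic base tendency to hold the button,
    a ``ceiling_fraction`` of participants press nearly all the time
    (producing heavy non-normal raw distributions), and the true
    condition effects (``shift_coupling``, ``shift_no_coupling``,
    seconds relative to the *human* baseline) are small compared with
    the between-participant spread.  Times are clipped to
    ``[0, duration]``.

    Returns a tidy DataFrame with columns
    ``participant, condition, time_pressed_s``.
    """
    rng = np.random.default_rng(seed)
    ceiling = rng.random(n_participants) < ceiling_fraction
    base = np.where(
        ceiling,
        rng.uniform(duration - 8.0, duration, n_participants),
        rng.normal(0.4 * duration, 0.2 * duration, n_participants),
    )
    shifts = {"human": 0.0, "coupling": shift_coupling,
              "no_coupling": shift_no_coupling}
    rows = []
    for p in range(n_participants):
        b = base[p] + rng.normal(0.0, baseline_sd)
        for cond in CONDITIONS:
            t = b + shifts[cond] + rng.normal(0.0, condition_sd)
            rows.append((p, cond, float(np.clip(t, 0.0, duration))))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "time_pressed_s"]
    )
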